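"""Checks against the deposited whole-blood TPM matrix (optional).

The study's TPM matrix (11 patients, 9 healthy controls; rows keyed by
Ensembl gene IDs) is publicly deposited but not bundled here.  Users who
download it can run :func:`marker_gene_checks` to reproduce the headline
marker-gene numbers: group medians of glycophorin C (GYPC,
ENSG00000136732) expression, its direction-folded AUC, the Youden-optimal
TPM cutoff (reported near 450 in the source cohort), and LOOCV sensitivity
and specificity with the single-gene bagged-tree ensemble.
"""

from __future__ import annotations

import numpy as np

from . import discriminate
from .io_formats import read_tpm_matrix

GYPC = "ENSG00000136732"


def marker_gene_checks(tpm_path, labels_path, gene: str = GYPC,
                       ensemble_size: int = 500, seed: int = 0) -> dict:
    """Marker-gene summary on an externally downloaded TPM matrix."""
    tpm, labels = read_tpm_matrix(tpm_path, labels_path)
    if gene not in tpm.tpm.index:
        raise KeyError(f"{gene} not found in the matrix")
    values = tpm.tpm.loc[gene, labels.sample_ids].to_numpy(dtype=float)
    case = tpm.tpm.loc[gene, labels.case_ids].to_numpy(dtype=float)
    ctrl = tpm.tpm.loc[gene, labels.control_ids].to_numpy(dtype=float)
    roc = discriminate.best_cutoff(values, labels, gene)
    sens, spec, confusion = discriminate.loocv_ensemble(
        [gene], tpm, labels, ensemble_size=ensemble_size, seed=seed)
    return {
        "gene": gene,
        "median_tpm_case": float(np.median(case)),
        "median_tpm_control": float(np.median(ctrl)),
        "folded_auc": roc.folded_auc,
        "best_cutoff_tpm": roc.cutoff,
        "direction": roc.direction,
        "loocv_sensitivity": sens,
        "loocv_specificity": spec,
        "loocv_confusion": confusion,
    }
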