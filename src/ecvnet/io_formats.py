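"""Tabular / network / report input-output and the core data containers.

All matrices travel as tab-separated text with a header row of sample IDs and
a first column headed ``gene_id``.  Networks are exported as SIF (one
``parent<TAB>regulates<TAB>child`` line per edge) for Cytoscape-style viewers
and as JSON for lossless round trips.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

TPM_TOTAL = 1e6


class FormatError(ValueError):
    """Raised when an input table violates the documented contracts."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

def _check_unique(index: pd.Index, what: str) -> None:
    if index.duplicated().any():
        dup = index[index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} IDs: {dup[:5]}")


@dataclass
class CountMatrix:
    """Integer read counts (genes x samples) with per-gene lengths in bases."""

    counts: pd.DataFrame
    gene_lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.empty:
            raise FormatError("empty count matrix")
        _check_unique(self.counts.index, "gene")
        _check_unique(self.counts.columns, "sample")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric count cell")
        if np.any(values < 0):
            raise FormatError("negative count")
        if not np.all(np.equal(np.mod(values, 1), 0)):
            raise FormatError("non-integer count")
        self.counts = self.counts.astype(np.int64)
        missing = self.counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise FormatError(f"missing gene length for {missing.tolist()[:5]}")
        self.gene_lengths = self.gene_lengths.reindex(self.counts.index).astype(float)
        if np.any(self.gene_lengths.to_numpy() <= 0):
            raise FormatError("gene lengths must be positive")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


CASE, CONTROL = "case", "control"


@dataclass
class SampleLabels:
    """case/control assignment, ordered like the matrix it accompanies."""

    group: pd.Series  # index = sample IDs, values in {case, control}

    def __post_init__(self) -> None:
        _check_unique(self.group.index, "sample")
        bad = set(self.group.unique()) - {CASE, CONTROL}
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        if not (self.n_case and self.n_control):
            raise FormatError("both groups must be non-empty")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.group.index)

    @property
    def case_ids(self) -> list[str]:
        return list(self.group.index[self.group == CASE])

    @property
    def control_ids(self) -> list[str]:
        return list(self.group.index[self.group == CONTROL])

    @property
    def n_case(self) -> int:
        return int((self.group == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.group == CONTROL).sum())

    def matches(self, sample_ids) -> bool:
        return set(sample_ids) == set(self.group.index)


@dataclass
class TPMMatrix:
    """Transcripts-per-million matrix; every column sums to 1e6."""

    tpm: pd.DataFrame
    column_sum_rtol: float = 1e-6

    def __post_init__(self) -> None:
        _check_unique(self.tpm.index, "gene")
        _check_unique(self.tpm.columns, "sample")
        values = self.tpm.to_numpy(dtype=float)
        if np.any(~np.isfinite(values)):
            raise FormatError("non-finite TPM cell")
        if np.any(values < 0):
            raise FormatError("negative TPM value")
        sums = values.sum(axis=0)
        rel = np.abs(sums - TPM_TOTAL) / TPM_TOTAL
        if np.any(rel > self.column_sum_rtol):
            raise FormatError(
                f"TPM column sums deviate from 1e6 (max rel err {rel.max():.3g})"
            )
        self.tpm = self.tpm.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tpm.columns)


@dataclass
class ExpressionMatrix:
    """Real-valued expression (genes x samples) with a scale tag."""

    frame: pd.DataFrame
    scale: str  # tpm | log_tpm | standardized

    def __post_init__(self) -> None:
        if self.scale not in {"tpm", "log_tpm", "standardized"}:
            raise ValueError(f"unknown scale tag {self.scale!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)


@dataclass
class PipelineConfig:
    """Knobs for the full analysis; defaults are the study conditions.

    top_fraction is the differential-edge selection fraction (the study's
    "top 0.001%" = 1e-5 of basal edges); de_count_filter is the total-count
    floor for the volcano comparison.
    """

    top_fraction: float = 1e-5
    min_selected_edges: int = 1
    max_parents: int = 3
    candidate_parents_k: int = 10
    spline_df: int = 4
    restarts: int = 3
    ridge: float = 1.0
    seed: int = 0
    pseudo_count: float = 1.0
    de_count_filter: int = 6
    ensemble_size: int = 500
    standardize: bool = True        # fit the network on standardized log2(TPM+1)
    ecv_absolute: bool = False      # |ECv| before group averaging (alt convention)
    loocv_all_representatives: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must lie in (0, 1]")
        for name in ("min_selected_edges", "max_parents", "candidate_parents_k",
                     "spline_df", "restarts", "ensemble_size"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pseudo_count <= 0:
            raise ValueError("pseudo_count must be positive")
        if self.de_count_filter < 0:
            raise ValueError("de_count_filter must be >= 0")

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return PipelineConfig(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise FormatError(f"empty or missing file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if frame.empty:
        raise FormatError(f"no data rows in {path}")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return frame


def _read_keyed_series(path, column: str) -> pd.Series:
    frame = _read_table(path)
    if column not in frame.columns:
        if frame.shape[1] == 1:
            column = frame.columns[0]
        else:
            raise FormatError(f"column {column!r} not found in {path}")
    return frame[column]


def read_labels(path) -> SampleLabels:
    return SampleLabels(_read_keyed_series(path, "group").astype(str))


def read_count_matrix(path, lengths_path, labels_path) -> tuple[CountMatrix, SampleLabels]:
    """Read counts + gene lengths + sample labels, preserving file order."""
    raw = _read_table(path)
    try:
        numeric = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric count cell: {exc}") from exc
    lengths = pd.to_numeric(_read_keyed_series(lengths_path, "length"))
    counts = CountMatrix(numeric, lengths)
    labels = read_labels(labels_path)
    if not labels.matches(counts.sample_ids):
        raise FormatError("label table does not cover the matrix samples")
    labels = SampleLabels(labels.group.reindex(counts.sample_ids))
    return counts, labels


def read_tpm_matrix(path, labels_path) -> tuple[TPMMatrix, SampleLabels]:
    """Read an externally produced TPM matrix (relaxed column-sum check).

    Deposited matrices are often rounded, so deviations of the column sums
    from 1e6 up to 0.1% are tolerated; anything beyond raises, anything
    beyond 1e-6 relative warns.
    """
    raw = _read_table(path)
    try:
        numeric = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric TPM cell: {exc}") from exc
    tpm = TPMMatrix(numeric, column_sum_rtol=1e-3)
    rel = np.abs(tpm.tpm.sum(axis=0).to_numpy() - TPM_TOTAL) / TPM_TOTAL
    if np.any(rel > 1e-6):
        warnings.warn(
            f"TPM column sums deviate from 1e6 by up to {rel.max():.2e} (rounded input?)",
            stacklevel=2,
        )
    labels = read_labels(labels_path)
    if not labels.matches(tpm.sample_ids):
        raise FormatError("label table does not cover the matrix samples")
    return tpm, SampleLabels(labels.group.reindex(tpm.sample_ids))


def write_matrix(frame: pd.DataFrame, path, float_format: str | None = None) -> None:
    frame.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def write_labels(labels: SampleLabels, path) -> None:
    labels.group.rename("group").to_csv(path, sep="\t", index_label="sample_id")


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.rename("length").to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def _edge_list(network) -> list[tuple[str, str]]:
    if hasattr(network, "edges"):
        edges = list(network.edges)
    else:
        edges = list(network)
    return [(str(p), str(c)) for p, c in edges]


def write_network_sif(network, path) -> None:
    """One ``parent<TAB>regulates<TAB>child`` line per edge, lexically sorted."""
    lines = [f"{p}\tregulates\t{c}" for p, c in sorted(_edge_list(network))]
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_sif(path) -> list[tuple[str, str]]:
    edges = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"malformed SIF line: {line!r}")
        edges.append((parts[0], parts[2]))
    return edges


def write_network_json(model, path) -> None:
    """Lossless serialization of a fitted network (nodes, knots, coefficients)."""
    payload = {
        "gene_ids": model.gene_ids,
        "score": model.score,
        "config": model.config,
        "nodes": {
            g: {"intercept": model.intercepts[g], "resid_var": model.resid_var[g],
                "score": model.node_scores[g]}
            for g in model.gene_ids
        },
        "edges": [
            {
                "parent": p,
                "child": c,
                "support": [sm.basis.lo, sm.basis.hi],
                "interior_knots": list(sm.basis.interior),
                "coef": list(sm.coef),
                "col_means": list(sm.col_means),
            }
            for (p, c), sm in sorted(model.smoothers.items())
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def write_report(report, edge_set, subnets, out_dir) -> dict[str, Path]:
    """Write the summary tables: subnetwork gene list (with the best-AUC
    flag per subnetwork), the ranked differential-edge table, and the
    classification summary.  Deterministic: same inputs give identical bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    subnet_genes = {g for sn in subnets for g in sn.genes}
    if report is not None:
        unknown = set(report.candidate_genes) - subnet_genes
        if unknown:
            raise FormatError(f"report genes outside the subnetworks: {sorted(unknown)[:5]}")

    gene_rows = []
    for sn in subnets:
        for g in sn.genes:
            gene_rows.append({
                "subnetwork": sn.component_id,
                "gene_id": g,
                "auc": round(sn.gene_aucs[g], 6),
                "best_auc_in_subnetwork": int(g == sn.representative),
                "min_abs_pearson_r": round(sn.min_abs_correlation, 6),
            })
    genes_path = out_dir / "subnetwork_genes.tsv"
    pd.DataFrame(gene_rows).to_csv(genes_path, sep="\t", index=False)

    edges_path = out_dir / "differential_edges.tsv"
    edge_set.table.to_csv(edges_path, sep="\t", index=False)

    cls_path = out_dir / "classification.json"
    payload = None if report is None else report.to_dict()
    cls_path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return {"genes": genes_path, "edges": edges_path, "classification": cls_path}


def run_pipeline(config, counts=None, labels=None, tpm=None, out_dir=None):
    """Orchestration entry point; see :func:`ecvnet.pipeline.run_pipeline`."""
    from .pipeline import run_pipeline as _run
    return _run(config, counts=counts, labels=labels, tpm=tpm, out_dir=out_dir)
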