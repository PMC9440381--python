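"""End-to-end orchestration: counts -> TPM -> network -> ECv -> markers.

Every stage is deterministic given (inputs, config, config.seed).  The
single config seed is expanded into per-stage seeds through a fixed scheme
(``numpy.random.SeedSequence(seed).generate_state(...)``), so reruns with
the same inputs produce byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import discriminate, ecv_diff, network, preprocess
from .io_formats import (
    CountMatrix,
    ExpressionMatrix,
    PipelineConfig,
    SampleLabels,
    TPMMatrix,
    write_matrix,
    write_network_json,
    write_network_sif,
    write_report,
)


def stage_seeds(seed: int) -> dict[str, int]:
    """Per-stage 31-bit seeds expanded from the single config seed."""
    state = np.random.SeedSequence(seed).generate_state(4)
    names = ["simulate", "learn", "loocv", "spare"]
    return {name: int(s % (2**31 - 1)) for name, s in zip(names, state)}


def prepare_expression(tpm: TPMMatrix, config: PipelineConfig,
                       genes: list[str] | None = None
                       ) -> tuple[ExpressionMatrix, list[str]]:
    """log2(TPM + pseudo) restricted to ``genes`` then (optionally) row-
    standardized; returns the matrix and the constant genes dropped."""
    log = preprocess.log_transform(tpm, config.pseudo_count)
    if genes is not None:
        log = ExpressionMatrix(log.frame.loc[genes], log.scale)
    if not config.standardize:
        return log, []
    return preprocess.standardize(log)


@dataclass
class PipelineResult:
    config: PipelineConfig
    tpm: TPMMatrix
    expression: ExpressionMatrix
    model: network.GeneNetworkModel
    ecv: ecv_diff.ECvMatrix
    edge_set: ecv_diff.DifferentialEdgeSet
    subnetworks: list
    report: discriminate.DiscriminationReport
    volcano: pd.DataFrame | None
    log: list[str]
    paths: dict


def run_pipeline(config: PipelineConfig, counts: CountMatrix | None = None,
                 labels: SampleLabels | None = None,
                 tpm: TPMMatrix | None = None,
                 out_dir=None) -> PipelineResult:
    """normalize -> learn -> ECv -> differential edges -> subnetworks ->
    discrimination, with every artifact written under ``out_dir`` when given.
    """
    if labels is None:
        raise ValueError("sample labels are required")
    if (counts is None) == (tpm is None):
        raise ValueError("provide exactly one of counts or tpm")
    seeds = stage_seeds(config.seed)
    log: list[str] = [f"seed={config.seed} stage_seeds={seeds}"]

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    volcano = None
    if counts is not None:
        tpm = stage("tpm")(preprocess.compute_tpm, counts)
        log.append(f"tpm: {len(tpm.gene_ids)} genes x {len(tpm.sample_ids)} samples")
        volcano = stage("volcano")(
            preprocess.simple_de, tpm, labels, counts, config.de_count_filter,
            config.pseudo_count)
        kept = stage("filter")(preprocess.filter_genes, counts, config.de_count_filter)
        genes = kept.gene_ids
        log.append(f"count filter > {config.de_count_filter}: kept {len(genes)} genes")
    else:
        genes = None
        log.append(f"external TPM input: {len(tpm.gene_ids)} genes")

    expression, constant = stage("prepare")(prepare_expression, tpm, config, genes)
    if constant:
        log.append(f"dropped {len(constant)} constant gene(s)")
    model = stage("learn")(network.learn_structure, expression, config, seeds["learn"])
    log.append(f"network: {len(model.edges)} edges, score={model.score:.6f}, "
               f"seed={seeds['learn']}")

    ecv = stage("ecv")(ecv_diff.compute_ecv, model, expression)
    edge_set = stage("diffedges")(
        ecv_diff.differential_edges, ecv, labels, config.top_fraction,
        config.min_selected_edges, config.ecv_absolute)
    log.append(f"differential edges: {edge_set.n_selected} of {len(ecv.edges)} "
               f"(q={config.top_fraction})")

    if edge_set.n_selected:
        subnets = stage("subnet")(ecv_diff.extract_subnetworks, edge_set)
        subnets = stage("subnet_stats")(ecv_diff.subnetwork_stats, subnets, tpm, labels)
        log.append(f"subnetworks: {len(subnets)}")
        representatives = [sn.representative for sn in subnets]
        report = stage("classify")(
            discriminate.evaluate_markers, representatives, tpm, labels,
            config.ensemble_size, seeds["loocv"], config.loocv_all_representatives)
        log.append(
            f"classification: stepwise={list(report.stepwise_selected)} "
            f"tree={list(report.tree_genes)} "
            f"loocv sens={report.loocv_sensitivity:.4f} spec={report.loocv_specificity:.4f}")
    else:
        # degenerate basal network (no edges): no subnetworks, no marker
        subnets, report = [], None
        log.append("no differential edges selected; no marker evaluation")

    paths: dict = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_matrix(tpm.tpm, out_dir / "tpm.tsv", float_format="%.6f")
        write_network_sif(model, out_dir / "network.sif")
        write_network_json(model, out_dir / "network.json")
        ecv.frame.reset_index().to_csv(out_dir / "ecv.tsv", sep="\t", index=False,
                                       float_format="%.10g")
        paths = write_report(report, edge_set, subnets, out_dir)
        write_network_sif([e for e in edge_set.edges], out_dir / "differential_edges.sif")
        if volcano is not None:
            volcano.to_csv(out_dir / "volcano.tsv", sep="\t", index=False,
                           float_format="%.10g")
        (out_dir / "log.txt").write_text("".join(line + "\n" for line in log))
        paths.update({"tpm": out_dir / "tpm.tsv", "sif": out_dir / "network.sif",
                      "network": out_dir / "network.json", "ecv": out_dir / "ecv.tsv",
                      "log": out_dir / "log.txt"})

    return PipelineResult(config, tpm, expression, model, ecv, edge_set,
                          subnets, report, volcano, log, paths)
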