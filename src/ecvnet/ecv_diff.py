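"""Per-sample edge contribution values and differential-edge extraction.

The edge contribution value (ECv) of edge u->v in sample s is the fitted,
centered smoother for u->v evaluated at s's expression of u: a per-sample,
per-edge activity score on the basal network.  Group-averaging ECv per edge
and ranking edges by the absolute difference of the group means yields the
"differentially regulated" edges (top fraction q, default the study's
0.001% = 1e-5); their weakly connected components are the subnetworks, each
summarized by its internal TPM correlation and a representative gene chosen
by direction-folded AUC.

Contributions are kept signed per sample and the absolute value is applied
at the group-difference step; averaging |ECv| instead is available behind
``absolute_first`` since the convention is not pinned down.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .discriminate import auc
from .io_formats import ExpressionMatrix, SampleLabels, TPMMatrix
from .network import GeneNetworkModel

Edge = tuple[str, str]


@dataclass(frozen=True)
class ECvMatrix:
    edges: tuple[Edge, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # edges x samples

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.edges), len(self.sample_ids)):
            raise ValueError("ECv matrix shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite ECv")

    @property
    def frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.edges, names=["parent", "child"])
        return pd.DataFrame(self.values, index=idx, columns=list(self.sample_ids))


@dataclass(frozen=True)
class DifferentialEdgeSet:
    table: pd.DataFrame         # all basal edges ranked by delta
    q: float
    n_selected: int

    @property
    def edges(self) -> tuple[Edge, ...]:
        sel = self.table[self.table["selected"] == 1]
        return tuple(zip(sel["parent"], sel["child"]))

    @property
    def deltas(self) -> dict[Edge, float]:
        sel = self.table[self.table["selected"] == 1]
        return {(p, c): d for p, c, d in zip(sel["parent"], sel["child"], sel["delta"])}


@dataclass
class Subnetwork:
    component_id: int
    genes: tuple[str, ...]
    edges: tuple[Edge, ...]
    edge_deltas: dict = field(default_factory=dict)
    min_abs_correlation: float | None = None
    gene_aucs: dict = field(default_factory=dict)
    representative: str | None = None
    best_auc: float | None = None


def compute_ecv(network: GeneNetworkModel, data: ExpressionMatrix) -> ECvMatrix:
    """ECv(u->v, s) = centered smoother of u->v at sample s's expression of u.

    ``data`` must be on the same scale/standardization the network was
    fitted on.
    """
    missing = [g for g in network.gene_ids if g not in data.frame.index]
    if missing:
        raise KeyError(f"genes missing from data: {missing[:5]}")
    edges = tuple(sorted(network.edges))
    rows = np.empty((len(edges), data.frame.shape[1]))
    for i, (p, c) in enumerate(edges):
        rows[i] = network.smoothers[(p, c)].contribution(
            data.frame.loc[p].to_numpy(dtype=float))
    return ECvMatrix(edges, tuple(data.frame.columns), rows)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def differential_edges(ecv: ECvMatrix, labels: SampleLabels, q: float,
                       floor: int = 1, absolute_first: bool = False) -> DifferentialEdgeSet:
    """Rank basal edges by |mean case ECv - mean control ECv|, keep the top
    max(floor, round(q * E)) of them (capped at E); ties break lexically.
    """
    if not (0 < q <= 1):
        raise ValueError("q must lie in (0, 1]")
    if labels.n_case == 0 or labels.n_control == 0:
        raise ValueError("both groups must be non-empty")
    cols = list(ecv.sample_ids)
    case_idx = [cols.index(s) for s in labels.case_ids]
    ctrl_idx = [cols.index(s) for s in labels.control_ids]
    values = np.abs(ecv.values) if absolute_first else ecv.values
    mean_case = values[:, case_idx].mean(axis=1)
    mean_ctrl = values[:, ctrl_idx].mean(axis=1)
    delta = np.abs(mean_case - mean_ctrl)

    table = pd.DataFrame({
        "parent": [e[0] for e in ecv.edges],
        "child": [e[1] for e in ecv.edges],
        "mean_case": mean_case,
        "mean_control": mean_ctrl,
        "delta": delta,
    }).sort_values(["delta", "parent", "child"], ascending=[False, True, True],
                   kind="mergesort").reset_index(drop=True)
    n_edges = len(table)
    n_sel = min(n_edges, max(int(floor), _round_half_up(q * n_edges)))
    table["rank"] = np.arange(1, n_edges + 1)
    table["selected"] = (table["rank"] <= n_sel).astype(int)
    return DifferentialEdgeSet(table, q, n_sel)


def extract_subnetworks(selected: DifferentialEdgeSet) -> list[Subnetwork]:
    """Weakly connected components of the selected edges (directions kept in
    the membership, ignored for grouping); ordered by size then lexically.
    """
    edges = selected.edges
    if not edges:
        raise ValueError("empty differential edge selection")
    graph = nx.DiGraph(edges)
    deltas = selected.deltas
    comps = []
    for comp in nx.weakly_connected_components(graph):
        genes = tuple(sorted(comp))
        members = tuple(e for e in edges if e[0] in comp)
        comps.append((genes, members))
    comps.sort(key=lambda gc: (-len(gc[0]), gc[0]))
    return [
        Subnetwork(i + 1, genes, members,
                   {e: deltas[e] for e in members})
        for i, (genes, members) in enumerate(comps)
    ]


def subnetwork_stats(subnets: list[Subnetwork], tpm: TPMMatrix,
                     labels: SampleLabels) -> list[Subnetwork]:
    """Complete each subnetwork: minimum |Pearson r| over member-gene TPM
    rows, per-gene folded AUC, and the representative (best-AUC) gene.
    Ties on AUC go to the gene with the larger incident delta, then lexical.
    """
    out = []
    for sn in subnets:
        missing = [g for g in sn.genes if g not in tpm.tpm.index]
        if missing:
            raise KeyError(f"genes missing from TPM matrix: {missing}")
        rows = tpm.tpm.loc[list(sn.genes)].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(rows)
        tri = np.abs(corr[np.triu_indices(len(sn.genes), k=1)])
        tri = tri[np.isfinite(tri)]
        min_r = float(tri.min()) if tri.size else 1.0

        aucs = {}
        for g in sn.genes:
            values = tpm.tpm.loc[g, labels.sample_ids].to_numpy(dtype=float)
            aucs[g] = auc(values, labels).folded
        incident = {g: max((sn.edge_deltas[e] for e in sn.edges if g in e),
                           default=0.0)
                    for g in sn.genes}
        rep = min(sn.genes, key=lambda g: (-aucs[g], -incident[g], g))
        out.append(Subnetwork(sn.component_id, sn.genes, sn.edges,
                              dict(sn.edge_deltas), min_r, aucs, rep,
                              aucs[rep]))
    return out
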