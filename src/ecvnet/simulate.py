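"""Synthetic cohorts from a known directed network with known perturbed edges.

The generator provides ground truth for every downstream stage: a random DAG
over a random topological order, a smooth (cubic-spline) regulatory function
on every edge, and a small set of perturbed edges whose regulation differs
between cases and controls.  Latent gene expression lives on a log2 scale;
observed data are integer read counts with per-sample library sizes and
per-gene length scaling, so the TPM path is exercised end to end.

Two perturbation modes are supported (multiplier m, m=1 means no effect):

``output``
    In case samples the edge transmits ``m * f(x_parent)`` to the child
    (m=0 ablates the edge's output).  The parent's expression is untouched.
``input``
    In case samples the edge's parent gene is knocked down: its expression
    is shifted by ``-(1 - m) * knockdown_depth`` log2 units, changing the
    signal flowing into the edge.  This is the mode whose ground truth
    matches what per-sample edge contribution values can detect, since an
    edge's contribution is a function of its parent's expression.  Input-mode
    perturbations are drawn among edges whose parent has exactly one
    outgoing edge, so the truly differential edge set equals the perturbed
    set rather than spilling onto siblings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from ._splines import BSplineBasis, SplineFunction, greville
from .io_formats import CASE, CONTROL, CountMatrix, SampleLabels

EDGE_INTERIOR_KNOTS = 6     # interior knots of every true edge function
NODE_HALF_WIDTH = 4.0       # spline support = intercept +/- this, log2 units


@dataclass(frozen=True)
class TrueNetwork:
    gene_ids: tuple[str, ...]
    order: tuple[str, ...]                       # a topological order
    edges: tuple[tuple[str, str], ...]
    functions: dict
    intercepts: dict
    noise_sd: dict
    max_parents: int = 3

    def __post_init__(self) -> None:
        g = nx.DiGraph(self.edges)
        g.add_nodes_from(self.gene_ids)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("true network must be acyclic")
        for e in self.edges:
            if e not in self.functions:
                raise ValueError(f"edge {e} has no function")
        indeg = {}
        for _, c in self.edges:
            indeg[c] = indeg.get(c, 0) + 1
        if indeg and max(indeg.values()) > self.max_parents:
            raise ValueError("a node exceeds max_parents")

    def parents_of(self, gene: str) -> list[str]:
        return [p for p, c in self.edges if c == gene]


@dataclass(frozen=True)
class SyntheticTruth:
    network: TrueNetwork
    perturbed_edges: tuple[tuple[str, str], ...]
    effect: float                                 # multiplier; 0 = ablation
    mode: str = "output"
    knockdown_depth: float = 3.0                  # log2 units, input mode
    severity_range: tuple[float, float] = (0.75, 1.25)  # per-sample knockdown scaling
    gene_lengths: pd.Series = field(default=None)
    library_range: tuple[float, float] = (2e5, 5e5)
    overdispersion: float = 0.0

    def __post_init__(self) -> None:
        if self.effect < 0:
            raise ValueError("effect multiplier must be >= 0")
        if self.mode not in {"output", "input"}:
            raise ValueError(f"unknown perturbation mode {self.mode!r}")
        extra = set(self.perturbed_edges) - set(self.network.edges)
        if extra:
            raise ValueError(f"perturbed edges not in the network: {sorted(extra)}")


def _random_edge_function(rng: np.random.Generator, intercept: float,
                          amplitude: float) -> SplineFunction:
    """Random smooth regulation curve: a dominant monotone trend (activation
    or repression, random sign) plus bounded spline wiggle.  Coefficients at
    the Greville abscissae reproduce the linear trend exactly, so the
    monotone component lives inside the spline space."""
    lo, hi = intercept - NODE_HALF_WIDTH, intercept + NODE_HALF_WIDTH
    interior = tuple(np.linspace(lo, hi, EDGE_INTERIOR_KNOTS + 2)[1:-1])
    basis = BSplineBasis(lo, hi, interior)
    slope = rng.choice([-1.0, 1.0]) * rng.uniform(0.25, 0.5) * amplitude
    g = greville(basis)
    wiggle = rng.uniform(-0.25 * amplitude, 0.25 * amplitude, basis.n_basis)
    coef = slope * (g - intercept) + wiggle
    return SplineFunction(basis, tuple(float(v) for v in coef))


def generate_truth(n_genes: int, density: float, n_perturb: int, effect: float,
                   seed: int, *, amplitude: float = 1.0, noise_sd: float = 0.5,
                   max_parents: int = 3, mode: str = "output",
                   knockdown_depth: float = 3.0,
                   length_range: tuple[int, int] = (500, 5000),
                   library_range: tuple[float, float] = (2e5, 5e5),
                   overdispersion: float = 0.0) -> SyntheticTruth:
    """Sample a ground-truth network and its perturbation.

    Edges are Bernoulli(density) over pairs ordered by a random topological
    order; a child keeping more than ``max_parents`` draws has a uniform
    subset of ``max_parents`` retained, so its parent count is
    min(Binomial, max_parents).  Edge functions are random cubic splines
    with coefficients uniform on [-amplitude, amplitude].
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    if not (0 <= density <= 1):
        raise ValueError("density must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    gene_ids = tuple(f"G{i:04d}" for i in range(n_genes))
    order = tuple(gene_ids[i] for i in rng.permutation(n_genes))

    intercepts = {g: float(rng.uniform(4.0, 8.0)) for g in gene_ids}
    edges: list[tuple[str, str]] = []
    for j, child in enumerate(order):
        draws = rng.uniform(size=j) < density
        chosen = [order[i] for i in range(j) if draws[i]]
        if len(chosen) > max_parents:
            keep = rng.choice(len(chosen), size=max_parents, replace=False)
            chosen = [chosen[i] for i in sorted(keep)]
        edges.extend((p, child) for p in chosen)

    functions = {
        (p, c): _random_edge_function(rng, intercepts[p], amplitude)
        for p, c in edges
    }
    network = TrueNetwork(gene_ids, order, tuple(edges), functions, intercepts,
                          {g: float(noise_sd) for g in gene_ids}, max_parents)

    if mode == "input":
        out_degree = {}
        for p, _ in edges:
            out_degree[p] = out_degree.get(p, 0) + 1
        eligible = [e for e in edges if out_degree[e[0]] == 1]
    else:
        eligible = list(edges)
    if n_perturb > len(eligible):
        raise ValueError(
            f"requested {n_perturb} perturbed edges but only {len(eligible)} eligible"
        )
    idx = rng.choice(len(eligible), size=n_perturb, replace=False) if n_perturb else []
    perturbed = tuple(eligible[i] for i in sorted(idx))

    lengths = pd.Series(
        rng.integers(length_range[0], length_range[1] + 1, n_genes).astype(float),
        index=list(gene_ids), name="length",
    )
    return SyntheticTruth(network, perturbed, float(effect), mode,
                          float(knockdown_depth), gene_lengths=lengths,
                          library_range=library_range,
                          overdispersion=float(overdispersion))


def knockdown_scenario(n_genes: int, density: float, n_targets: int, effect: float,
                       seed: int, *, amplitude: float = 0.8,
                       regulator_amplitude: float = 0.8, noise_sd: float = 0.5,
                       regulator_noise_sd: float = 1.0, max_parents: int = 3,
                       knockdown_depth: float = 3.0,
                       severity_range: tuple[float, float] = (0.75, 1.25),
                       **kwargs) -> SyntheticTruth:
    """A single knocked-down regulator disrupting its outgoing edges.

    Builds a random background network over n_genes - 1 genes, then plants
    one additional regulator gene upstream with edges to ``n_targets``
    randomly chosen background genes; in case samples the regulator is
    knocked down (input-mode perturbation with the given effect multiplier).
    This emulates the situation the differential-edge analysis is designed
    to detect: one suppressed gene whose regulatory interactions form the
    perturbed subnetwork.
    """
    if n_targets >= n_genes:
        raise ValueError("need more genes than targets")
    base = generate_truth(n_genes - 1, density, 0, 1.0, seed,
                          amplitude=amplitude, noise_sd=noise_sd,
                          max_parents=max_parents, mode="input",
                          knockdown_depth=knockdown_depth, **kwargs)
    net = base.network
    rng = np.random.default_rng([seed, 17])
    reg = f"G{n_genes - 1:04d}"
    indeg = {g: 0 for g in net.gene_ids}
    outdeg = {g: 0 for g in net.gene_ids}
    for p, c in net.edges:
        indeg[c] += 1
        outdeg[p] += 1
    # effector (sink) targets keep the perturbation confined to the module
    open_targets = [g for g in net.gene_ids
                    if indeg[g] < max_parents and outdeg[g] == 0]
    if len(open_targets) < n_targets:
        raise ValueError("not enough sink genes with spare parent slots")
    idx = rng.choice(len(open_targets), size=n_targets, replace=False)
    targets = [open_targets[i] for i in sorted(idx)]

    intercepts = dict(net.intercepts)
    intercepts[reg] = float(rng.uniform(4.0, 8.0))
    new_edges = tuple((reg, t) for t in targets)
    functions = dict(net.functions)
    for e in new_edges:
        functions[e] = _random_edge_function(rng, intercepts[reg],
                                             regulator_amplitude)
    noise = dict(net.noise_sd)
    noise[reg] = float(regulator_noise_sd)
    network = TrueNetwork(net.gene_ids + (reg,), (reg,) + net.order,
                          net.edges + new_edges, functions, intercepts,
                          noise, max_parents)
    lengths = pd.concat([
        base.gene_lengths,
        pd.Series([float(rng.integers(500, 5001))], index=[reg], name="length"),
    ])
    return SyntheticTruth(network, new_edges, float(effect), "input",
                          float(knockdown_depth), severity_range=severity_range,
                          gene_lengths=lengths, library_range=base.library_range,
                          overdispersion=base.overdispersion)


def latent_expression(truth: SyntheticTruth, n_case: int, n_control: int,
                      rng: np.random.Generator) -> tuple[pd.DataFrame, SampleLabels]:
    """Latent log2 expression, genes x samples, cases first."""
    net = truth.network
    n = n_case + n_control
    sample_ids = [f"case{i + 1:02d}" for i in range(n_case)] + \
                 [f"ctrl{i + 1:02d}" for i in range(n_control)]
    is_case = np.array([1] * n_case + [0] * n_control, dtype=bool)

    kd_shift = {}
    if truth.mode == "input":
        for p, _ in truth.perturbed_edges:
            kd_shift[p] = -(1.0 - truth.effect) * truth.knockdown_depth

    x = {}
    for child in net.order:
        vals = np.full(n, net.intercepts[child])
        for parent in net.parents_of(child):
            contrib = net.functions[(parent, child)](x[parent])
            if truth.mode == "output" and (parent, child) in truth.perturbed_edges:
                mult = np.where(is_case, truth.effect, 1.0)
                contrib = contrib * mult
            vals = vals + contrib
        if child in kd_shift:
            # knockdown severity varies per sample (patients differ), so
            # co-knocked genes are not collinear through the group label
            severity = rng.uniform(*truth.severity_range, n)
            vals = vals + np.where(is_case, kd_shift[child] * severity, 0.0)
        sd = net.noise_sd[child]
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, n)
        x[child] = vals

    frame = pd.DataFrame({s: [x[g][i] for g in net.gene_ids]
                          for i, s in enumerate(sample_ids)},
                         index=list(net.gene_ids))
    labels = SampleLabels(pd.Series([CASE] * n_case + [CONTROL] * n_control,
                                    index=sample_ids, name="group"))
    return frame, labels


def simulate_counts(truth: SyntheticTruth, n_case: int, n_control: int, seed: int,
                    *, return_latent: bool = False):
    """Integer read counts for a two-group cohort.

    Latent log2 expression maps to transcript abundance 2**x; the expected
    fragment share of a gene is proportional to abundance times length (kb);
    counts are Poisson draws at a per-sample library size uniform on the
    truth's library range (negative-binomial via the optional
    overdispersion).
    """
    if n_case < 1 or n_control < 1:
        raise ValueError("both group sizes must be positive")
    rng = np.random.default_rng(seed)
    lib = rng.uniform(*truth.library_range, n_case + n_control)
    latent, labels = latent_expression(truth, n_case, n_control, rng)

    abundance = np.exp2(latent.to_numpy())
    kb = truth.gene_lengths.reindex(latent.index).to_numpy() / 1e3
    share = abundance * kb[:, None]
    share = share / share.sum(axis=0, keepdims=True)
    lam = share * lib[None, :]
    if truth.overdispersion > 0:
        od = truth.overdispersion
        lam = lam * rng.gamma(1.0 / od, od, size=lam.shape)
    counts = rng.poisson(lam)

    matrix = CountMatrix(
        pd.DataFrame(counts, index=latent.index, columns=latent.columns),
        truth.gene_lengths,
    )
    if return_latent:
        return matrix, labels, latent
    return matrix, labels


def oracle_ecv(truth: SyntheticTruth, latent_sample: pd.Series,
               edge: tuple[str, str], group: str = CONTROL) -> float:
    """True contribution of ``edge`` for one sample, by direct basis expansion.

    Deliberately bypasses the pipeline's evaluation code: the stored knot
    vector and coefficients are handed to scipy's BSpline, with linear
    continuation beyond the boundary knots.  The output-mode multiplier is
    applied for case samples (an ablated edge contributes exactly 0); in
    input mode the knockdown already lives in the latent values.
    """
    if edge not in truth.network.functions:
        raise KeyError(f"unknown edge {edge}")
    fn = truth.network.functions[edge]
    x = float(latent_sample[edge[0]])
    spl = BSpline(fn.basis.knots, np.asarray(fn.coef), 3, extrapolate=True)
    xc = min(max(x, fn.basis.lo), fn.basis.hi)
    value = float(spl(xc)) + (x - xc) * float(spl.derivative()(xc))
    if (truth.mode == "output" and group == CASE
            and edge in truth.perturbed_edges):
        value *= truth.effect
    return value


def save_truth(truth: SyntheticTruth, path) -> None:
    """Ground-truth summary (edges, perturbed set, effect) as JSON."""
    payload = {
        "gene_ids": list(truth.network.gene_ids),
        "edges": [list(e) for e in truth.network.edges],
        "perturbed_edges": [list(e) for e in truth.perturbed_edges],
        "effect": truth.effect,
        "mode": truth.mode,
        "knockdown_depth": truth.knockdown_depth,
        "intercepts": truth.network.intercepts,
        "noise_sd": truth.network.noise_sd,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
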