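"""Marker evaluation and model selection for case/control discrimination.

Covers the discrimination toolbox applied to the subnetwork representatives:
pair-counting AUC with direction folding, a Youden-J optimal cutoff on the
TPM scale, bidirectional stepwise logistic regression under AIC, an
interaction screen (an interaction is worth keeping only if it improves AIC
by more than 1), a small Gini classification tree used for variable
selection, and leave-one-out cross-validation with a bagged-tree ensemble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

from .io_formats import CASE, SampleLabels, TPMMatrix

RIDGE = 1e-6  # separation fallback penalty on logistic coefficients


class AucResult(NamedTuple):
    raw: float
    folded: float


@dataclass(frozen=True)
class RocResult:
    gene_id: str
    raw_auc: float
    folded_auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str  # case-low | case-high


@dataclass
class DiscriminationReport:
    candidate_genes: tuple[str, ...]
    roc: list[RocResult]
    stepwise_selected: tuple[str, ...]
    stepwise_aic: float
    stepwise_trace: list[dict]
    tree_genes: tuple[str, ...]
    interaction_base: str | None
    interaction_table: list[dict]
    loocv_sensitivity: float
    loocv_specificity: float
    loocv_confusion: dict
    loocv_features: tuple[str, ...]
    ensemble_size: int
    seed: int
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidate_genes": list(self.candidate_genes),
            "roc": [vars(r) for r in self.roc],
            "stepwise_selected": list(self.stepwise_selected),
            "stepwise_aic": self.stepwise_aic,
            "stepwise_trace": self.stepwise_trace,
            "tree_genes": list(self.tree_genes),
            "interaction_base": self.interaction_base,
            "interaction_table": self.interaction_table,
            "loocv": {
                "sensitivity": self.loocv_sensitivity,
                "specificity": self.loocv_specificity,
                "confusion": self.loocv_confusion,
                "features": list(self.loocv_features),
                "ensemble_size": self.ensemble_size,
                "seed": self.seed,
            },
            "warnings": self.warnings,
        }


# ---------------------------------------------------------------------------
# AUC and cutoff
# ---------------------------------------------------------------------------

def _split(values, labels: SampleLabels) -> tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    if values.size != len(labels.sample_ids):
        raise ValueError("values and labels differ in length")
    mask = (labels.group == CASE).to_numpy()
    return values[mask], values[~mask]


def auc(values, labels: SampleLabels) -> AucResult:
    """Pair-counting AUC: (wins + 0.5 ties) / (n_case * n_control), where a
    win is a case value exceeding a control value.  Computed through
    midranks (the Mann-Whitney identity); folded = max(raw, 1 - raw).
    """
    case, ctrl = _split(values, labels)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([case, ctrl])
    ranks = pd.Series(pooled).rank(method="average").to_numpy()
    u = ranks[: case.size].sum() - case.size * (case.size + 1) / 2.0
    raw = float(u / (case.size * ctrl.size))
    return AucResult(raw, max(raw, 1.0 - raw))


def best_cutoff(values, labels: SampleLabels, gene_id: str = "") -> RocResult:
    """Cutoff maximizing Youden J over midpoints of adjacent unique values.

    Direction (case-low vs case-high) follows the folded AUC; J ties go to
    the smallest cutoff.
    """
    case, ctrl = _split(values, labels)
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("both groups must be non-empty")
    res = auc(values, labels)
    case_high = res.raw >= 0.5
    uniq = np.unique(np.concatenate([case, ctrl]))
    if uniq.size == 1:
        mids = np.array([uniq[0]])
    else:
        mids = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for t in mids:
        if case_high:
            sens = float((case > t).mean())
            spec = float((ctrl <= t).mean())
        else:
            sens = float((case < t).mean())
            spec = float((ctrl >= t).mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(t), sens, spec)
    _, cutoff, sens, spec = best
    return RocResult(gene_id, res.raw, res.folded, cutoff, sens, spec,
                     "case-high" if case_high else "case-low")


# ---------------------------------------------------------------------------
# logistic regression with AIC
# ---------------------------------------------------------------------------

def _ridge_logistic(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Damped Newton for the ridge-penalized logistic log-likelihood.

    The tiny penalty keeps the optimum finite under separation; backtracking
    guards against overshoot in the flat tails."""

    def objective(beta):
        return -_loglik(design, y, beta) + 0.5 * RIDGE * beta @ beta

    beta = np.zeros(design.shape[1])
    obj = objective(beta)
    for _ in range(500):
        eta = np.clip(design @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(p * (1 - p), 1e-10)
        grad = design.T @ (y - p) - RIDGE * beta
        if np.max(np.abs(grad)) < 1e-8:
            return beta
        hess = (design * w[:, None]).T @ design + RIDGE * np.eye(design.shape[1])
        step = np.linalg.solve(hess, grad)
        scale = 1.0
        for _ in range(40):
            trial = beta + scale * step
            trial_obj = objective(trial)
            if trial_obj <= obj + 1e-14:
                break
            scale *= 0.5
        if abs(obj - trial_obj) < 1e-12 and np.max(np.abs(scale * step)) < 1e-8:
            return trial
        beta, obj = trial, trial_obj
    raise RuntimeError("ridge-penalized logistic regression did not converge")


def _loglik(design: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(design @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(y @ np.log(p) + (1 - y) @ np.log(1 - p))


def logistic_aic(features: np.ndarray, y: np.ndarray) -> float:
    """AIC = -2 log L + 2k of a logistic fit with intercept.

    Separation (diverging coefficients or a failed maximum-likelihood fit)
    falls back to a small ridge penalty; the reported log-likelihood is the
    unpenalized one at the stabilized coefficients.
    """
    features = np.asarray(features, dtype=float)
    if features.ndim == 1:
        features = features[:, None]
    if features.shape[1]:
        design = np.column_stack([np.ones(len(y)), features])
    else:
        design = np.ones((len(y), 1))
    k = design.shape[1]
    beta = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
            if fit.mle_retvals.get("converged", False) and np.max(np.abs(fit.params)) < 15:
                beta = np.asarray(fit.params)
        except Exception:
            beta = None
    if beta is None:
        warnings.warn("separation detected; ridge-stabilized logistic fit",
                      stacklevel=2)
        beta = _ridge_logistic(design, y)
    return -2.0 * _loglik(design, y, beta) + 2.0 * k


def _feature_frame(genes, tpm: TPMMatrix, labels: SampleLabels) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene z-scored TPM (samples x genes) and the 0/1 outcome."""
    x = tpm.tpm.loc[list(genes), labels.sample_ids].to_numpy(dtype=float).T
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    x = (x - x.mean(axis=0)) / sd
    y = (labels.group.to_numpy() == CASE).astype(float)
    return x, y


def stepwise_logistic_aic(candidates, tpm: TPMMatrix, labels: SampleLabels
                          ) -> tuple[tuple[str, ...], float, list[dict]]:
    """Bidirectional stepwise selection from the intercept-only model.

    At each step the single best add/remove move is taken while it strictly
    decreases AIC.  Returns (selected genes, final AIC, trace).
    """
    candidates = list(candidates)
    if len(candidates) > 15:
        raise ValueError("stepwise selection limited to 15 candidates")
    if labels.n_case < 3 or labels.n_control < 3:
        raise ValueError("need at least 3 samples per group")
    x, y = _feature_frame(candidates, tpm, labels)
    cols = {g: x[:, i] for i, g in enumerate(candidates)}

    def fit_aic(genes: tuple[str, ...]) -> float:
        feats = (np.column_stack([cols[g] for g in genes])
                 if genes else np.empty((len(y), 0)))
        return logistic_aic(feats, y)

    current: tuple[str, ...] = ()
    current_aic = fit_aic(current)
    trace = [{"action": "start", "gene": None, "aic": current_aic}]
    while True:
        moves = []
        for g in candidates:
            if g in current:
                moves.append(("remove", g, tuple(h for h in current if h != g)))
            else:
                moves.append(("add", g, tuple(sorted(current + (g,)))))
        scored = [(fit_aic(subset), action, g, subset)
                  for action, g, subset in moves]
        scored.sort(key=lambda t: (t[0], t[1], t[2]))
        best_aic, action, gene, subset = scored[0]
        if best_aic < current_aic - 1e-9:
            current, current_aic = subset, best_aic
            trace.append({"action": action, "gene": gene, "aic": best_aic})
        else:
            break
    return current, current_aic, trace


def interaction_scan(base: str, others, tpm: TPMMatrix, labels: SampleLabels
                     ) -> list[dict]:
    """For each other gene g, compare AIC of (intercept + base) against
    (intercept + base + base*g product term); retained iff the drop
    exceeds 1.
    """
    others = list(others)
    if base in others:
        raise ValueError("base gene cannot appear among the others")
    x, y = _feature_frame([base] + others, tpm, labels)
    zbase = x[:, 0]
    aic_base = logistic_aic(zbase[:, None], y)
    table = []
    for i, g in enumerate(others, start=1):
        inter = zbase * x[:, i]
        aic_int = logistic_aic(np.column_stack([zbase, inter]), y)
        delta = aic_base - aic_int
        table.append({"gene": g, "aic_base": aic_base, "aic_interaction": aic_int,
                      "delta_aic": delta, "retained": bool(delta > 1.0)})
    return table


# ---------------------------------------------------------------------------
# classification tree
# ---------------------------------------------------------------------------

def _gini(y: np.ndarray) -> float:
    if y.size == 0:
        return 0.0
    p = y.mean()
    return 2.0 * p * (1.0 - p)


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Exhaustive threshold scan; tie-break lower feature index then smaller
    threshold.  Returns (impurity, feature, threshold) or None."""
    best = None
    for j in range(x.shape[1]):
        uniq = np.unique(x[:, j])
        if uniq.size < 2:
            continue
        for t in (uniq[:-1] + uniq[1:]) / 2.0:
            left = x[:, j] <= t
            n_l, n_r = left.sum(), (~left).sum()
            if n_l < min_leaf or n_r < min_leaf:
                continue
            imp = (n_l * _gini(y[left]) + n_r * _gini(y[~left])) / y.size
            if best is None or imp < best[0] - 1e-12:
                best = (imp, j, float(t))
    return best


def _grow(x, y, depth, max_depth, min_leaf, used: set):
    node = {"n": int(y.size), "prediction": int(round(float(y.mean())))}
    if depth >= max_depth or y.size < 2 * min_leaf or _gini(y) == 0.0:
        return node
    split = _best_split(x, y, min_leaf)
    if split is None or split[0] >= _gini(y) - 1e-12:
        return node
    _, j, t = split
    used.add(j)
    left = x[:, j] <= t
    node.update({
        "feature": j, "threshold": t,
        "left": _grow(x[left], y[left], depth + 1, max_depth, min_leaf, used),
        "right": _grow(x[~left], y[~left], depth + 1, max_depth, min_leaf, used),
    })
    return node


def fit_tree(candidates, tpm: TPMMatrix, labels: SampleLabels,
             max_depth: int = 3, min_leaf: int = 2) -> tuple[dict, tuple[str, ...]]:
    """Greedy Gini CART on raw TPM values; returns (tree, genes used in splits)."""
    candidates = list(candidates)
    x = tpm.tpm.loc[candidates, labels.sample_ids].to_numpy(dtype=float).T
    y = (labels.group.to_numpy() == CASE).astype(float)
    used: set = set()
    tree = _grow(x, y, 0, max_depth, min_leaf, used)

    def relabel(node):
        if "feature" in node:
            node["gene"] = candidates[node["feature"]]
            relabel(node["left"])
            relabel(node["right"])
    relabel(tree)
    return tree, tuple(sorted(candidates[j] for j in used))


# ---------------------------------------------------------------------------
# LOOCV with a bagged-tree ensemble
# ---------------------------------------------------------------------------

def loocv_ensemble(feature_genes, tpm: TPMMatrix, labels: SampleLabels,
                   ensemble_size: int = 500, seed: int = 0
                   ) -> tuple[float, float, dict]:
    """Leave-one-out CV of a bagged depth-limited tree ensemble.

    Each held-out sample is predicted by majority vote of an ensemble
    trained on the rest (bootstrap rows, random feature subset per split
    when more than one feature); predictions are pooled into sensitivity
    (case = positive) and specificity.  Fully seeded and deterministic.
    """
    feature_genes = list(feature_genes)
    x = tpm.tpm.loc[feature_genes, labels.sample_ids].to_numpy(dtype=float).T
    y = (labels.group.to_numpy() == CASE).astype(int)
    n = len(y)
    if n < 4 or labels.n_case < 2 or labels.n_control < 2:
        raise ValueError("need n >= 4 with >= 2 samples per group")
    fold_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, n)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        y_tr = y[mask]
        if y_tr.min() == y_tr.max():
            warnings.warn("degenerate training fold (one class); majority vote",
                          stacklevel=2)
            preds[i] = int(y_tr[0])
            continue
        forest = RandomForestClassifier(
            n_estimators=ensemble_size, max_depth=3, min_samples_leaf=2,
            max_features=1 if len(feature_genes) == 1 else "sqrt",
            bootstrap=True, random_state=int(fold_seeds[i]),
        )
        forest.fit(x[mask], y_tr)
        preds[i] = int(forest.predict(x[i:i + 1])[0])
    tp = int(((preds == 1) & (y == 1)).sum())
    fn = int(((preds == 0) & (y == 1)).sum())
    tn = int(((preds == 0) & (y == 0)).sum())
    fp = int(((preds == 1) & (y == 0)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, {"tp": tp, "fn": fn, "tn": tn, "fp": fp}


# ---------------------------------------------------------------------------
# assembled marker evaluation
# ---------------------------------------------------------------------------

def evaluate_markers(candidates, tpm: TPMMatrix, labels: SampleLabels,
                     ensemble_size: int = 500, seed: int = 0,
                     loocv_all: bool = False) -> DiscriminationReport:
    """Run the full discrimination battery on the candidate (representative)
    genes: per-gene ROC, stepwise-AIC logistic selection, tree selection,
    interaction screen anchored on the best marker, and LOOCV (on the single
    best marker by default, mirroring a one-gene final model).
    """
    candidates = tuple(candidates)
    roc = [best_cutoff(tpm.tpm.loc[g, labels.sample_ids].to_numpy(dtype=float),
                       labels, g) for g in candidates]
    selected, final_aic, trace = stepwise_logistic_aic(candidates, tpm, labels)
    _, tree_genes = fit_tree(candidates, tpm, labels)
    by_auc = max(roc, key=lambda r: (r.folded_auc, -candidates.index(r.gene_id)))
    base = selected[0] if len(selected) == 1 else by_auc.gene_id
    others = [g for g in candidates if g != base]
    interactions = interaction_scan(base, others, tpm, labels) if others else []
    features = candidates if loocv_all else (base,)
    sens, spec, confusion = loocv_ensemble(features, tpm, labels,
                                           ensemble_size, seed)
    return DiscriminationReport(
        candidates, roc, selected, final_aic, trace, tree_genes, base,
        interactions, sens, spec, confusion, features, ensemble_size, seed,
    )
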