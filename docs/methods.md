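# Methods

`ecvnet` implements a differential gene-network analysis for small
two-group bulk RNA-Seq cohorts (on the order of 10 samples per group).
The premise: when a disease perturbs *how* genes regulate each other
rather than only *how much* each gene is expressed, a per-sample score of
each regulatory edge's activity can expose group differences that a
marginal per-gene test underpowers away.  The pipeline is

1. TPM normalization of a count matrix,
2. estimation of one directed "basal" network from all samples pooled,
3. per-sample, per-edge **edge contribution values (ECv)**,
4. selection of edges whose group-averaged ECv differs most,
5. grouping of those edges into subnetworks and selection of a
   representative marker gene per subnetwork,
6. evaluation of the markers (AUC, optimal cutoff, stepwise-AIC logistic
   selection, classification tree, leave-one-out cross-validation).

## Normalization and input scale

TPM for gene g in a sample is `rate_g / Σ_h rate_h × 1e6` with
`rate_g = count_g / length_g(kb)`; columns sum to 1e6 by construction
(checked to 1e-9 relative; externally loaded matrices are admitted at
1e-3 because deposited tables are often rounded).  Network fitting uses
**standardized log2(TPM+1)** per gene: spline regressors on raw TPM,
which spans five orders of magnitude, are numerically fragile, and
standardization puts all genes on one footing for a penalized Gaussian
score.  Raw-scale fitting remains available (`standardize=False`).
Genes with total count ≤ 6 (the same floor the volcano comparison uses)
and constant genes are excluded from network estimation.

## Basal network model

Each gene is modelled as

    x_child = μ + Σ_parents f_parent(x_parent) + ε,   ε ~ N(0, σ²),

with every `f` a cubic B-spline on the observed parent range
(`spline_df` free coefficients, default 4, i.e. one interior knot at the
median; linear continuation beyond the boundary knots so evaluation is
defined on the whole real line).  Contributions are centered to zero
training mean; the mean lives in the intercept.  Spline coefficients
carry a mild ridge penalty (`ridge`, default 1.0 on standardized data) —
without it, two correlated parents can receive huge mutually-canceling
contributions and the per-edge decomposition that ECv relies on becomes
meaningless.  The penalty plays the role of the coefficient prior in
Bayesian nonparametric-regression network estimators.

Structure is scored by BIC: `-2 log L + log(n) · k` per node, with `k`
counting intercept, spline coefficients and variance; the network score
is the sum over nodes, so each move is scored by refitting one node.
Search is greedy hill climbing over add / delete / reverse / **swap**
moves (swap replaces one parent with a candidate; without it, children
whose `max_parents` slots fill early can never recover the true parent).
Moves are restricted to each gene's top-k |Spearman| candidate parents
(`candidate_parents_k`, default 10) and enumerated in a fixed lexical
order with first-improvement acceptance.  The first restart climbs from
the empty graph; further restarts (default 3 total) climb from a *fixed*
portfolio of pseudo-random initial structures.  The estimate is therefore
a deterministic function of (data, config): re-estimating under different
seeds must return the identical structure, which `check_reproducibility`
verifies (it would catch any nondeterminism, e.g. unordered iteration).
Greedy search with seed-dependent randomization was rejected because
near-tied orientation optima made independent runs disagree on about half
of strong-signal datasets — determinism is the stronger form of the
reproducibility property this analysis depends on.

## Edge contribution values and differential edges

For edge u→v and sample s,

    ECv(u→v; s) = f̂_{u→v}(x_u(s)),

the fitted centered smoother evaluated at s's (standardized log) level of
u — a per-sample measure of the signal flowing through the edge.  Per
edge, group means of the signed ECv are taken (an |ECv|-first convention
is available via `ecv_absolute`) and edges are ranked by
Δ = |mean_case − mean_control|.  The top `max(floor, round(q·E))` edges
are selected (q = `top_fraction`, default 1e-5, the "top 0.001%" rule;
the floor of 1 keeps small synthetic networks from returning an empty
selection — a regime the original million-edge setting never meets).
Ties break lexically by (parent, child), so selection is deterministic.
Weakly connected components of the selected edges form the subnetworks,
ordered by size then gene names.  Each subnetwork reports the minimum
|Pearson r| between member genes' TPM rows and a representative gene: the
member with the highest direction-folded AUC, `max(AUC, 1−AUC)`, so
markers suppressed in cases score the same as markers elevated in cases.

Because ECv of an edge depends only on its parent's expression, what this
statistic detects is a between-group change in the *input* of an edge.
A regulatory disruption is visible exactly insofar as it shifts the
expression feeding the fitted functions — a point that drives the design
of the synthetic ground truth below.

## Marker evaluation

- **AUC** by the Mann–Whitney midrank identity (= exhaustive pair
  counting with ties at ½), on raw TPM; AUC is invariant to the monotone
  log transform, and cutoffs are reported on the TPM scale.
- **Best cutoff**: Youden J maximized over midpoints of adjacent unique
  values; ties take the smallest cutoff; direction follows the folded AUC.
- **Stepwise logistic selection**: bidirectional from the intercept-only
  model, one best add/remove per step while AIC strictly decreases.
  Features are per-gene z-scores (AIC is invariant to affine feature
  maps).  Separation — frequent in leave-one-out folds of n = 20 — falls
  back to a damped-Newton fit with ridge 1e-6; the reported likelihood is
  the unpenalized one at the stabilized coefficients.  Note that AIC
  stepwise *overselects under the null by design* (per-candidate
  false-inclusion ≈ P(χ²₁ > 2) ≈ 0.16); the null tests assert exactly
  that per-candidate rate, not a fictitious zero rate.
- **Classification tree**: greedy Gini CART, depth ≤ 3, minimum leaf 2,
  exhaustive threshold scan, deterministic tie-breaks (lower gene index,
  then smaller threshold); used for variable selection only.
- **Interaction screen**: for each other gene g, AIC of
  (intercept + base) versus (intercept + base + base·g); the interaction
  is retained only if AIC improves by more than 1.
- **LOOCV**: each held-out sample predicted by majority vote of a bagged
  ensemble of depth-3 trees (`ensemble_size`, default 500; random feature
  subsets per split when more than one feature; scikit-learn's random
  forest, fully seeded).  By default only the single best representative
  is used, matching a one-gene final model; `loocv_all_representatives`
  switches to all of them.

## Synthetic ground truth

The generator produces a random DAG over a random topological order
(Bernoulli(density) edges, parent count capped at `max_parents` by
uniform thinning, so a child's in-degree is min(Binomial, cap)); latent
log2 expression propagates through random smooth regulation curves (a
dominant monotone trend of random sign plus bounded spline wiggle — pure
wiggle is not a plausible regulation curve and can transmit nothing over
a biologically meaningful input range); counts are Poisson draws with
per-sample library sizes (uniform on 2–5 × 10⁵) and per-gene length
scaling, with optional Gamma overdispersion.  Defaults: intercepts
uniform on 4–8 log2 units, noise sd 0.5, gene lengths 0.5–5 kb.

Perturbations carry a multiplier m (m = 1: groups exchangeable; this
null is verified by rank-sum calibration tests).  Two modes:

- `output` (per-edge): case samples receive `m · f(x_parent)` — the
  edge's output is scaled, m = 0 ablates it.  The parent's expression is
  untouched, so the *fitted* ECv of that edge cannot see the change;
  this mode exists for truth-level oracles and null checks.
- `input` (knockdown): the edge's parent gene is knocked down in cases by
  `(1−m)·knockdown_depth` log2 units (default 3, an 8-fold suppression),
  scaled per patient by a severity factor uniform on 0.75–1.25 —
  patients differ, and perfectly collinear co-knockdowns would be
  statistically degenerate.  This changes the signal flowing through the
  edge, which is precisely what ECv measures.

`knockdown_scenario` builds the reference recovery condition: one planted
regulator (intrinsic noise sd 1.0, making it the statistically
identifiable hub of its module) knocked down in cases, its edges pointing
at sink ("effector") genes so the truly differential edge set is exactly
the planted set rather than cascading downstream.  The frozen benchmark
(30 genes, background density 0.06 and amplitude 0.8, regulator amplitude
0.8, 5 ablated edges, 30+30 samples) is defined in
`ecvnet.benchmarks`; recovery is scored as recall of the planted edges
among the top-5 Δ-ranks, matching unordered gene pairs because edge
orientation is weakly identified at these sample sizes.

What the generator does **not** emulate: batch effects, library-prep
biases, cell-type composition shifts, overdispersion beyond a single
Gamma knob, and co-regulation that is not mediated by the modelled DAG.
Passing the recovery benchmarks therefore shows the machinery is correct
and well-calibrated under its own assumptions — not that real whole-blood
cohorts of this size will yield stable networks.

## Benchmark problem sizes

The reference conditions are chosen to be informative at interactive run
times: structure recovery uses 30-gene / ~40-edge truths with amplitude
2.0 and noise 0.3 at n = 200 pooled samples (mean skeleton F1 ≈ 0.8 over
seeds 1–5); differential-edge recovery uses the knockdown scenario at
30+30 samples over ten seeds (mean top-5 recall ≈ 0.8); the
stepwise-versus-exhaustive check enumerates all 2⁹ subsets on 50 datasets
built from orthogonalized features, where greedy selection provably
suffices — on adversarially correlated noise, single-move stepwise is
known to differ from best-subset search, which is a property of the
algorithm, not a defect.

## Degenerate inputs and numerical choices

All-zero sample columns are rejected at TPM time; constant genes are
dropped with a warning before standardization and search; an edgeless
learned network short-circuits to an empty selection and a null
classification report; node designs are kept overdetermined (a parent is
not added when the column count would reach n−1); residual variances are
floored at 1e-12; one-class LOOCV training folds predict the majority
class with a warning.  All tabular output is tab-separated with fixed
float formats, and every artifact is a deterministic function of
(inputs, config, seed) — reruns are byte-identical.

## Known limitations

With ~20 samples the basal network is necessarily tiny and orientation
is often arbitrary; the top-0.001% rule then degenerates to the floor-1
selection.  ECv cannot detect a regulatory change that leaves the
parent's expression distribution untouched (see the `output` mode
discussion above).  The variable-selection and evaluation steps reuse
the same cohort, so LOOCV estimates are optimistic — the honest remedy,
an independent validation cohort, is outside what a 20-sample study can
provide.
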