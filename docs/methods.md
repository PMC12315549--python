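# Methods

## Model

The classifier composes three stages over a protein–protein interaction
(PPI) network and a functional partition of the assayed proteins.

**Propagation.** With X the p × n scaled expression matrix, W the symmetric
nonnegative adjacency, D its degree diagonal, and
L = I − D^(−1/2) W D^(−1/2) the normalized Laplacian, the propagated signal
H minimizes

    Tr(HᵀLH) + Tr((H − X)ᵀ Φ (H − X)),    Φ = Diag(φ), φ > 0,

whose unique minimizer is H = (Φ + L)^(−1) Φ X. The smoothness term pulls
interacting proteins together; the steadiness term anchors each protein to
its own measurement, with per-protein trade-off weights φ learned from data.
L is positive semi-definite and φ strictly positive, so Φ + L is symmetric
positive definite; the solve is a Cholesky factorization, reused within a
training iteration for the forward pass and the φ-gradient. Zero-degree
proteins (assayed but absent from the edge list) take 0^(−1/2) := 0, giving
them an identity Laplacian row: they receive no smoothing, only
Φ-anchoring, and every assayed biomarker stays in the model. Self-loops are
zeroed on ingestion because they would silently change D.

**Aggregation.** Z_k = Σ_{i∈C_k} Λ_k^(i) H^(i) with Λ_k = softmax(λ_k)
(max-shifted for numerical stability). Each cluster effect is a convex
combination of its members; the trained Λ_k is the model-driven importance
ranking of proteins within their functional group.

**Prediction.** P_s = σ(Θ_sᵀ Z) per subtype s ∈ {Aβ, MTA, WMH}, with no
intercept (kept exactly as the model is defined). Probabilities are clipped
to [1e−12, 1 − 1e−12] before logs, since the cross-entropy is undefined at
0 and 1.

**Objective.** Σ_s BCE(P_s, Y_s) + δ·R with
R = ‖φ‖² + ‖λ‖² + Σ_s ‖Θ_s‖². In ablation variants R sums only the blocks
the variant actually trains.

## Gradients

All gradients are hand-derived and validated against central finite
differences of the full objective; that numerical agreement is the binding
contract. Two derivations deserve note:

* The backprop weight from Z_k onto member row i of H is the softmax weight
  Λ_k^(i) — the raw λ_k^(i) does not satisfy the chain rule through the
  convex combination.
* With A = Φ + L and upstream gradient G = ∂L/∂H, the φ-gradient is
  rowsum((A^(−1)G) ⊙ (X − H)) + 2δφ, using
  dH/dφ_i = A^(−1) E_ii (X − H) and the simplification
  A^(−1){I − A^(−1)Φ}X = A^(−1)(X − H). The superficially similar ordering
  G ⊙ [A^(−1)(X − H)] differs entrywise for general A and does not pass the
  finite-difference check.

## Training

Block-coordinate descent per iteration: all three Θ heads (cheapest; heads
are independent given Z), then all λ_k jointly, then φ (costliest; each
trial step refactorizes Φ + L). Each block uses backtracking halving — a
step is accepted only if the objective does not increase — so the objective
trace is monotone non-increasing by construction. φ is projected to
≥ φ_floor (default 1e−4) after each step; the projected candidate is what
the line search evaluates, so monotonicity survives the projection.

Step sizes are per-block and adaptive: the base rate (default 0.5) grows by
1.3× after a first-try acceptance (capped at 10³× base) and keeps the halved
value after a backtrack (floored at 10⁻⁸× base). A small fixed step makes
the λ and φ blocks crawl — the model first fits the prevalence through Θ and
only much later differentiates proteins — whereas adaptive steps converge in
a few hundred iterations with the monotonicity guarantee intact.

Initialization: λ_k = 1/|C_k| per element (uniform importances), Θ = 0
(all predictions 0.5), φ = 1. Defaults: δ = 1e−3, max 2000 iterations, stop
when the relative objective change drops below 1e−7. Training refuses
single-class subtypes by name.

## Biomarker clustering

Distances between proteins are Jaccard dissimilarities between their binary
GO-group annotation vectors (rows of the incidence matrix). Agglomeration
uses the Lance–Williams Ward update applied directly to these
dissimilarities — Ward's criterion formally assumes squared-Euclidean
geometry, so this is the common "library semantics" extension, and merge
heights can occasionally invert. Flat clusters are therefore defined by
merge index (all merges up to the cut applied in order). The partition is
the lowest cut at which every cluster has ≥ 2 members; candidate cuts sit
between runs of equal heights, which are applied atomically so "lowest" is
well defined under ties. Equal-distance merge candidates are broken toward
the lexicographically smallest node pair, making the dendrogram
deterministic across platforms; note that under tied input distances any
Ward implementation's output is tie-break-dependent, so cross-library
comparisons are only meaningful on tie-free instances. Cosine, Euclidean
and Manhattan metrics are available for sensitivity analyses.

The upstream DAVID-style functional annotation is an input, not a
computation: the package consumes the protein × GO-group incidence matrix
(or a precomputed GMT). For the record, the study-style grouping used
similarity term overlap 3 and similarity threshold 1, with final group
membership ≥ 2.

## Preprocessing

Order: missing-rate filter → kNN imputation → differential expression on
the (log-scale) imputed values → z-score + logistic scaling. Proteins with
missing fraction strictly above 10% are dropped. Imputation replaces a
missing cell by the mean of that sample's values over the k = 5 nearest
protein rows, with plain Euclidean distance over co-observed entries and
only proteins observed at the target sample as candidates — co-expression
is the informative axis when proteins are far outnumbered by samples.
Scaling maps each protein row through z = (v − mean)/SD (n−1 denominator)
then σ(z) into (0, 1); a provenance flag prevents accidental double
scaling.

Differential expression is a deliberately simple stand-in for moderated-t
pipelines: Welch's two-sample t per protein per subtype, two-sided p,
Benjamini–Hochberg within subtype, selection at adjusted p < 0.05 (both
configurable), biomarkers as the union over subtypes. Without empirical-
Bayes variance moderation, calls near the significance boundary can differ
from a limma-style analysis; this is a documented divergence, not a target
of equivalence.

## Evaluation

AUROC is the Mann–Whitney statistic (ties credited 0.5), computed by the
rank-sum identity and checked against exhaustive pair counting.
Sensitivity/specificity/PPV/NPV (plus accuracy as a provisional sixth
metric) are evaluated at threshold 0.5 — the logistic decision boundary —
with zero-denominator ratios reported as missing, never as 0. Risk-bin odds
ratios use equal-width deciles ([0.9, 1.0] closed), the lowest occupied bin
as reference, and the Haldane–Anscombe 0.5 correction whenever a 2×2 cell
is zero.

The protocol fits on the 4/5 training portion of each discovery fold and
scores the fixed validation cohort, giving n_repeats × n_folds prediction
vectors (100 at the default 20 × 5). Folds stratify on the joint 8-way
label combination when every combination has ≥ n_folds members, else on the
rarest single subtype; summary statistics are mean ± 1.96·SD/√N across the
repeated predictions. Ablations: AM1 freezes Λ uniform, AM2 removes
aggregation (p-dimensional heads on H), AM3 removes propagation (H := X),
AM4 removes both; all share the training loop and protocol.

## Synthetic cohorts

The generator emulates the study conditions (defaults: 127 proteins, 475
participants, 16 clusters, subtype prevalences 0.30/0.22/0.36) from the
model's own generative assumptions:

* **Network:** stochastic-block adjacency aligned with the ground-truth
  clusters (within/between edge probabilities 0.6/0.05, weights
  U(0.5, 1.0)).
* **Annotation:** each cluster's proteins share 3 dedicated GO-group
  columns; optional cross-cluster overlap columns.
* **Expression:** three correlated (r = 0.3) latent pathology axes, each
  bimodal (a mixture with separation 4 SD — amyloid burden is famously
  bimodal in elderly cohorts). Every cluster loads on the axes through a
  shared severity direction with a ±1 sign per cluster; each deviating
  subtype flips one cluster's sign, so the three subtype signals are
  strong, near-equal in spread, and distinct, with positively co-occurring
  labels like the real subtypes. Within a cluster the first member (the
  "driver") carries full axis loading 1.0 and the rest 0.2, plus a
  cluster-level factor (SD 0.3) and protein noise (SD 0.5); rows then pass
  through the same z-score + logistic scaling as real data.
* **Labels:** Bernoulli draws from the model's own forward probabilities
  σ(Θ*ᵀZ* + b) with φ* = 8, λ* planting the driver at gap 2.5 (softmax
  weight 0.65 vs 0.09), Θ* = ±2 per the sign pattern, and per-subtype
  intercepts b tuned by bisection to hit the target prevalences. The
  fitted model has no intercept; it absorbs b through the (0, 1)-valued
  cluster effects. An optional measurement-noise SD (default 0.25)
  perturbs the observed expression relative to the label-generating
  signals.

Because labels are Bernoulli draws from bounded logits, the generating
logits cap achievable discrimination: at the defaults the oracle
(generating-logit) AUROC is ≈ 0.89 per subtype, and a fitted model at
n = 600 training samples typically lands within ~0.01 of it. That cap is a
property of the label mechanism, not of the optimizer: training AUROC
cannot approach 1 under this mechanism at these effect sizes.

What passing tests show — and don't: the synthetic cohort has exactly the
covariance and link structure the model assumes, so self-consistency
results demonstrate correct implementation and identifiability, not
real-world performance. The generator does not emulate Olink assay noise
structure, detection-limit censoring, plate effects, or demographic
covariates.

## Numerical choices

* BCE clipping ε = 1e−12; softmax max-shifted; probabilities clipped into
  the open unit interval.
* Linear systems solved by Cholesky factorization; no matrix inverse is
  ever formed; the factorization is shared between the forward solve and
  the φ-gradient within an iteration.
* Step acceptance tolerance 1e−12; trace monotonicity is asserted at 1e−9.
* Duplicate undirected edges are summed (with a warning); edges touching
  unknown proteins are skipped; GMT cluster files must be exact partitions
  (overlap or uncovered proteins are errors, because the aggregation
  algebra assumes disjoint clusters).
* All randomness flows from a single seed expanded into per-stage
  SeedSequence streams, so generate → fit → evaluate is bit-reproducible.

## Problem sizes used in the checked results

Self-consistency and recovery use p = 40, m = 8, 600 training / 400
validation samples; the ablation comparison uses 10 seeds at 400/400; the
protocol check uses 20 × 5 folds on a 110/40 split; oracle equivalences use
n ≤ 50 (AUROC), 8-point dissimilarity matrices (Ward), and lists ≤ 6 (BH).
These sizes keep every check fast on a single CPU while leaving the
measured quantities comfortably inside their acceptance margins.

## Known limitations

* The differential-expression stage is unmoderated Welch-t; limma-style
  empirical Bayes will rank borderline proteins differently.
* Ward on Jaccard is a pragmatic extension outside Ward's geometric
  assumptions; inverted merge heights are handled but can make "cut
  height" unintuitive.
* Dense linear algebra limits the model to a few hundred proteins —
  appropriate for targeted panels, not proteome-wide data.
* The logistic heads have no intercept, so prevalence must be absorbed
  through the cluster effects; with strongly unbalanced labels this costs
  a little discrimination relative to an intercepted model.
* The repeated-CV protocol scores a single fixed validation cohort, so its
  confidence intervals describe training variability, not cohort sampling
  variability.
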