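# Methods

`clusterbn` learns **group Bayesian networks**: discrete Bayesian
networks whose nodes are *groups* of original variables (plus a
separated target and optional confounders), each group summarised by a
single synthetic representative. The pipeline is (1) hierarchical
clustering of mixed variables, (2) aggregation and discretization,
(3) structure and parameter learning, (4) target-specific adaptive
refinement of the grouping. A two-layer simulator and an evaluation
harness make every stage testable against known ground truth.

## Variable clustering and aggregation

Variables may be quantitative or qualitative. A cluster's synthetic
central variable is the first principal component of the PCAmix design:
quantitative members standardized to zero mean and unit (population)
variance; each qualitative member expanded into centered indicator
columns scaled by `1/sqrt(p_s)` for category proportion `p_s`. The
first eigenvalue `λ₁` of `ZᵀZ/N` is the cluster **homogeneity**, and it
equals the sum over members of squared correlation (quantitative) or
correlation ratio `η²` (qualitative) with the scores. Scores are
oriented so the first design column loads nonnegatively; the centering
and scaling constants and loadings are stored so held-out rows can be
projected exactly.

Clustering is agglomerative: at each step the pair of clusters whose
merge loses the least homogeneity, `H(A) + H(B) − H(A∪B)`, is merged,
with that loss as the merge height. The candidate homogeneity is
recomputed exactly (a fresh eigendecomposition per candidate union);
at a few hundred variables this costs seconds and avoids the
approximations of Lance–Williams updates. Ties break on the
lexicographically smallest pair of member names. Exact recomputation
can in principle produce height inversions; heights are clamped by a
running maximum so the dendrogram is monotone and every cut is well
defined. The *aggregation levels* (merge heights read from the top)
guide the choice of the initial group count; `n_groups="auto"` picks
the k whose level exceeds the next one by the largest drop.

Medoid aggregation is available as an alternative: the member
minimizing total dissimilarity `1 − assoc²` to the others (squared
Pearson correlation, correlation ratio, or squared Cramér's V depending
on the kinds involved), with ties to the first column.

Separated variables (the target, declared confounders) are excluded
*before* clustering, so no group ever contains them.

## Discretization

Cluster representatives are often multimodal, so they are binned by a
density-approximative rule rather than fixed quantiles: a Gaussian KDE
(Silverman bandwidth, 512-point grid spanning the data ± one bandwidth)
is scanned for significant peaks — local maxima with height ≥ 10 % of
the global maximum and prominence ≥ 5 % of it. With ≥ 2 peaks, a 1-D
k-means seeded at the peak locations runs to convergence and the bin
boundaries are midpoints between sorted centroids; with one peak the
sample quartiles are used (four bins). Values equal to a boundary fall
in the upper bin. Empty training bins (possible under heavy ties) are
merged away, so every training bin is non-empty and the fitted map
reproduces the fit-time labels exactly. Separated quantitative
variables are discretized by the same rule; qualitative ones keep their
levels.

## Structure and parameter learning

Structures are scored by the decomposable BIC,

    score(Xᵢ, Π(Xᵢ)) = Σⱼₖ N_ijk log(N_ijk / N_ij·) − qᵢ(rᵢ−1)/2 · log N,

maximized by greedy hill climbing over single-arc additions, deletions
and reversals (strict improvement required, so the search terminates
and is deterministic given a seed). At each local optimum the incumbent
is perturbed by random legal moves — 10 % of the current arc count, at
least 1 — and climbing resumes; 10 restarts by default, keeping the
best structure seen.

Learning is repeated on `B = 200` nonparametric bootstrap resamples of
the rows (resampling at full N). Arc *strength* is the fraction of
resampled structures containing the arc in either direction; the
*direction* fraction records its majority orientation. The inclusion
threshold is chosen adaptively: among candidate thresholds (the
observed strengths and 0), take the one minimizing the L1 distance
between the strength vector and its thresholded {0,1} idealization,
smallest on ties. The averaged DAG keeps arcs above threshold with
their majority orientation; any directed cycle (rare) is broken by
dropping its weakest arc.

Parameters are Bayesian estimates under a uniform prior with imaginary
sample size 1: `θ(X=k|j) = (N_jk + iss/(r·q)) / (N_j· + iss/q)`, so
unseen parent configurations fall back to uniform.

Equivalence classes are represented as CPDAGs (v-structures compelled,
closure rules applied, the rest undirected); Markov blankets and
moralized graphs come with the usual definitions.

## Prediction

The target's posterior given all other nodes is estimated by
likelihood weighting: the target is sampled from its CPT given its
(observed) parents and each particle is weighted by the likelihood of
the evidence; with everything but the target observed only the
target's own CPT and its children's CPTs vary across particles, which
the implementation exploits to vectorize over rows and particles. An
exact closed-form posterior (`posterior_exact`) is provided and used as
the oracle in tests: `P(t|rest) ∝ P(t|Π(t)) · Π_c P(c|Π(c))` over the
target's children `c`. Rows with zero-probability evidence get a
uniform posterior and a warning.

## Adaptive refinement

The objective is the class-weighted cross-entropy of the target:
`H = −Σᵢ wᵢ log pᵢ` with `wᵢ = 1/(K·#{o = oᵢ})` and `pᵢ` the predicted
probability of row i's *observed* class, so each of the K classes
contributes total weight 1/K regardless of imbalance (for the canonical
binary target, `wᵢ = 1/(2·#{o = oᵢ})`, each class weighing 1/2). (A variant with raw
class-proportion weights, under which the majority class dominates and
negative rows drop out, is kept behind `literal_weights=True` for
comparison; the balanced form is the default because equal class shares
are the point of the weighting.) Because `pᵢ` is a Monte-Carlo
estimate, the loss is evaluated over 20 independent likelihood-weighting
runs and summarised as mean plus a (min, max) band.

Refinement hill-climbs over dendrogram splits: candidates are the
splittable groups in the target's Markov blanket (optionally all groups
within a moralized-graph distance `d`). Each candidate model is rebuilt
with the structure search initialized at the incumbent structure, the
two new group nodes inheriting the split node's arcs. The
best-scoring candidate is accepted only if its mean loss falls below
the *lower* end of the incumbent's band; otherwise the search stops.
Accepted losses therefore decrease strictly and the loop halts after at
most p − k splits. The loss is evaluated in-sample during refinement;
generalization is measured separately by cross-validation.
Refinement-level random restarts are not implemented (only
structure-level restarts are); `max_iter` caps the loop if desired.

## Two-layer simulator

Ground truth is a two-layer model: layer 1 is a discrete BN over
`n_groups` latent group variables (default 3 states) whose DAG is drawn
uniformly over labelled DAGs by a Markov chain (propose a random
ordered pair; toggle the arc when acyclicity allows; burn-in 10·n²
proposals — validated by a chi-square uniformity test over the 25
labelled 3-node DAGs) and whose CPT rows are symmetric Dirichlet(1)
draws. Each group emits `group_size` observed children at noise level
ε: discrete children copy the parent's state with probability 1 − ε and
otherwise move to a uniformly random other state; continuous children
emit the parent's state index plus Gaussian noise. The continuous σ is
calibrated per child so the expected nearest-level state-recovery error
equals ε: boundary states err to one side only, interior states to
both, so σ solves `Φ(−1/(2σ)) · (2 − p_first − p_last) = ε` with the
parent's marginal estimated once from 20 000 forward samples of
layer 1. This makes "noise level" mean the same thing for both child
kinds, which the prediction-error-versus-noise comparison requires.

The flat "standard network inference" baseline learns a detailed
network over all layer-0 variables, derives groups by hierarchical
community detection (igraph fastgreedy on the moralized skeleton) and —
deliberately charitably — picks the dendrogram cut closest to the true
grouping; group arcs are projected using the *true* grouping wherever
at least one detailed arc crosses two groups, majority direction on
conflicts, lexicographic on ties, weakest-arc cycle breaking.

## Evaluation

Groupings are compared by variation of information (natural log), zero
iff identical, symmetric, triangle inequality. Structures are compared
by the CPDAG structural Hamming distance (insertion, deletion, or
orientation change each count 1) normalized by the ground-truth edge
count; learned group ids are matched to true groups by a Hungarian
assignment on member overlap first. AUROC uses the midrank statistic
(equal to trapezoidal ROC integration, asserted in tests); AUPRC is the
step integral of precision over recall. Cross-validation is stratified
by target class (guarding against single-class folds) with fold
assignment a function of the seed alone, so competing configurations
see identical folds; all transforms (clustering, loadings,
discretization maps) are fit on training folds only.

## Problem sizes and defaults

Model-level defaults follow the workflow's standard configuration:
B = 200 bootstrap resamples, 10 restarts, imaginary sample size 1,
20 scoring runs. The simulation-study driver defaults to a desk-scale
design — 10 groups × 5 children, n = 500, 20 replicates per scenario,
with lighter learning settings (B = 25, 1 restart, parent sets capped
at 4) — chosen as this package's own compromise between statistical
resolution and turnaround; the full-size design (20 groups, 100
replicates, full learning settings) is reachable through the same
configuration objects.

## What the simulator does and does not emulate

The two-layer generator reproduces the features the method is built
for: latent modular structure, mixed measurement types, calibrated
measurement noise, and heterogeneous emissions. It does *not* emulate
children with multiple latent parents, overlapping or nested groups
beyond the two layers, missing data mechanisms, selection effects, or
real-world distributional quirks (skew, zero inflation). Passing the
synthetic-recovery tests therefore shows the machinery is correct and
self-consistent under the model's own assumptions, not that any
particular real dataset satisfies them.

## Numerical choices and degenerate inputs

- Hill-climbing accepts only strictly improving moves (margin 1e-12);
  first move in enumeration order wins ties.
- CPT rows sum to 1 within 1e-10 (validated at construction).
- Zero-variance variables, single-level qualitative variables,
  constant targets, vectors with fewer than 8 values at discretization,
  k out of range at cutting, and singleton-group splits all raise
  informative errors rather than degrading silently.
- Cross-entropy probabilities are clipped at 1e-12 before the log.
- All randomness flows from explicit seeds through
  `numpy.random.SeedSequence` spawning, which is what makes the model
  JSON byte-stable under a fixed seed.

## Known limitations

- Discrete targets only (binary is the canonical case; small
  multiclass targets use the 1/K-balanced loss); a continuous target
  would need a different objective.
- One-dimensional group representatives; a group whose members span
  several distinct axes of variation is summarised by its first axis
  only (refinement mitigates this by splitting such groups when the
  target cares).
- In-sample refinement can overfit when n is small relative to the
  number of candidate splits; use the cross-validation harness to check
  generalization.
- The averaged-structure-then-parameters convention (parameters fit
  once on the full data given the averaged DAG) is one of several
  defensible model-averaging styles.
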