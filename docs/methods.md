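# Methods

## Model

An aCGH cohort is a matrix `X` of log2 copy-number ratios, one row per
tumor sample and one column per probe, with probes ordered genomically
and annotated with chromosome, base-pair position and arm. Two prior
properties of such data drive the model: adjacent probes on one arm tend
to report the same underlying copy number, and a chromosome usually
harbors few alteration events.

Each partitioning step learns a linear separator `f(x) = β·x + b` that
assigns samples to the two half-spaces of a hyperplane in probe space.
Given labels `y ∈ {−1, +1}` treated as regression targets, `(β, b)`
minimizes the residual sum of squares subject to two *budget*
constraints (constraint form, not penalties):

* `Σ_j |β_j| ≤ s1` — sparsity: few probes carry weight;
* `Σ w_{j,j−1} |β_j − β_{j−1}| ≤ s2` — piecewise constantness: adjacent
  same-arm probes carry similar weight, with pairs never spanning an arm
  or chromosome boundary.

The fusion weight normalizes for inter-probe distance. High-density
arrays have gaps varying over orders of magnitude, and fusing across a
large gap is less justified than fusing 1 kb neighbors. The default
form is `w = min(1, d_med/d)`: weight 1 up to the median gap `d_med` of
the map, decaying inversely beyond it. It is monotone in the gap,
bounded in `(0, 1]` and scale-free; the exact functional form is
configuration (`compute_fusion_weights(form=...)` accepts `uniform` or
any callable) because no single form is canonical.

### Unsupervised alternation

Labels are not known; the separator and the labels are found jointly in
the maximum-margin-clustering style: initialize labels with 2-means on
the raw profiles (Euclidean, best of 10 restarts under the run's seed),
then alternate (a) solving the QP with the current labels and (b)
relabeling each sample with `sign(β·x_i + b)`, a decision value of
exactly 0 mapping to +1. Squared-error regression of the ±1 labels is
used rather than a hinge loss: with labels fixed the problem is then a
convex QP under linear constraints, and regression-style targets are
known to avoid the premature label freezing seen when alternating with
a hard-margin classifier.

Termination: the label sequence either reaches a fixed point (the usual
case, within a handful of sweeps) or enters a cycle; cycles are detected
by hashing the label state, and the lowest-objective state of the cycle
is returned with `converged=False`. A hard cap of 50 sweeps applies.
When every sample lands on one side, the result is flagged `trivial`
and reported as such — no class-balance constraint is imposed, since
budget choice, not balancing, is the intended control of triviality.

### Budgets

`s1` and `s2` set the scale of the separator, and suitable values
depend on the array platform and cohort statistics. The defaults
(`s1 = 2.0`, `s2 = 1.0`) come from a scale argument: to map carriers of
an event of amplitude ~1 (in log2 units) onto targets at ±1, the weight
mass summed over the event's probes must be ≈ 2 regardless of how many
probes the event spans, so an L1 budget of 2 accommodates focal through
whole-chromosome events; the corresponding boundary jumps then cost at
most a few tenths of fusion budget. Too-small budgets produce trivial
clusterings, very large ones reduce the procedure to plain 2-means
(both regimes are exercised in the tests); the useful range between
them is broad. For a new platform, the practical recipe is a small grid
search on a sample subset, taking the smallest budgets that give a
non-trivial clustering on every chromosome.

### Iterative partitioning

Each chromosome is analyzed independently. The cohort is split, then
each group is split again recursively. Every new separator is
constrained orthogonal (`β·β_ancestor = 0`) to the separators of the
ancestors on its root-to-node path, so successive splits explore new
directions of variation, analogous to successive principal components.
Orthogonality is restricted to path ancestors rather than all
separators in the tree: sibling subtrees describe disjoint sample sets
and there is no reason to couple their geometry.

A node is split only if all three hold:

1. it contains more than `min_group_size` samples (default 5 — smaller
   groups cannot achieve a meaningful permutation p-value);
2. it sits above `max_depth` (default 3 — deeper groups are empirically
   too small or no longer significant);
3. the split's permutation p-value is at most `p_threshold`
   (default 0.1; the centroid distance is not the quantity the QP
   optimizes, which makes the test conservative, so a permissive
   threshold is appropriate).

Leaves record which rule stopped them (`too_small`, `max_depth`,
`not_significant`, or `failure` if the solver broke down on that node;
failures never abort sibling subtrees). Per-node seeds are derived by
hashing the root seed with the node path, so trees are reproducible and
sibling randomness is independent.

## Split significance

The observed statistic is the Euclidean distance between the two
groups' centroids (per-probe median profiles) over all probes of the
chromosome. The null is built by shuffling the probes of the data set
and re-applying the frozen separator: each of `n_perm` (default 1000)
rounds shuffles every probe column independently across samples,
assigns each shuffled pseudo-sample a side by `sign(β·x + b)`, and
records the centroid distance of the two resulting groups (0 if a side
is empty). A normal distribution is fitted to the null distances by
moments and `p = 1 − Φ((observed − μ)/σ)`.

Shuffling columns across samples destroys sample identity while
preserving every probe's marginal distribution, so the null groups are
genuinely random sample groups produced by the same classifier — which
is the comparison the test is meant to make. Two alternative schemes
are available via `scheme=`: a single probe permutation shared by all
samples (`within_samples_joint`) and independent per-sample probe
permutations (`within_samples`). Both preserve each sample's value
multiset, which makes them degenerate for events spanning a large
fraction of the chromosome: a carrier of a whole-chromosome gain is
still a carrier after any within-sample reshuffle, the null groups
reproduce the observed groups, and the test loses all power exactly for
the largest events. They are kept for comparison, not as defaults.

Degenerate cases: a one-sided labeling returns `p = 1` directly; a null
with zero spread returns `p ∈ {0, 1}` by sign of the observed excess,
flagged `degenerate`. Normality of the null is not re-tested per split;
the fitted moments are stored in the result for diagnostic inspection.

Known limitation: when an event spans a sizable fraction of the probes
at intermediate prevalence, the shuffled pseudo-samples retain partial
carrier signal, the classifier sorts them unevenly, and the null
distances grow — the test then loses power (an event spanning 20% of
the chromosome at 30% prevalence tests around `p ≈ 0.1` at cohort size
60, while focal, arm-level and whole-chromosome versions of the same
event test at `p < 0.01`). This conservatism is inherited by design:
the null deliberately lets the classifier do whatever it can on
structureless data. No multiple-testing correction is applied across
chromosomes or splits; the per-split threshold is the only gate.

## CNA calling and co-occurrence

Cluster centroids are summarized into discrete calls by a deliberately
simple, pluggable rule: a call is a maximal run of at least
`min_probes` (default 5) consecutive probes within one arm whose
centroid values all exceed `+amp_threshold` (gain) or fall below
`−amp_threshold` (loss), with the run's mean centroid value as
amplitude. The defaults (`amp_threshold = 0.2` log2 units,
`min_probes = 5`) sit above the typical aCGH noise floor; segmentation
of centroids by heavier machinery is intentionally out of scope. Calls
are emitted as BED (0-based half-open) or SEG (1-based inclusive).

Co-occurrence: each called CNA defines a sample membership (the samples
of its cluster); for every unordered pair of CNAs the 2×2 joint
membership table over all samples is tested with a one-sided Fisher
exact test for enrichment (upper hypergeometric tail at the observed
co-membership count). The p-value is computed in exact integer
arithmetic, so it is reproducible to the last bit and matches
enumeration oracles exactly. Pairs with a fixed margin (a CNA in all or
no samples) are flagged degenerate with `p = 1`. All pairs are
reported with their p-values; thresholding is left to the user.

## Synthetic cohorts

The generator plants additive gain/loss blocks over independent
Gaussian probe noise: `value[i,j] = Σ amplitudes of events carrying
sample i and covering probe j + N(0, noise_sd)`. Probe maps place a p/q
boundary at the midpoint with uniform or lognormal gaps (the lognormal
model emulating the wide gap disparities of high-density arrays).
Named scenarios fix the study conditions used throughout the tests and
the acceptance script: 60 samples × 200 probes, noise sd 0.3, amplitude
1.0 events at 15–30% prevalence, spanning focal (~6% of probes) to
whole-chromosome ranges, including a nested two-level configuration
(a focal gain inside the carriers of an arm loss). Pure-noise
calibration runs use 30 samples × 80 probes, and permutation counts in
tests range 150–1000; these sizes keep the full suite and the
acceptance script comfortably fast while leaving all effect-to-noise
ratios at the stated values.

What the generator does *not* emulate: probe-level spatial noise
correlation, tumor purity/stromal dilution, per-sample quality tiers,
heavy-tailed or saturated probe responses, and wave artifacts. Passing
tests on these cohorts therefore demonstrate correctness of the
optimization, the tree logic and the statistics under the model's own
assumptions — not robustness to every artifact of real arrays.

## Numerical choices

* QP solver: dense Mehrotra predictor-corrector interior point on the
  split-variable formulation; KKT systems are regularized with 1e-9 on
  the diagonal and solved by LU. Convergence tolerance 1e-9 on scaled
  residuals and duality gap; downstream feasibility contract 1e-6.
  Budget `s1 = 0` short-circuits to `β = 0`, `b = mean(y)` exactly;
  `s2 = 0` collapses each fused chain to a single coefficient and
  solves the reduced weighted-L1 problem.
* Orthogonality sets with rank ≥ p are rejected (`LinAlgError`) — no
  non-trivial separator exists.
* Ties: decision value exactly 0 labels +1, everywhere.
* Missing data: probes missing in more than 20% of samples are dropped,
  the remainder median-imputed per probe (the QP needs complete
  vectors); `drop` and `error` policies are available.
* Duplicate genomic positions in an annotation are rejected rather than
  ordered arbitrarily.
* Floats are serialized at full precision (`repr`) and parsed with
  round-trip precision, so write/read cycles are lossless.
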