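# Methods

This note records the models the package implements, the defaults it ships
with and why, what the synthetic generator does and does not emulate, and
the numerical choices a user re-deriving results will want to know.

## Pipeline model

The pipeline treats regulatory inference for one target gene as a funnel:
an N × T matrix (N genes, T time points) is reduced to a panel of tens of
genes before any multivariate model is fitted. All stages after the
zero-variance filter operate on row-standardized expression (mean 0, sd 1,
n−1 denominator), so clustering, distances and the VAR see one common
scale. Zero variance is tested as exact equality of all entries, not a
tolerance. Whether the input should be log-transformed first is left to the
user; the tool takes the matrix as given.

### Fuzzy C-means

Minimises `Σ_k Σ_i u_ki^m d²(y_i, c_k)` with squared Euclidean distance and
the constraint that each gene's memberships sum to 1. The fuzzifier default
is the data-size relation `m(D, N) = 1 + (1418/N + 22.05) D^−2 +
(12.33/N + 0.243) D^(−0.0406 ln N − 0.1134)` (N genes, D time points),
overridable; for long time courses it approaches 1 and the clustering is
nearly hard. Updates alternate u^m-weighted centroid means with membership
updates of exponent 2/(m−1), computed on distance *ratios* to the per-gene
minimum so that near-1 fuzzifiers (steep exponents) cannot overflow or
underflow a whole membership column; genes numerically on a centroid split
their membership evenly among the centroids they touch. Convergence is an
absolute objective change below `tol = 1e-6`, capped at `max_iter = 300`.

The alternating updates only find local optima, and on archetype-structured
data the bad optima (two archetypes merged, one split) are separated from
the good one by a large objective gap. The fitter therefore runs `n_init =
10` restarts and keeps the lowest final objective. Restarts are seeded from
a spawned seed sequence, so a single integer seed reproduces the whole fit.
Initial memberships come from k-means++ (D²-sampled) seed genes by default;
a symmetric Dirichlet(1) draw is available as `init="dirichlet"` but lands
in merged-cluster optima often enough that the default was changed.

The Gap statistic compares `log W_k` of the *hardened* partition (sum of
squared distances to hardened cluster means) against `B = 20` reference
datasets drawn uniformly over each feature's observed range, with `k_hat`
the argmax of the gap curve. The full curve and reference standard errors
are emitted because the argmax is known to overshoot on structured data;
users may prefer an elbow. Whether gap dispersion should use fuzzy or
hardened partitions is genuinely open; hardened was chosen because the
reference-dispersion theory is defined for partitions.

### Smoothing

Local polynomial regression with tricube weights
`W(x; u) = (1 − (x/u)³)³` on `x < u`. For α ≤ 1 the bandwidth at an
evaluation point is the distance to its ⌊αT⌋-th nearest time point, with
⌊αT⌋ clamped to at least degree + 2 so the local polynomial stays
identifiable; for α > 1 it is α times the largest distance. Fits are
evaluated only at observed times; no extrapolation. The smoother is linear
in y, so its matrix trace is exact and
`GCV(α) = (RSS/T)/(1 − tr(L)/T)²` is cheap; an interpolating α (trace = T)
scores +∞ with a warning. Ties in GCV — which arise exactly, e.g. on
noiseless polynomial data — resolve toward the largest (smoothest) α, with
float round-off treated as a tie. The default grid is 0.02 to 1.00 in
steps of 0.02 and the default degree is 2.

### Distances

Lock-step distances use absolute differences, `(Σ|Y_j − Z_j|^n)^{1/n}`, so
odd Minkowski orders are well defined. DTW minimises the normalized cost
`Σ d(p_s) w_s / Σ w_s` over monotone, continuous warping paths with
pointwise cost `|Y_u − Z_v|`. Step weights follow the index-step
convention: symmetric weighting gives diagonal steps weight 2 and
horizontal/vertical steps weight 1 (every path then has total weight
t_Y + t_Z, so the dynamic programme is exactly the normalized optimum);
asymmetric weighting counts only steps advancing the first series' index
(total t_Y). A value-difference reading of the weights would make them
sign-indefinite, which is why the index convention was adopted. No global
path constraint is applied by default; a Sakoe–Chiba band of configurable
half-width is available. The inner loop is numba-compiled; the test suite
checks it against exhaustive path enumeration, exactly, for all small
integer series. Only gene-to-target distances are computed (O(N·T²) worst
case), never the all-pairs matrix.

### Selection

The cluster's genes are sorted by ascending distance to the smoothed
target and their ranks *among all genes* are compared with the ordinal
ranks 1..n by a two-sided paired Wilcoxon signed-rank test, growing n from
`start = 10` in steps of 1. Zero differences are discarded before ranking
(classic Wilcoxon). For effective n ≤ 25 the p-value is exact: the null
distribution over all 2^n sign assignments is computed by integer
convolution over doubled midranks, which handles ties without
approximation; beyond that a normal approximation with tie correction is
used. The procedure stops at the first p < 0.05 and reports the last
non-significant n; if no test is significant the whole cluster is
significant, and clusters smaller than `start` are kept whole with a
warning.

Two properties of this sequential rule are worth knowing. Detection trails
a planted rank break by however many distant genes the test needs to
accumulate significance (about seven in simulations), and because no
multiple-testing correction is applied across the incremental tests — by
design — the rule occasionally fires early on rank noise. Both behaviours
are inherent to the procedure, not bugs; the p-value trace is always
written so users can inspect the path.

Rescue then admits every gene of *any other* cluster whose distance is at
most the maximum distance among the significant genes (inclusive
boundary). The significant and rescued sets together contain every gene
within the threshold distance, which is the precise sense in which no
relevant gene is missed by the cluster boundary. The exact rescue cutoff
is this tool's definition; only "distances in the acceptable range" is
prescribed by the method's description.

### Network

OLS VAR(1) with intercept: `Y_future` regressed on `[Y_past, 1]`. When the
Gram matrix is singular (p ≥ T − 1) the Moore–Penrose pseudoinverse is
used, `rank_deficient` is set and a warning raised. The residual
covariance divides by T − 1 − (p + 1); if that is non-positive the
uncorrected second-moment matrix is reported with a warning.

Lagged partial correlations are defined by the two-regression identity
`√(a_1k a*_1k) sgn(a*_1k)` — forward: target at t+1 on all genes at t;
reverse: source at t on the target at t+1 plus the other genes at t. The
production implementation computes the same quantity from the precision
matrix of the joint (p+1)-variable covariance, one target at a time; the
two-regression form is retained as the test oracle, and the algebraic
non-negativity of the coefficient product is asserted at runtime.

Dynamic (functional) correlation standardizes each series under the
trapezoid-weighted inner product — centred by ⟨f, 1⟩ and scaled by
√⟨f − ⟨f,1⟩, f − ⟨f,1⟩⟩ — so the diagonal is exactly 1; boundary weights
use the one-sided conventions t_0 := t_1, t_{T+1} := t_T. The functional
(rather than ordinary sample) variance is used precisely so that self-
correlation is exact. Note the weights do not sum to one, so functional
centering does not annihilate constants; constant series are rejected
explicitly. Dynamic partial correlations come from the inverse correlation
matrix, `−ω_kl/√(ω_kk ω_ll)`. Selected panels often contain near-duplicate
genes (co-clustered background), which makes that matrix numerically
singular; the module-level function raises with a hint, while the pipeline
applies a default shrinkage of 0.05 toward the identity — the standard
remedy in the shrinkage-estimation network literature this stage follows.

Edges are ranked by |weight|, self-loops excluded by default (the
autoregulation diagonal trivially dominates), magnitude ties broken
lexicographically on (source, target), and the top 150 written — a
magnitude ranking stands in for formal edge significance testing
(local-FDR fitting is out of scope). Both lagged (directed) and dynamic
(undirected) edge types are emitted and labelled, since which of the two a
downstream analysis should trust is context-dependent.

## Synthetic data

The generator emulates a dense one-cycle circadian course at reduced
scale: 300 genes × 480 time points by default (the motivating datasets are
two orders of magnitude larger in genes, identical in time points).
Background genes are drawn round-robin from `n_clusters = 4` standardized
archetypes — phase-shifted sinusoids spanning one period plus one monotone
trend — plus i.i.d. Gaussian observation noise (`noise_sd = 0.2`, five
times smaller than the unit archetype amplitude, a separation at which
cluster recovery should be essentially perfect).

The regulatory core follows `y(t+1) = A y(t) + g·pattern(t+1) + ε` with
`g = (I − A)·1`, so every core gene's deterministic component tracks a
shared distinctive shape — a sharp standardized pulse at 3/4 of the cycle,
the profile of a nocturnally induced gene and unlike any background
archetype — while the couplings act on the stochastic deviations around
it. The default core has 6 genes: a target with weak self-memory (0.3)
driven by 3 persistent regulators (self-lag 0.85, coupling +0.45), plus
two co-driven bystanders; the matrix is triangular apart from its
diagonal, so stability is immediate. The process is burned in for 200
steps with the drive held at its initial value, and observation noise of
the same `noise_sd` is added to the core as well.

Two deliberate asymmetries encode what a similarity-based screen can and
cannot find. Couplings are positive: an anti-phased (repressive) regulator
of a standardized target is structurally invisible to distance-based
selection, and planting one would make the ground truth unrecoverable by
any correct implementation. And the target's self-lag is weak: a strongly
autoregressive target absorbs its regulators' lagged signal into its own
lag term, leaving little detectable partial correlation — the generator
models a sharply induced output gene instead, which is also the
biologically motivated regime. Real data differ from this generator in
having unequal cluster sizes, gene-specific noise scales, multiple
co-regulated modules, and repressive edges; passing tests on this
generator therefore demonstrate correctness of the machinery and
recoverability in a favourable but realistic regime, not performance
guarantees on arbitrary transcriptomes.

## Numerical and interface choices

- Cluster indices, like all indices in the API, are 0-based; membership
  argmax ties resolve to the smallest index.
- `floor(α·T)` neighbours are clamped to at least degree + 2; GCV ties go
  to the largest α; distance-rank ties keep input order (stable sort).
- Determinism: every stochastic routine takes an integer seed;
  sub-streams are spawned via seed sequences, so repeated runs are
  bit-identical. The pipeline writes a manifest of all resolved
  parameters; re-running from the manifest reproduces every artifact byte
  for byte (the gap curve is only produced when K is resolved as "auto").
- The simulation scales used throughout the tests and the verification
  script — 300×480 matrices, 20-seed replications, p = 20 VAR panels —
  were chosen so the planted effects are comfortably detectable while a
  full verification run stays around a minute on one CPU.

## Known limitations

- The sequential Wilcoxon rule is uncorrected for multiplicity (above) and
  its stopping point has high variance on weakly structured clusters.
- Repressive (anti-phased) regulators cannot be discovered by the
  similarity funnel even though the VAR stage could rank them; they are
  lost before the network stage.
- VAR(1) assumes a first-order, time-invariant linear dynamic on the
  selected panel; slow shared trends (e.g. the common circadian drive)
  inflate some bystander edges, and only the relative ranking — not a
  calibrated error rate — is provided for edges.
- DTW distances are computed against a single smoothed target; multiple
  target genes are out of scope.
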