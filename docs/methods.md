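# Methods

This note documents the models and estimators implemented in `coexnet`,
the defaults and why they were chosen, the numerical decisions, and what
the synthetic benchmarks do and do not establish.

## Association measures and adjacencies

An adjacency matrix satisfies `0 ≤ A_ij ≤ 1`, `A_ij = A_ji`, `A_ii = 1`
(enforced by `validate_adjacency` to 1e-12).  Association matrices
(correlations, MI, directional R²) may be signed or asymmetric and are
mapped into adjacencies by the transforms below.

### Biweight midcorrelation

For a vector `x`, `u_i = (x_i − med(x)) / (9 mad(x))` with the *unscaled*
median absolute deviation (no 1.4826 consistency factor — the weighting is
relative, so the factor would only rescale `u`).  Weights are
`w_i = (1 − u_i²)² 1{|u_i| < 1}`; bicor is the cosine similarity of the
weighted median-centred vectors.  Two totalizing rules:

* **Outlier-proportion cap** (`max_p_outliers`, default 0.02).  On each
  side of the median, `u` is divided by `|u|` evaluated at that side's
  `max_p_outliers` sample quantile whenever that value exceeds 1, so at
  most (approximately) that fraction of points per side can reach weight
  zero.  With `max_p_outliers = 0.5` the cap never triggers and the plain
  biweight formula is recovered — the unit tests exploit this to compare
  against a literal transcription of the defining equations.
* **mad = 0 fallback.**  If `mad(x) = 0` but `x` is not constant (more
  than half the values tied at the median), the biweight terms are
  undefined; the vector falls back to mean-centred unit-weight (Pearson)
  terms.  Constant vectors are rejected.

### Discretized mutual information

Profiles are discretized into `R` equal-width bins over `[min, max]`,
right-open except the last (so the maximum is always assigned).  The
default `R = round(√m)` (half-away-from-zero; the square-root rule has no
printed rounding convention, nearest-integer is the least surprising total
choice).  All entropies are in nats.

MI is always computed through the entropy identity
`MI = H(dx) + H(dy) − H(dx,dy)`, each term with the chosen estimator:

* `plugin`: `−Σ p̂ log p̂`; the identity then reproduces the direct
  double-sum definition exactly, and `MI = G/(2m)` where `G` is the
  multinomial likelihood-ratio statistic of independence (asserted to
  1e-10 in the tests, which also check the bounds
  `MI ≤ min(H_x,H_y) ≤ (H_x+H_y)/2 ≤ max(H_x,H_y)`).
* `miller_madow`: plugin plus `(B⁺ − 1)/(2m)` with `B⁺` the number of
  non-empty bins — for the joint entropy, `B⁺` counts non-empty *cells*.
  Because the three corrections are applied independently, the corrected
  MI can be slightly negative or exceed a marginal entropy; MI is clamped
  at 0 from below and the derived adjacencies are clipped into [0, 1].
  This is the default estimator for all MI pipelines: at `R = √m` the
  plugin estimator's upward bias (roughly `(R−1)²/(2m)` nats for
  independent pairs) would otherwise dominate weak associations.

### MI adjacencies and the cor-MI map

`ASU = 2·MI/(H_i+H_j)`, `AUV1 = ASU/(2−ASU)`, `AUV2 = MI/max(H_i,H_j)`;
`1 − AUV1` and `1 − AUV2` are universal distances (triangle inequality
checked exhaustively on small fixtures).  Under bivariate normality with
`√m` bins, `AUV2 ≈ F(|cor|)` where

    F(s) = log(1 + ε − s²)/log(ε) · (1 − ω) + ω,   ω = 0.43·m^−0.30,  ε = ω^2.2.

The constants are taken as given and not refit.  `F` maps [0,1] to [0,1]
strictly increasingly whenever `0 < ε ≤ ω < 1`, which holds for every
`m ≥ 4` (asserted).  The prediction consumes `|cor|` since `F` depends on
`s²` only.  The approximation is specific to this binning rule; no claim
is made for other discretizations.

### Regression R²

Polynomial (degree `d`, default 3) and cubic-spline design matrices; the
spline uses the truncated-power basis
`[1, x, x², x³, (x−k_1)³₊, …]` with knots at equally spaced interior
quantiles of the predictor (placement matters less than count; the count
rule is 5 knots for m > 100, 3 for m < 30, else 4, read literally at the
boundaries).  A natural-spline basis with boundary linearity constraints
would differ near the extremes; the truncated-power basis is the
documented model here.  Least squares is solved by pseudoinverse with
root-mean-square column scaling for conditioning, and verified against a
normal-equations oracle.  `R² = cor(y, ŷ)²`; when `y` or `ŷ` is constant
the correlation is undefined and R² is defined as 0 (a constant fit
explains nothing).  The directional matrix is symmetrized by `max` by
default: a relationship detected in either direction counts.

### Transforms and TOM

Hard threshold is inclusive (`s ≥ τ`).  Soft thresholds: `|cor|^β`
(unsigned, default β = 6) and `((1+cor)/2)^β` (signed, default β = 12).
The general rescaling `((S − lower)/(upper − lower))^β` reproduces the
signed adjacency at bounds (−1, 1) and the symmetric uncertainty at
bounds (0, (H_i+H_j)/2) with β = 1 — both reductions are tested exactly.
TOM is computed with a matrix product for the shared-neighbour sum
(`O(n³)` dense) and asserted equal to the triple-loop definition.

### MI network inference

* **RELNET**: inclusive threshold `MI ≥ τ`, values preserved.
* **CLR**: row background statistics use the off-diagonal entries with the
  sample standard deviation (ddof = 1); a zero-variance row contributes
  z = 0 with a warning.
* **MRNET**: full MRMR forward-selection ordering per target (no stopping
  rule — every candidate is scored at entry); the redundancy sum covers
  previously selected predictors only, never the target; pair score is the
  max of the two directional scores, floored at 0.  Argmax ties break on
  the lowest index.
* **ARACNE**: edges with `MI ≤ τ` (default τ = 0) removed first, then
  every triplet of surviving edges is tested against
  `MI_ij ≤ min(MI_ik, MI_kj) − ε` on the *original* post-threshold matrix
  and flagged edges are removed simultaneously — order-independent by
  construction.  Tolerance ε ∈ [0, 1].

Inference scores become adjacencies by dividing by the maximum
off-diagonal score.

## Module detection

Dissimilarity `1 − A`, unweighted average linkage (UPGMA, via scipy,
oracle-checked against a naive agglomerator), then a fixed-height cut:
branches below the cut with at least `min_module_size` leaves (default 20)
become modules labeled 1..K in decreasing size order, the rest get the
background label 0.

The automatic cut height is the midpoint of the widest gap between
consecutive merge heights in the upper half of the tree (falling back to
0.995 × the maximum height when the upper half is flat).  A fixed
*fraction-of-maximum* rule was considered and rejected: it only separates
branches when the dissimilarity saturates at 1, which holds for
`((1+cor)/2)^12` but not for MI- or R²-based dissimilarities, whose
top-level merges form a tight band strictly below 1; a cut at 0.995 × max
then lands inside the band and collapses the partition.  The widest-gap
rule adapts to the measure's dynamic range while remaining deterministic,
which preserves the design requirement that *identical* clustering
settings be used for every measure so that differences in recovered
modules are attributable to the association measure alone.  This is a
deliberately simple stand-in for dynamic branch-cutting algorithms;
absolute recovery rates therefore should not be compared against results
obtained with dynamic cutting, only *between measures* run through this
same procedure.

Partition agreement is the unadjusted Rand index (pair-counting, via
scikit-learn, oracle-checked), with label 0 treated as an ordinary
cluster.

## Synthetic benchmarks

**Pair sweep.**  2000 target correlations equally spaced in
(−0.999, 0.999); for each, `x ~ N(0,1)^m`, `y = r·x + √(1−r²)·η`, default
m = 1000.  This isolates the estimators from real-data artifacts
(outliers, batch effects, non-normal margins); agreement shown here is an
upper bound on what to expect in practice, where MI estimates degrade at
small m and outliers can inflate MI but not bicor (machinery for flagging
such pairs is in `discordance_screen`, which standardizes |cor| and the
MI adjacency across pairs and reports the extreme discordant pairs in
each direction at a z-threshold of 1.9).

**Module simulation.**  Defaults: 200 genes × 200 samples; three modules
of 60 genes plus 20 background noise genes; per module a seed profile
`e ~ N(0,1)^m`; linear members are `strength·e + noise`, quadratic members
`strength·(e − ē)² + noise` (quadratic members exist in two of the three
modules, fraction 0.5), `strength = 1`, `noise_sd = 0.5` (signal-to-noise
of 2, i.e. within-module correlations ≈ 0.8 — strong but not degenerate
co-expression).  Since `E[e·(e²−1)] = 0` for symmetric `e`, quadratic and
linear members of the same module are uncorrelated but strongly dependent:
correlation networks split such modules, MI/regression networks do not,
which is the ordering the acceptance benchmark asserts.  Couplings are
positive by default; a `sign_flip_prob` option introduces negatively
coupled members, under which *signed* networks necessarily split modules
into correlated halves (negative correlation means disconnection in a
signed network) — useful for studying that effect, but not part of the
default benchmark, which is designed so that every pipeline can in
principle recover the linear-only configuration perfectly.

Problem sizes in the acceptance script (2000 pairs at m = 1000; 10 seeds
of the 200 × 200 module design; 1000 random contingency tables; 50
oracle instances at n ≤ 8) keep a full run in the low minutes on one CPU
while leaving the summary statistics stable to well within the margins
asserted.

## Known limitations

* No missing-value handling: inputs with missing cells are rejected at
  read time, since none of the estimators defines a missing-data policy
  and silently dropping samples would change `m` everywhere.
* MI estimation is equal-width binning only (no kNN/kernel/adaptive
  estimators, no permutation p-values); the cor-MI map is calibrated for
  `√m` bins and bivariate normality.
* The module cut is a static rule, not dynamic tree cutting; see above.
* No GO-enrichment or eigengene machinery; evaluation is purely
  partition-based (Rand index against simulated truth).
* Scaling is desk-scale dense linear algebra: `O(n²m)` pairwise sweeps
  and `O(n³)` TOM/ARACNE; a few thousand genes are comfortable, tens of
  thousands are not the target.
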