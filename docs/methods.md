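# Methods

## Model and procedure

The quantity of interest is the joint probability density π(x) of a 2-D
score pair x = (factor score, PANSI score) in an adolescent cohort, and the
binned joint/conditional probabilities derived from it. The procedure is
deliberately assumption-light: no Gaussian model is fitted to the scores.

**Scoring.** Subscale scores are sums of integer item responses. Reverse-
keyed items (BSSA-10 items 6–10) are recoded `(min + max) − raw` before
summation, so every subscale points in a consistent direction (high school-
adjustment scores mean better adjustment, including the integration-problems
subscale). A respondent missing any item of a subscale receives no score for
that subscale: a sum over a partial item set is not comparable to a complete
one. The PANSI NSI/PI item split and the BQREB factor→item map are not part
of the published instrument descriptions available to us; defaults (the
original PANSI keying; BQREB BP = items 1–4, CM = 5–7, R = 8–10) are
configuration arguments of `builtin_specs`.

**Density estimation.** π(x) is estimated with a product Gaussian kernel,
diagonal bandwidth matrix, and per-dimension normal-reference bandwidths
h_d = σ̂_d n^(−1/6) (the standard Silverman-type rate for a two-dimensional
kernel estimate; σ̂ is the ddof = 1 sample SD). The diagonal product kernel
keeps the density a simple double sum, which an independent brute-force
implementation can verify to machine precision. Integer scores are used
without jitter; the resulting density is smooth on ℝ² and carries some mass
outside the valid score rectangle. That leakage is absorbed at binning time
(below) rather than by boundary-corrected kernels.

**Sampling.** A random-walk Metropolis–Hastings chain targets J ∝ π:
candidates x_c ~ N(x_k, σ²I), acceptance probability min(1, J(x_c)/J(x_k)),
rejected proposals repeating the current state. Only density ratios enter,
so the target need not be normalized, and scaling J by any positive
constant provably leaves a seeded chain unchanged (tested). The chain
starts at the observed score pair of one uniformly drawn respondent, which
guarantees a positive-density start. The first M states are discarded as
burn-in; M defaults to N/10 with N = 20,000 iterations, the chain length
used for all shipped tables.

**Proposal scale.** σ = 1 (identity proposal covariance) is the default,
matching the method as originally stated. On score ranges spanning tens of
points a unit proposal is a small step: acceptance rates exceed 0.9 and the
chain's effective sample size drops. `suggested_proposal_scale` implements
the standard optimal-scaling rule for random-walk Metropolis,
σ = 2.38/√d × (mean per-axis sample SD) with d = 2, which lands acceptance
near the efficient ≈ 0.3 region; `RunConfig(proposal_scale="auto")` applies
it per pair. Both settings leave the stationary distribution unchanged —
the choice only affects Monte Carlo efficiency at fixed N.

**Binning.** Each subscale's score range is split into the three published
closed integer intervals (e.g. SP: (3,8), (9,13), (14,18)). Real-valued
chain states are assigned by midpoint cuts between adjacent intervals
(boundary between (3,8) and (9,13) at 8.5) with the outer bins extended to
±∞. This makes the cells a partition of ℝ²: counts always sum to the number
of retained samples, despite KDE mass outside the score rectangle. Joint
tables divide counts by the sample size; conditional tables renormalize
each factor-axis row (zero-mass rows are emitted as flagged missing, not
silently dropped). Because the product-Gaussian kernel integrates in closed
form over rectangles, `expected_joint_from_kde` provides the exact cell
masses the empirical table should approach — used throughout the tests as a
quadrature oracle independent of the sampler.

**Risk summary.** `headline_risk` reduces a table to one figure: the
maximum, over designated adverse factor bins, of the conditional
probability mass on designated adverse PANSI bins. The shipped convention
(`ADVERSE_BINS`) takes the lowest bin of protective constructs (SP, AE, IP,
APGAR, PI) and the highest bin of risk constructs (BP, CM, R), with
moderate-to-high negative ideation ((20,29) ∪ (30,40)) as the adverse NSI
event. This reduction is a documented package convention; published
headline percentages for this class of analysis do not state their
derivation, and no attempt is made to reproduce specific values.

## Psychometric validation

Item blocks are checked for factorability before any factor interpretation:
Pearson correlations over listwise-complete rows; KMO from the anti-image
partial correlations q_ij = −s_ij/√(s_ii s_jj), S = R⁻¹ (verified in tests
against an independent regression-residual implementation); Bartlett's
sphericity χ² = −(n − 1 − (2p+5)/6)·ln det R with df = p(p−1)/2 and the
asymptotic χ² reference (no small-sample correction); the Kaiser criterion
(eigenvalues strictly > 1) for retention; and principal-component loadings
(eigenvectors × √eigenvalue) with varimax rotation (statsmodels'
`rotate_factors`) for k ≥ 2. PCA-plus-varimax is a design choice: the
validation stage needs a reproducible, rotation-invariant-communality
extraction, not a full common-factor model.

## Synthetic cohorts

Raw study responses are not available, so the generator produces
study-shaped data: one latent normal variable per subscale with a target
correlation matrix (default: the reported scale-level correlations among
the nine subscales, e.g. 0.558 between NSI and PI), item latents
y = λf + √(1−λ²)ε with a common loading λ = 0.7, and ordinal responses cut
at equal-mass standard-normal thresholds. Latents are correlated through
the symmetric square root of the target matrix, so any positive
semidefinite target is admissible. `ceiling_skew` shifts all thresholds
down by that many latent SDs, piling mass on the top response category to
emulate the ceiling effects seen in real scale data. Reverse-keyed items
emit the reversed raw response so that scored subscales track the latent
targets with positive sign.

Defaults are the study conditions: n = 413 respondents, the reported
correlation targets, λ = 0.7, no ceiling skew. What passing tests on these
cohorts show: the pipeline recovers the distributions it is fed, end to
end, at study scale. What they cannot show: behavior under item-level
residual structure, differential item functioning, or informative
missingness, none of which the copula generator emulates.

## Numerical choices and degenerate inputs

- KDE evaluation works in log space per kernel before summing, so far-tail
  queries underflow to 0 rather than NaN; a zero-variance coordinate is an
  error (the caller is told to jitter or widen the cohort).
- A chain started where the target is zero errors immediately, naming the
  state; after a positive start the chain provably never visits a
  zero-density state.
- Probability-table constructors enforce their invariants (joint sums to 1,
  conditional rows sum to 1, cells in [0,1]) at 1e−12 and reject violations
  rather than repairing them silently.
- Correlation matrices are symmetrized and clipped to [−1, 1] to remove
  float round-off before invariant checks; a singular matrix is an error
  suggesting ridge regularization, never applied automatically.
- Tie-break at bin cuts: `numpy.digitize` right-open convention, so a
  sample exactly at 8.5 falls in the upper bin; the choice is arbitrary and
  affects a measure-zero set of the sampler's continuous states.
- Per-pair chain seeds derive from `SeedSequence([master_seed, pair_index])`
  (kept below 2³¹), so restricting a run to a pair subset leaves the other
  pairs' chains unchanged.

## Problem sizes

Shipped analyses use the study-scale defaults: cohorts of n = 413, chains
of N = 20,000 iterations with 2,000 burn-in per pair, 14 pairs per full
run. Test-suite checks that only probe determinism or plumbing use shorter
chains (600–2,000 iterations), since the contracts they check are
length-independent; statistical checks use the full study-scale settings
(20,000–50,000 iterations, n = 10⁴ for correlation-recovery bounds).

## Known limitations

- The KDE bandwidth and kernel of the original MATLAB analysis
  (`mvksdensity`) are not published; figures produced from it are not
  expected to match pixel-for-pixel.
- Three-bin grids are coarse; cells near score boundaries mix adjacent
  score levels, and no shrinkage is applied to sparse cells.
- The conditional tables condition on the factor axis only; conditioning on
  PANSI would require transposing the pair, which the pipeline supports by
  listing the pair with axes swapped only for factor-vs-factor questions it
  does not currently expose.
- Kaiser retention is known to over-extract on large item sets; it is
  implemented as specified, not as a recommendation.
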