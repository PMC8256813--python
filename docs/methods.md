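# Methods

## Estimand and model

Both samples are modelled as i.i.d. two-parameter Weibull, X ~ Weibull(a_X,
k_X) and Y ~ Weibull(a_Y, k_Y), independent of each other.  The coefficient
of variation of a Weibull variable is a function of the shape alone,
λ(k) = sqrt(Γ(1+2/k)/Γ(1+1/k)² − 1), strictly decreasing in k (λ(1) = 1 is
the exponential case).  The estimand is δ = λ(k_X) − λ(k_Y); the scales are
nuisance parameters that drop out of every construction below.  λ is
evaluated through log-gamma differences so large shapes do not overflow;
shapes below ~0.0014, where λ itself exceeds double range, raise an
explicit overflow error.

## Maximum likelihood

The shape MLE solves the profile score F(k) = 1/k + mean(ln x) −
Σxᵏln x / Σxᵏ = 0; the scale then follows as (Σxᵏ/n)^(1/k).  We iterate
Newton–Raphson from the Menon closed-form start k_u = (π/√6)·√((n−1)/s²)
with s² the *sum* of squared deviations of the logs.  Defaults: tolerance
10⁻⁶ on |F|, at most 100 iterations, k clamped above 10⁻⁸ between steps.
The score is monotone in k (the derivative term Σxᵏ·Σxᵏz² − (Σxᵏz)² is a
Cauchy–Schwarz excess), so the iteration is stable; samples are normalized
by their geometric mean first, which is exact (the shape MLE is
scale-invariant, the scale MLE equivariant) and keeps xᵏ in double range.
Non-convergence is reported via a flag rather than an exception so that
resampling callers can apply their redraw policy; a replicate, bootstrap
resample or pivotal draw whose inner fit fails is redrawn (up to 100
attempts) and counted, keeping draw counts fixed without silently biasing
the resampling distributions.

All heavy loops fit many samples at once: the Newton iteration is
vectorized over the rows of an (R, n) matrix, which is what makes the
pivotal-quantity and bootstrap constructions and the coverage study
tractable on a single CPU.

## Interval constructions

**GCI.**  k̂/k is pivotal for the Weibull: its distribution equals that of
the shape MLE k̂* of a Weibull(1,1) sample of the same size.  A pivotal
draw is R_k = k̂_obs/k̂* with k̂* refitted to a fresh Weibull(1,1) sample;
q independent pairs (R_{k_X}, R_{k_Y}) are mapped through λ and
differenced, and the α/2 and 1−α/2 empirical quantiles of R_δ form the
interval.  The observed MLEs are constants of the data and are computed
once outside the loop.  Default q = 2500.

**Bootstrap (PB and BS).**  Both groups are resampled nonparametrically
with replacement at their own sizes; each resample contributes one draw of
the CV difference.  The per-resample CV is, by default, the empirical
moment statistic sd/mean (ddof = 1).  This choice was the one genuinely
open design decision: the reference results this package reproduces show
percentile-bootstrap coverage *decreasing* with sample size (0.9614 at
n = m = 10 down to 0.9362 at 100), which the moment statistic reproduces,
whereas refitting the Weibull MLE on every resample gives the textbook
pattern of coverage rising toward the nominal level and sits several
Monte-Carlo standard errors away from those reference cells.  The MLE
variant remains available via `statistic="mle"`.  PB takes the α/2 and
1−α/2 quantiles of the draws; BS is δ̂ ± z_{1−α/2}·SE with δ̂ the MLE
plug-in estimate and SE the standard deviation of the draws.  Default
B = 500.

**MOVER / Hendricks–Robey.**  Each group gets the CV interval
λ̂ ± t_{1−α/2, n−1}·λ̂/√(2n); the one-sided margins are recombined in
quadrature around λ̂_X − λ̂_Y.  The critical value is the upper-tail
1−α/2 quantile — the positive value; using a lower-tail "α/2 percentile"
literally would invert the interval.  This method consumes no randomness.

**Bayesian (MCMC and HPD).**  Under a′ = (1/a)^k the density is
a′k x^(k−1)exp(−a′xᵏ); with gamma(v₁, z₁) on a′ and gamma(v₂, z₂) on k
(defaults all 0.1, i.e. diffuse), a′ | k is conjugate gamma(v₁+n, z₁+Σxᵏ)
while k is updated by random-walk Metropolis targeting its exact full
conditional — likelihood × gamma prior, evaluated in log space, with
nonpositive proposals rejected outright.  The a′ conditional uses the
hyperparameters configured for the a′ prior, so non-default priors behave
correctly.  Chains start at the MLE (Menon estimator, then unit shape, as
fallbacks), a′ at its conditional mean given k, which justifies the short
default burn-in.  The proposal scale starts at 2.4× the asymptotic sd of
the shape MLE (≈1.87 k̂/√n) and, by default, is multiplicatively adapted
every 50 burn-in iterations toward a 20–45% acceptance rate, then frozen;
a fixed-scale mode (`adapt=False`, explicit `proposal_sd`) is available
for strict kernel reproducibility.  No thinning.  Defaults: 20 000
iterations, 1000 burn-in.  Per-iteration differences
δᵗ = λ(k_Xᵗ) − λ(k_Yᵗ) give the equal-tailed interval (quantiles) and the
HPD interval — the shortest contiguous window of the sorted draws
containing ⌈(1−α)N⌉ points, which is never longer than the equal-tailed
interval on the same draws.

Empirical quantiles throughout use linear interpolation of order
statistics at p(N−1)+1 (numpy's default); the convention matters only at
O(1/N).

## Simulation engine

One scenario fixes (n, m, a_X, a_Y, k_X, k_Y, α) and the tuning constants
(M replications; q, B, chain length).  Per replication the engine draws
both samples, fits the observed MLEs (redrawing the replicate if a fit
fails, with a count), builds every requested interval and accumulates the
indicator {L ≤ δ ≤ U} (boundaries inclusive) and the width U − L.
Reported: mean coverage, mean length, and binomial/empirical Monte-Carlo
standard errors.

Randomness: a master `SeedSequence` spawns one child stream for the data
plus one per method tag, in a fixed order over all six tags, so running a
subset of methods reproduces exactly the numbers of a full run.  Streams
are per-method rather than per-replicate-and-method: the isolation
property is the same and it permits the vectorized execution paths
(MOVER and the bootstrap inner loops are vectorized across resamples; the
Gibbs sampler runs all M replicate chains simultaneously as state
vectors).  The equal-tailed and HPD intervals are two summaries of the
same pair of chains and share one sampler run.

The default grid is the full study design: common scale a ∈ {0.5, 2},
k_X = 1, k_Y ∈ {0.5, 1, 2, 2.5, 4, 9} (true δ ∈ {−1.2360, 0, 0.4772,
0.5720, 0.7194, 0.8671}), eight size pairs from (10,10) to (100,100), with
M = 5000, q = 2500, B = 500, 20 000-iteration chains.  The full 96-cell ×
6-method grid at those constants is a cluster-scale computation; the
package's own verification runs single cells at full scale where cheap
(MOVER at M = 5000) and reduced scale otherwise (GCI at M = 1000,
q = 1000; PB at M = 1000, B = 300; HPD at M = 500 with 4000-iteration
chains), always comparing within three combined binomial standard errors.
A `reduced` grid mode (M = 500, q = 500, B = 200, T = 2000) exists for
desk-scale sweeps.

## Synthetic data

`sample_weibull` uses the inverse transform a·(−ln U)^(1/k), exact for any
parameter values, and `generate_fixture` writes long-format CSV plus a
JSON sidecar with the generating parameters and true δ.  The generator
emulates the study conditions exactly — i.i.d. Weibull observations at the
grid's parameter values — and therefore none of the features of real
wind-speed records (serial correlation, seasonality, measurement
truncation, mixed regimes).  Passing coverage tests consequently
demonstrates correctness of the interval constructions *under the model*,
not robustness to model misfit; the AIC/BIC screening report
(`model_fit_report`, Weibull vs exponential/gamma/log-normal, all fitted
by maximum likelihood) is the package's built-in check that the Weibull
assumption is reasonable for a given dataset.

## Known limitations

- Two-parameter Weibull only: no location shift, no censoring.
- The bootstrap default (moment CV per resample) and the MLE variant give
  noticeably different small-sample coverage; see above for why the moment
  statistic is the default.
- One printed reference value (CV 0.4441 at shape 2.3956) is internally
  inconsistent with its own shape estimate; the formula gives 0.4446, and
  the package reports the computed value.
- Very small shapes (k < ~0.006) push λ toward double-precision limits;
  the simulation grid's smallest shape (0.5) is far from that regime.
- Bayesian intervals at large shapes (k_Y = 9) and large samples mix more
  slowly; the adaptive proposal handles the tested range but acceptance
  rates should be checked when pushing beyond it.
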