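# Methods

## Model and assumptions

All estimators in this package derive from one local model: around a
sample point on a D-dimensional manifold, the fraction of points inside a
ball of radius R scales like eta(x) R^D with a slowly varying density
factor eta.  Comparing two neighborhood scales at the same point cancels
eta, giving the local two-scale estimate

    delta_k(x) = ln 2 / ln( R_2k(x) / R_k(x) ),

where R_k and R_2k are the distances to the k-th and 2k-th nearest
neighbors.  Everything analytic below additionally assumes the density is
*locally uniform* and the manifold flat at the neighborhood scale; the
Gaussian, Cauchy and sphere samplers exist precisely to probe what
happens when those assumptions fail (non-uniform density, heavy tails,
curvature).

Under local uniformity, the normalized distance r = R_k/R_2k of the k-th
among 2k-1 neighbors has density D/B(k,k) r^(Dk-1) (1-r^D)^(k-1), and the
change of variables r -> delta gives the local-estimate density

    q(delta) = D ln2 / B(k,k) * 2^(-Dk/delta) (1 - 2^(-D/delta))^(k-1) / delta^2.

The monotone substitution a = 2^(-D/delta) maps this onto a Beta(k, k)
law on (0,1).  Three consequences organize the package:

1. **Median property.**  The Beta(k,k) median is exactly 1/2, so the
   median of q is exactly D for every k, including k = 1 where the mean
   is infinite.  The sample median of local estimates (mFSA) is therefore
   the primary global statistic.
2. **Median error law.**  The median of n = 2l+1 i.i.d. local estimates
   has density [P(a)(1-P(a))]^l q(d) / B(l+1,l+1) with P(a) = I_a(k,k).
   Its standard deviation is computed by quadrature, and a
   Laplace–Stirling expansion gives the closed form
   sigma ~ kappa D / sqrt(nk), kappa = sqrt(pi)/(2 ln 2) ~ 1.27846.
3. **Likelihood.**  Treating local estimates as i.i.d. draws from q gives
   a one-parameter likelihood whose score has a unique positive root; at
   k = 1 the root is the closed form n / sum ln(R_2/R_1), identical to
   the Levina–Bickel (k = 1) estimator.

The mean aggregate is kept for reference: its expectation follows the
hyperbola E[delta_k] ~ D + a D/(k-1).  Fitting the constant by
unweighted least squares of (E[delta_k]/D - 1)(k-1) over k = 2..50 at
D = 2 gives a = 0.681 (the fit range is a convention; values across
sensible ranges agree to ~0.01).

## Bias correction (cmFSA)

On finite samples with hard boundaries the median estimate is
systematically low, increasingly so at high D.  The correction model

    D ~ C(d) = d exp( sum_l alpha_l d^l )

is linear in the alphas after taking logs: ln(D/d) = sum_l alpha_l d^l.
It satisfies C(d) -> d and C'(d) -> 1 as d -> 0 (no correction where
there is no bias) when exponents are >= 1.  Coefficients depend strongly
on sample size n and neighborhood size k, so calibration always runs at
the working (n, k), on uniform hard-boundary hypercubes with integer
dimensions spanning the range of interest, at least 15 realizations each.

Two fitting conventions are implemented: `ols_all` (ordinary least
squares pooling every realization-level pair; with the single exponent
{1} this reproduces the closed form alpha = sum(ln E_i d_i)/sum(d_i^2)
exactly) and `odr_means` (unweighted orthogonal distance regression on
the per-dimension means of ln(D/d), via scipy.odr).  Default exponent
sets: {1} for the narrow regime D = 2..30; {-1, 1, 2, 3} for the wide
regime D = 2..80.

Per-dimension residual statistics (mean and sd of the post-fit log
residual ln(D/C(d))) are stored in the model.  The *ideal error rate* —
the probability that the corrected estimate rounds to the wrong integer
if residuals are normal in log space — maps those statistics to the
corrected estimate's mean and sd through the exact lognormal moments and
evaluates 1 - [Phi((D+1/2-mu)/sigma) - Phi((D-1/2-mu)/sigma)].

The correction inherits the calibration family's assumptions: it absorbs
finite-sample and edge effects of *uniform, flat* data and is known to
overcorrect on curved (spheres) or non-uniformly sampled (Gaussian,
Cauchy) manifolds.  Applying a model outside its calibrated (n, k) or
dimension range warns rather than fails.

## Geometry and numerics

* Distances are Euclidean.  The periodic ("circular") convention uses the
  per-coordinate minimum image on the unit torus, implemented with a
  cKDTree with unit boxsize; it requires coordinates in [0,1) and rejects
  anything else rather than wrapping silently.  Hard-boundary search uses
  a KD-tree in low ambient dimension and a BLAS-backed brute-force scan
  above 12 dimensions.  Search is always exact: the estimator divides
  consecutive order statistics, which approximate neighbors corrupt.
* Degenerate radii: R_k = R_2k gives delta = +inf; R_k = 0 < R_2k
  (duplicate points) is flagged, counted, and also mapped to +inf so the
  median stays usable; R_2k = 0 is an error.  The median of an even
  count is the midpoint of the central order statistics.  Non-finite
  local estimates are a hard error in the likelihood path, where q is
  undefined.
* All improper integrals over delta in (0, inf) are computed after the
  a-substitution onto (0,1), which removes the heavy tail; the median
  sampling density is evaluated in log space (betaln) because its
  combinatorial factor and bracket term under/overflow separately for
  n >~ 700.  Quadrature tolerances are 1e-10 relative.
* The likelihood root is bracketed on [1e-6, 10 * median(delta)] with
  doubling expansion and solved by Brent's method; the k = 1 closed form
  is a separate code path and doubles as a regression check.

## Synthetic data

The samplers generate the study conditions the estimators are validated
under: uniform [0,1)^D hypercubes (hard or periodic), standard D-variate
normals, Cauchy-norm clouds (uniform direction times |standard Cauchy|
radius — the stated radial density on u > 0 is normalized to the
half-Cauchy), uniform sphere surfaces (intrinsic D, ambient D+1), and a
chaotic logistic map z driven by two independent logistic maps (growth
rates 3.99, couplings 0.3, states wrapped modulo 1; an unwrapped variant
is available since the periodicity can be read as a property of either
the state or only of the embedded-space distances).  The burn-in default
is 1000 steps.  Delay embedding emits E coordinates
[x(t), x(t-tau), ..., x(t-(E-1)tau)].

These generators emulate idealized geometry only: no observational
noise, no varying local ID, no realistic autocorrelation structure
beyond the logistic map.  Tests passing on them demonstrate correctness
of the estimators under their stated assumptions, not robustness on
noisy laboratory recordings.

## Problem sizes and reproducibility

Heavy computations are sized for a desk run: benchmark means use 100
realizations of n = 2500 points at k = 5; the wide calibration uses
every second integer dimension in 2..80 with 15 realizations.  The whole
test suite runs in about a minute and `scripts/acceptance.py` in about
one more.  Every stochastic routine takes an explicit seed and spawns
child seeds via `numpy.random.SeedSequence`; identical seeds give
bit-identical clouds, models and reports.

## Known limitations

* The analytic theory assumes i.i.d. local estimates; on a real cloud
  neighboring estimates share neighbors and are dependent, so
  goodness-of-fit against q is only approximate at finite n.
* The standard-error slope of the median versus sample size is -1/2 only
  asymptotically; at k = 1 the n = 11 point is inflated by the heavy
  right tail of the median law, steepening a three-point log-log fit
  over n in {11, 101, 1001} to about -0.56 (at k >= 11 the same fit
  gives -0.50).
* cmFSA extrapolates poorly outside its calibrated dimension range and
  overestimates on curved or non-uniformly sampled manifolds.
* No curvature-, density- or noise-aware corrections are attempted.
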