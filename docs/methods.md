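# Methods

## The problem and the model

Household-well arsenic surveys give scattered point measurements C(xᵢ) in
µg/L with four awkward properties: strong right skew (sample skewness can
approach 9–10 with means near 12 µg/L but maxima in the hundreds),
approximate log-normality, spatial correlation over roughly 10–15 km, and
left-censoring at the laboratory detection limit (0.9 µg/L here), with
non-detects recorded at half the limit (0.45 µg/L).  All modelling is
therefore done on Z = log₁₀ C.  Base 10 is fixed throughout: the typical
fitted sills of ~0.06 (log units)² are consistent with log₁₀ variability of
a 0.45–776 µg/L concentration range, and a single documented base makes the
back-transform unambiguous.

Two interpolators estimate Z on a regular cell-center grid:

1. **Ordinary kriging.**  Under second-order stationarity the spatial
   dependence is the semivariogram γ(h); the method-of-moments estimate is
   computed pair-by-pair on lag bins and fitted with a bounded model
   (spherical / exponential / Gaussian, all in the "practical-range"
   3h/a parameterisation).  The OK weights solve the augmented system with
   the unbiasedness constraint Σλ = 1.
2. **Coordinate-regression network (BPNN).**  A feed-forward net
   (2 inputs → 1–2 tanh hidden layers → linear output) trained by
   full-batch Levenberg–Marquardt on (x, y) → Z.

Model selection between the two is by three-fold cross-validation on a
concentration-ordered split, scored by R² = 1 − SSE/SStot and RMSE.

## Conventions and numerical choices

* **γ(0) ≡ 0.**  The nugget applies only at h > 0, so OK reproduces the
  measured value exactly at every sampled location.  Duplicate coordinates
  (which make the OK matrix singular) are averaged into one sample with a
  warning; zero-lag pairs are excluded from the empirical variogram bins —
  they estimate the nugget, not a positive lag.
* **Variogram binning defaults**: max lag = half the maximum pairwise
  distance, 15 equal-width bins, bins with fewer than 30 pairs dropped; the
  reported lag of a bin is the mean pair distance within it.  These are
  ordinary geostatistical desk practice, configurable per call.
* **Variogram fitting**: trust-region nonlinear least squares weighted by
  pair counts (weights normalised, so scaling all counts by a constant
  changes nothing), bounds c₀ ≥ 0, c > 0, a > 0, restarted from 5 range
  values spread log-uniformly across the lag span to escape nugget/range
  local minima.  A flat empirical variogram leaves the range unidentifiable;
  the fit then returns the constant as the sill with
  `range_identifiable=False` instead of a spurious range.
* **Kriging solve**: one LU factorization of the (M+1)×(M+1) augmented
  system per sample configuration, back-substituted for every target (the
  matrix is symmetric indefinite by construction); on failure the sample
  block diagonal gets a 1e-12 jitter before erroring out.  All samples are
  used at every target (global neighborhood): at survey scale (≲1000 wells)
  this is cheap and avoids search-neighborhood artifacts.  Tiny negative
  kriging variances (roundoff) are clipped to 0.
* **Back-transform**: concentration maps are 10^Z with no lognormal-kriging
  bias correction.  This is a deliberate, documented simplification — the
  median-type estimate is conservative relative to the lognormal mean; both
  interpolators are treated identically so the comparison is fair.
* **Network conventions**: neuron input is netⱼ = Σᵢ XᵢWⱼᵢ − bⱼ (bias
  subtracted — kept exactly in this form so serialized parameters have one
  meaning); weights and biases initialize uniform in [−1, 1]; hidden
  activation tanh, output linear.  Raw coordinates in meters would saturate
  tanh, so inputs are affinely scaled by the centroid and half-extent of the
  training data; the scaling constants are stored with the model and applied
  transparently at prediction.
* **LM schedule**: λ₀ = 10⁻³, factor 10, λ capped at 10¹² (overflow raises
  a divergence error carrying the best parameters), max 1000 epochs,
  convergence at training mse ≤ 10⁻² (log₁₀ units²).  Accepted steps never
  increase the SSE by construction.  Training restarts (default 3) keep the
  best run by training mse and stop early once a run reaches the mse goal —
  by the stopping rule, such a run is already "trained".
* **Architecture search space**: first hidden layer even sizes 2–50,
  optional second hidden layer even sizes 2–50; the search trains each
  candidate on every fold pair and ranks by average validation R², ties by
  validation RMSE.  A fold where training diverges is a NaN cell; a
  candidate is disqualified only if every fold fails.  The default
  production structure is (2, 10, 10, 1).
* **R² definition**: 1 − SSE/SStot, not squared Pearson correlation — the
  predictive coefficient of determination, which can be negative for a
  predictor worse than the mean.  Metrics are computed on the log₁₀ scale on
  which both models are fitted.
* **Ordered split rule**: sort by descending concentration, break ties by
  well id, deal round-robin to A, B, C.  Sizes differ by at most one (921
  wells → 307/307/307) and per-set means agree within sampling error.
  Censored records participate at their substituted value 0.45 — survey
  summary statistics plainly include them.
* **Risk formulas**: DI = C·IR/BW, HQ = DI/RfD,
  TR = DI·(EF·ED/AT)·CSF·10⁻³, with C always in µg/L from the
  back-transformed map, never a log value.  Defaults: IR 1.4 L/day, ED 30 yr,
  EF 365 day/yr, BW 64.5 kg, AT 79.0 × 365 = 28 835 days, RfD 0.3 µg/kg·day,
  CSF 1.5 (mg/kg/day)⁻¹.  Boundary conventions, chosen once and kept
  configurable: TR exactly 10⁻⁶ or 10⁻⁴ is level 2 ("between" read
  inclusively); HQ exactly 1 is acceptable (the adverse flag requires
  strictly > 1); exactly 50 µg/L is still suitable for irrigation and
  aquaculture.  The four concentration classes are the half-open,
  lower-inclusive bands [0,5), [5,10), [10,50), [50,∞) µg/L — the only
  reading of the conventional <5/5–10/10–50/>50 class list that partitions
  the line.
* **Grid**: 1 km × 1 km cells by default, lower-left anchored, cell-center
  sampling, extent = bounding box of the wells padded by one cell (ceiling
  rule on cell counts), optional mask polygon, NODATA −9999 in ESRI ASCII
  output.

## The synthetic-data generator

`synthetic.simulate_gaussian_field` draws one realization of a Gaussian
random field of Z with covariance derived from a variogram model
(C(0) = c₀ + c; C(h) = c − (γ(h) − c₀) for h > 0, i.e. the nugget is
spatially uncorrelated noise), by dense Cholesky factorization with a 1e-10
diagonal jitter — exact at desk scale (≤ ~2000 points), which is why no
spectral machinery is used.  `sample_wells` back-transforms to µg/L and
applies the censoring rule (C < 0.9 → recorded 0.45, flagged).

The default study conditions (`survey_like_spec`) emulate a Lanyang-Plain-
type survey: exponential variogram with nugget 0.015, partial sill 0.05,
range 15 km; field mean log₁₀(0.89) so the median concentration sits at
0.89 µg/L and about half the records are non-detects; 30 km × 20 km extent.
Well locations are uniform over the extent by default, with an optional
clustering factor — the spatial design of real household-well surveys is
rarely published, and uniform placement is the testable default; no claim is
made that it matches any particular survey.

What the generator does *not* emulate: non-stationarity (coastal/inland
trends, aquifer-boundary effects), anisotropy, measurement-protocol
variation between campaign years, and the extreme tail behaviour that drives
real skewness to ~9 (a stationary log-normal field with sill 0.065 yields
skewness ~2–4).  Tests passing on these fields therefore demonstrate
algorithmic correctness and sane statistical behaviour, not that either
interpolator is adequate for any particular real aquifer.  On such fields
kriging is the optimal linear predictor by construction, so the network
winning or losing the comparison here says nothing about real data, where
nonlinearity and non-stationarity can reverse the ordering.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise every code path
with comfortable statistical power: oracle comparisons at n ≤ 50 wells and
≤ 10 kriging samples; variogram parameter recovery on 30 independent
500-well fields (median fitted sill within 30% of truth, median range within
50% — lag binning and finite extent bias single-survey variogram fits, which
is exactly why the tolerance is generous and the statistic a median); the
end-to-end comparison on ten 600-well fields with sill ≫ nugget, requiring
only that both methods show positive average validation R² and land in the
same error regime, not any fixed number.

## Known limitations

* No lognormal-kriging (or any) back-transform bias correction; concentration
  surfaces are median-type estimates.
* Isotropic variograms only; no nested structures, no maximum-likelihood
  variogram estimation.
* Censored values enter all fits at the 0.45 µg/L substitution value; no
  likelihood-based treatment of censoring.
* The network offers no regularization beyond the mse stopping criterion;
  with very wide layers and tiny goals it will overfit by design, which the
  cross-validation is there to expose.
* Exposure assessment covers the ingestion route with point-valued
  parameters; no dermal/inhalation routes and no probabilistic (Monte
  Carlo) exposure analysis.
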