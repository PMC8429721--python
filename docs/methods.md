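# Methods

This note documents the statistical procedures implemented in `aridishift`,
the choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Indices

**Averaging multifunctionality.** Each soil function is log10-transformed
(all seven nutrient-pool functions are flagged for log10 by default, as are
elevation and plant species richness wherever they enter a model) and
Z-scored with the sample (n−1) standard deviation; the index is the row mean
of the Z-matrix.  Zero-variance columns raise an error naming the column
rather than silently producing NaN.  The simplified variant drops total N
(redundant with DNA concentration and organic C) and total P (dominated by
abiotic weathering) and averages the remaining five Z-columns.

**Multiple-threshold analysis.** The maximum level of each function is the
mean of its four largest observed values.  For each threshold t ∈ {1..99}%
the per-site multifunctionality is the number of functions *strictly*
exceeding t × maximum ("surpassing" is read as strict; ties do not count).
The count is regressed on the diversity metric by OLS at each threshold.
`Tmin`/`Tmax` are the lowest/highest significant thresholds, `Tmde` the
significant threshold with the steepest slope; `Mmin`/`Mmax`/`Mmde` are the
fitted counts at the maximum observed diversity at those thresholds — the
framework's one-line gloss ("the number of functions achieving at the
respective thresholds") is resolved this way and is configurable in
principle by recomputing from the returned per-threshold regressions.
Ordinary rather than count regression is used at each threshold; with seven
bounded counts per site the practical difference is negligible and the
linear slope is the index the summary statistics are defined on.

**Aridity classification.** Dryland subtypes are half-open upward intervals
with boundaries 0.35, 0.50, 0.80, 0.95 on the aridity (= 1 − AI) scale; 0.50
and 0.95 follow the UNEP aridity-index convention (AI 0.2 and 0.05), 0.35 is
the dryland onset and 0.80 the semiarid/arid boundary.

## Change-point protocol

A threshold is declared for a response series only when (1) a nonlinear
trend model (quadratic or GAM) beats the linear fit by more than 2 AIC
units, and (2) bootstrap validation at the fitted break passes.  The
modality of the gradient variable is always screened (one- vs two-component
Gaussian mixture by BIC, five seeded restarts) and reported, but it does not
veto detection by default: survey designs that allocate sites over climate
bands are legitimately multimodal in x, and a mixture fit to a uniform or
banded design routinely "prefers" two components without invalidating the
change-point regressions.  A `modality_gate` option restores the veto.

**Trend AIC.** All AICs use the Gaussian log-likelihood with the ML variance
(SSE/n), counting mean-model parameters plus one for the residual variance.
The GAM is a penalized cubic B-spline on uniform (Eilers–Marx) knots with a
second-difference coefficient penalty, whose null space then corresponds
exactly to linear functions — at infinite penalty the smoother reproduces
the OLS line, so the GAM can never spuriously undercut the linear AIC by
basis artifacts.  The smoothing parameter is selected by REML through the
mixed-model representation of the penalty; REML is the default because
plain GCV undersmooths often enough at n ≈ 130 to prefer a wiggly fit on
truly linear data well above the nominal rate (GCV with the mgcv-style
γ = 1.4 inflation remains available).  The effective degrees of freedom
(trace of the hat matrix) enter the AIC as the parameter count.

**Change-point fits.** Candidate break locations are midpoints between
consecutive distinct sorted x values with at least `min_side = 5` points per
side (midpoints avoid ties in side assignment).  At each candidate the
coefficients are estimated by OLS and the global SSE minimizer is returned;
because candidates are midpoints, a noiseless planted kink is recovered to
within one grid gap, not exactly.  The AIC parameter count includes the
break location itself plus the residual variance, following common
change-point practice.  Segmented winners are reported as *continuous*
thresholds, step/stegmented winners as *discontinuous*.  Among the three
forms, ΔAIC ≤ 2 ties resolve to the form with fewer parameters.

**Validation.** B bootstrap resamples are drawn independently within each
side of the break; per-resample OLS slopes and fitted values at the break
are compared across sides with two-sided Mann–Whitney U tests, and the break
is validated when both P < 0.05 and both side contrasts exceed numerical
noise (a 1e−9 relative floor — rank tests otherwise separate
machine-precision dust).  An important caveat, deliberate and documented:
the Mann–Whitney step treats bootstrap draws as independent samples, which
they are not, so it is *descriptive* — under a sampling-noise null with no
real break it can still flag differences far above the nominal rate.  The
protocol's null safety (no threshold declared on null data in ≥ 90% of runs,
measured) is carried by the ΔAIC gate, not by this step.

## Mixed models

The fixed-term sequence follows the reported-table convention: main effects
first (year, plant richness, microbial index, aridity, BNPP, pH, clay,
elevation, latitude, longitude), the three interactions last; the simplified
model keeps year, the two diversity terms, aridity, the two aridity ×
diversity interactions, and the three-way product.  Year enters as a numeric
covariate.  Response and continuous predictors are Z-scored *within the
fitted subset* (required for comparable standardized estimates in region
splits and windows); interactions are products of the standardized mains,
not re-standardized.

**Estimation.** The two crossed random intercepts (soil type, vegetation
type) give `Var(y) = σ²(I + γ_s Z_s Z_sᵀ + γ_v Z_v Z_vᵀ)`.  β and σ² are
profiled analytically; the variance ratios are optimized by Nelder–Mead on
the log scale with an explicit boundary pass that re-tests every pattern of
components pinned at zero (REML solutions frequently sit on the boundary,
which a log-scale search can only approach).  All solves go through the
Woodbury identity in the factor-level space, which also powers a fully
vectorized bootstrap.  The implementation is cross-checked against
statsmodels `MixedLM` in the test suite.

**Inference.** Sequential (type-I) F statistics come from a QR
decomposition of the V̂-whitened design; each 1-df term's denominator df is
a Satterthwaite approximation computed from numerical gradients of the
contrast variance and the numerical Hessian of the restricted
log-likelihood in (σ², σ_s², σ_v²).  Marginal and conditional R² follow the
fixed-vs-total variance decomposition (Nakagawa); VIFs come from the inverse
correlation matrix of the design and are flagged at ≥ 10.  A fit is
*singular* when any random-intercept variance falls below 1e−8; the
offending term is dropped and the model refit (a positive boundary-away
variance estimate on data simulated with zero group variance is a correct
REML answer, not a singularity).  Wald intervals are used throughout;
measured coverage at n = 500 is nominal (≈ 95%).

## Moving-window analysis

Sites are sorted by aridity (ties broken by site id) and windows of
w = 60 consecutive sites advance one site at a time: n − w + 1 windows, i.e.
one initial window plus n − w repeats.  Within each window the simplified
model is fit by REML (singular random terms dropped per the rule above) and
the standardized coefficients are bootstrapped by resampling sites with
replacement — design-based resampling, with random-term labels riding along.
Per resample the fixed effects are re-estimated by GLS with the window's
variance ratios held fixed; the variance components are not re-optimized
inside each resample because they are weakly identified in a 60-site window,
the bootstrap targets the fixed coefficients, and the fixed-ratio refit is
stable and fully vectorizable.  Windows where more than 20% of resamples
fail are flagged unusable rather than silently skipped.  A term is
significant in a window when the bootstrap tail probability of a sign flip
against its median is ≤ 0.05 (one-sided, direction from the median's sign).
Trajectories of per-window medians, indexed by window-mean aridity, are
smoothed with the P-spline GAM and screened with `detect_threshold`.

Window geometry matters for interpretation: with 54 of 130 sites below the
0.80 break and w = 60, *every* window except the last ~17 contains the
break.  A piecewise-constant planted coefficient therefore appears in the
window sequence as a ramp (the window estimate is roughly the
above-fraction-weighted mixture of the two regimes), the main-effect
trajectory has its sharpest curvature where below-break sites run out
(window-mean aridity ≈ 0.85), and the interaction term — which measures the
within-window aridity-dependence of the diversity effect — is nonzero
exactly in break-containing windows and peaks near the break.  The
interaction trajectory is accordingly the sharpest localizer of the planted
break and the one used for the end-to-end recovery check.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any real landscape: aridity drawn uniformly within each subtype band
(12/42/56/20 sites), log-normal integer richness declining with aridity
(plant decline steeper than microbial), guild richness binomially nested in
fungal richness, seven log10-scale function columns of the form
`g_j(aridity) + β_p(a)·z_plant + β_m(a)·z_mic + u_soil + u_veg + ε_j`, with
equicorrelated noise (default pairwise correlation 0.5), one random
intercept drawn per label and reused across sites, and the planted
coefficient profile switching at aridity 0.80 (half-open: the boundary site
takes the high-aridity values).  Default planted values — plant 0.35 → 0.0,
microbial −0.15 → +0.40, residual SD 0.25 — were chosen once so the shift is
detectable at n = 130 with the field design's window size; the decline
defaults (pre/post log10 slopes about −0.2/−3.0 at per-function breaks
0.59–0.96, nitrate and total P near-flat) make single-function nonlinearity
reliably detectable.  Planted β are expressed on the log10-function scale
per SD of the standardized diversity predictor; Z-scoring the functions
rescales recovered standardized coefficients by a positive factor,
preserving signs, significance patterns, and break locations — exact
recovery is therefore asserted on the latent (decline-removed) scale.

What the generator does *not* emulate: spatial autocorrelation (lat/lon are
bookkeeping covariates), sequence-level structure (no OTU tables or
rarefaction), measurement error in aridity, and real covariance between
design covariates and functions beyond the planted structure.  Passing
tests therefore demonstrate that the pipeline recovers known structure under
its own model assumptions — not that those assumptions hold in any field
dataset.

The microcosm generator produces 10 moisture levels × 3 replicates with
moisture content tracking % field capacity (27.6% at 100%), a negative
quadratic richness response peaking near 60% field capacity, process rates
rising with moisture but depressed at 120% (waterlogging), and a
diversity → function coupling three times stronger at ≤ 20% field capacity,
the dry-regime analogue of the field shift.

## Numerical choices and limitations

- Deterministic given seeds everywhere; the pipeline splits one top-level
  seed into per-stage and per-window streams via `SeedSequence.spawn`.
- Grid searches return the first SSE minimizer on ties; candidate sets are
  data-dependent (midpoints), so change points are resolved only to grid
  precision.
- The problem sizes used by the tests and the acceptance script (bootstrap
  B = 50–200 for simulation sweeps, 100–200 replicates for rate estimates)
  are the package's chosen defaults for routine verification; the analysis
  functions accept larger B (the conventional 500) for reported results.
- Single change point per series by design; no Bayesian change-point
  machinery; no SEM stage (regional conclusions are carried by the split
  regressions and mixed models).
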