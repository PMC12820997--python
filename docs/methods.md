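# Methods

This note documents the statistical models, estimators, and design choices
behind `piezospt`, a pipeline for analyzing the mobility of fluorescently
tagged membrane-protein puncta (e.g. PIEZO1) from single-particle-tracking
(SPT) data, together with the synthetic-data generators used to validate it.

## Trajectory model and conventions

A trajectory is a time-ordered sequence of 2D positions **x**₁…**x**_N in
micrometers at a fixed frame interval Δt (default 0.1 s). Frames the tracker
skipped are kept as NaN placeholder rows, so frame indices stay contiguous
and every lag time is well defined. Pixel centers sit at integer
coordinates; micron coordinates are pixel coordinates × 0.1092 μm/px, the
camera's effective pixel size at the magnification the pipeline targets.
Trajectories shorter than 20 s (200 frame slots at 10 Hz, counted
inclusively of gaps) are discarded — short tracks do not sample their
step-length distribution well enough for the mixture analysis below.

## TAMSD and anomalous diffusion

The time-averaged mean-squared displacement of one trajectory at frame lag
n is

    TAMSD(nΔt) = (1 / P_n) Σ_k |x_{k+n} − x_k|²,

summing over the P_n index pairs whose endpoints are both observed. With no
gaps P_n = N − n, the classical estimator; with gaps the valid-pair
denominator keeps the estimator unbiased under missingness. Lags with no
valid pair are flagged undefined and excluded from fits.

Diffusive behavior is summarized by the power law TAMSD(Δ) = K_α Δ^α,
fitted by OLS on (log lag time, log TAMSD). α < 1 is subdiffusion, α = 1
Brownian motion (with 2D MSD 4DΔ and per-axis step variance σ² = 2DΔt),
α > 1 superdiffusion. Two lag ranges are used: frame lags 2–4 for
fixed-cell calibration (lag 1 is the most noise-dominated, and noise-only
curves are flat so a short range suffices) and frame lags 1–20 for
live-cell trajectories.

The ensemble-averaged TAMSD is the per-lag arithmetic mean over
trajectories. Localization noise adds an approximately flat floor ε = 4σ²
to every TAMSD curve, which biases fitted exponents toward 0; the ensemble
exponent estimator therefore subtracts ε from the ensemble-averaged curve
before the log–log fit (lags driven non-positive are dropped with a
warning). The width of the underlying exponent distribution is estimated
as sqrt(max(0, var(α̂) − var_sampling)), where var(α̂) is the empirical
variance of per-trajectory fits and var_sampling — the scatter a
homogeneous ensemble would show purely from finite trajectory length and
noise — is measured by refitting exponents on a matched simulated
fractional-Brownian ensemble (same trajectory count and length, Δt, lag
range, the fitted mean α and K_α, and noise matching ε). This
matched-simulation variance subtraction is this package's concrete
implementation of noise-and-heterogeneity correction and is labeled as
such in output metadata. The 95% CI on the mean exponent is a
trajectory-level percentile bootstrap (1000 resamples, seeded).

On the standard validation fixture (300–400 fractional-Brownian walkers,
α = 0.5, 200 points, noise floor at ε) the corrected mean recovers the
true exponent within ±0.05 while the naive mean of per-trajectory fits is
biased low; the test suite asserts the correction strictly reduces the
absolute bias.

## Fixed-cell calibration

Puncta in paraformaldehyde-fixed cells cannot move, so their apparent
motion is pure localization noise: i.i.d. isotropic 2D Gaussian with
per-axis SD σ, giving a flat TAMSD at 4σ² and expected exponent ≈ 0.
Calibration identifies the noise-consistent subpopulation and reads off
two quantities:

1. **Exponent selection.** A two-component Gaussian mixture (EM, 20
   restarts, tol 1e-8, seeded) over per-trajectory exponents; members of
   the lower-mean component (posterior ≥ 0.5) are kept.
2. **K_α selection.** A two-component semiparametric mixture over log K_α:
   component densities are responsibility-weighted Gaussian kernel density
   estimates (Silverman bandwidth), the E-step draws responsibilities from
   them and the M-step reweights. The lower-mean component is kept. K_α is
   handled on the log scale because it is positive and right-skewed.
   For both stages, when the two fitted components overlap so heavily that
   the sample is effectively unimodal (Ashman's D < 2) there is no
   subpopulation to discard and the whole sample is retained; on
   noise-only simulations this keeps ≥ 90% of trajectories, as it should
   when the immobility assumption holds.
3. **Localization error.** ε is the K_α coordinate of the mode of a joint
   (log K_α, α) Gaussian KDE over the retained trajectories, evaluated on
   a 256×256 grid padded by 3 bandwidths per axis; ties break toward lower
   K_α. On simulated fixed cells ε recovers 4σ² within ~15% and scales as
   σ² exactly.
4. **Mobility threshold.** The 95th percentile (linear-interpolation
   quantile) of the retained trajectories' scaled radius of gyration.

## Scaled radius of gyration and classification

For an observed trajectory, Rg is the RMS distance of the non-gap
positions from their centroid and ⟨r⟩ the mean length of steps between
consecutive non-gap frames (steps spanning a gap are excluded — they
conflate several physical displacements). The scaled radius of gyration is

    sRg = sqrt(π/2) · Rg / ⟨r⟩.

For positions that are pure i.i.d. isotropic Gaussian noise,
Rg/⟨r⟩ → sqrt(2/π), so sRg ≈ 1 *independent of the noise magnitude* —
the property that makes the statistic calibratable across imaging
conditions. The finite-N mean is sqrt(1 − 1/N) ≈ 0.9975 at N = 200,
comfortably inside the ±0.02 band the validation checks. Trajectories with
sRg above the calibrated threshold are labeled mobile; the boundary and
degenerate cases (all points identical) are labeled immobile. By
construction, classifying an independent noise-only ensemble against its
own calibration labels ≈ 5% mobile.

## Mobile-class heterogeneity

**Ensemble level.** Each mobile trajectory's step components are scaled by
their own per-axis RMS (so the scaled RMS is exactly 1), removing
per-trajectory diffusivity, and pooled across both axes and all
trajectories. If every trajectory were a homogeneous Gaussian walker the
pooled sample would be standard normal; the analysis fits a single
Gaussian (sample mean/variance MLE) and a two-component Gaussian mixture
(EM, seeded restarts) and compares log-likelihoods. Because the single
Gaussian is nested in the mixture, the mixture's reported likelihood is
floored at the equal-components solution when EM lands in a worse local
optimum.

**Trajectory level.** Step lengths r = |Δx| are modeled as a k-component
Rayleigh mixture, p(r) = Σ p_i (r/σ_i²) exp(−r²/2σ_i²), the natural model
when each step is drawn from one of k latent mobility states with
stationary mixing proportions (i.i.d. per step, not Markov-persistent).
EM uses the closed-form M-step σ_i² = Σ γ r²/(2Σ γ) and quantile-spread
initial σ's with seeded jitter over 10 restarts; the log-likelihood is
asserted non-decreasing at every iteration, and the k = 1 case is the
closed-form MLE σ² = Σr²/2n. Orders k = 1..4 are compared by
AIC = 2(2k−1) − 2 log L̂ (k sigmas + k−1 proportions), with a parsimony
rule: starting from the minimum-AIC model, step down to the next-simpler
model whenever its AIC is within 4 units. Components map to apparent
diffusion coefficients D_i = σ_i²/(2Δt); slow/fast labels follow ascending
σ. Population structure is summarized as joint KDEs of (proportion,
log₁₀ D) per state, including the fraction of slow-state D values below
the noise-equivalent D = ε/(4Δt).

On simulated two-state walkers (σ = 0.03/0.10 μm, p = 0.5, 200 steps) the
k = 2 fit recovers all three parameters with median error well under 10%,
and ~90–98% of trajectories select k = 2.

## Treatment comparisons

Treatment effects on the mobile/immobile partition are session-stratified
2×2 contingency analyses. With matched same-session controls the common
odds ratio is Mantel-Haenszel, OR = Σ(a_i d_i/n_i)/Σ(b_i c_i/n_i), with
the Robins-Breslow-Greenland variance for the 95% CI and the MH chi-square
(1 df, no continuity correction) for the p value. When controls come from
other sessions, each treated session's OR is taken against the pooled
control and combined as a log-OR mean weighted by session treated counts;
the delta-method variance treats the pooled-control term as perfectly
correlated across sessions (it is the same random quantity), which seeded
coverage experiments confirm gives ≥ 93/100 CI coverage at a true OR of
1.5. The Haldane +0.5 correction is applied only to sessions with a zero
cell, never globally.

## Detection and linking

Movies are processed per frame: a difference-of-Gaussians bandpass
(σ = 1 and 3 px defaults), a threshold (explicit, or mean + k·SD of the
DoG frame as a reproducible stand-in for manual selection), 8-connected
components as candidate particles, and a symmetric-2D-Gaussian least
squares fit on a raw-image patch (radius ⌈3σ_small⌉) around each
component's peak for the sub-pixel centroid, falling back to the
intensity-weighted centroid (flagged) on failure. Linking is greedy:
candidate pairs between consecutive frames within 3 px are accepted in
ascending-distance order (which also makes the result independent of
detection order), tracks missing ≤ 1 frame continue across a NaN
placeholder, longer absences terminate the track. Global assignment and
multi-frame gap policies beyond the configurable bound are deliberately
out of scope. A density diagnostic reports per-frame nearest-neighbor
distances and the fraction of frames where the median falls below twice
the link radius — the regime where identity switches become plausible. On
rendered benchmark movies (SNR 20, spots ≥ 4 PSF widths apart) the chain
recovers every simulated track with localization RMSE < 0.15 px.

## Synthetic-data generators

The generators produce exactly the statistical structure the estimators
assume, each seeded and carrying a ground-truth channel:

- *immobile*: fixed position + i.i.d. isotropic Gaussian noise (default
  study condition σ = 0.02 μm, a typical localization precision for
  bright fluorophores at 10 Hz);
- *Brownian*: per-axis increments with variance 2DΔt;
- *fractional Brownian*: fractional Gaussian noise via exact Cholesky
  factorization of the fGn covariance — trajectories are ≤ a few hundred
  points, so exactness is preferred over approximate spectral methods —
  scaled so the 2D MSD is K_α Δ^α; α = 1 reduces to Brownian;
- *two-state*: per-step σ drawn i.i.d. from {σ_slow, σ_fast}, matching
  the stationary-mixture step model exactly;
- *gaps*: interior points dropped i.i.d. (endpoints preserved);
- *movies*: Gaussian PSF spots (σ = 1.3 px) on constant background with
  additive Gaussian noise, 16-bit, plus a pixel-coordinate truth table.

Standard validation sizes are 200-point trajectories in ensembles of
300–1000, sized so closed-form expectations are resolved within the stated
tolerances while the full suite runs in minutes on one CPU.

What the generators do **not** emulate: Markov-persistent state switching,
confined/corralled diffusion, photobleaching and blinking, Poisson photon
noise, drift, and spatially varying background. Passing tests therefore
demonstrate correctness of the estimators under the stated models, not
robustness to every artifact of real microscopy; in particular the
detection benchmark's additive-Gaussian noise is kinder than real shot
noise at low signal.

## Numerical choices and degenerate inputs

- EM settings: calibration GMM 20 restarts / tol 1e-8 / 500 iterations;
  Rayleigh mixtures 10 restarts / tol 1e-8 / 500 iterations; all seeded.
- A Rayleigh component supported by fewer than one expected step
  (p_i < 1/n) or a collapsed σ triggers a refit at k−1.
- Power-law fits refuse ranges with < 2 usable lags; zero/undefined TAMSD
  values are dropped from the range rather than imputed.
- sRg of an all-identical-point trajectory is undefined and classified
  immobile-degenerate.
- Sub-noise removal drops trajectories whose *median* TAMSD over the
  fitted lag range is below ε (the summary choice is logged); the
  threshold comparison is ≥, so ε = 0 removes nothing.
- The localization-error estimate always comes from calibration input;
  no literature value is hard-coded.
- Quantiles are linear-interpolation; KDE bandwidths are Silverman
  (1D) / Scott (2D, scipy default); CI quantiles use the exact normal
  0.975 point.

## Known limitations

- The greedy linker can mis-assign in dense fields; the id-switch
  diagnostic flags, but does not correct, that regime.
- The matched-simulation width correction assumes fractional Gaussian
  motion is an adequate homogeneous reference; strongly non-Gaussian
  heterogeneity would be attributed partly to width.
- The kernel-mixture selection's Ashman-D unimodality guard is a
  pragmatic bimodality test; samples with heavy one-sided tails may
  retain slightly more than intended.
- The weighted odds-ratio combination against a pooled control is one
  declared interpretation of count-weighted pooling; it is flagged in the
  output metadata so downstream users can substitute their own.
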