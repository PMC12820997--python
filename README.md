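# piezospt

Single-particle-tracking (SPT) analysis of fluorescently tagged
membrane-protein puncta — built around the workflow used to study PIEZO1
channel mobility in TIRF movies, and validated end to end on seeded
synthetic data.

Membrane proteins imaged as diffraction-limited spots show wildly
heterogeneous mobility: some puncta are immobile (their apparent motion is
pure localization error), and the mobile ones are typically subdiffusive
and switch between mobility states. This package implements the full
analysis chain for quantifying that heterogeneity:

- **Detection & linking** — difference-of-Gaussians bandpass, threshold,
  connected components, sub-pixel 2D-Gaussian centroids, greedy 3-px
  frame-to-frame linking with gap placeholders, 20-s minimum-duration
  filter.
- **TAMSD** — the time-averaged MSD, `TAMSD(nΔt) = (1/P_n) Σ_k |x_{k+n} −
  x_k|²` with a gap-aware valid-pair denominator, power-law fits
  `TAMSD(Δ) = K_α Δ^α`, and a noise/heterogeneity-corrected ensemble
  estimate of the anomalous exponent α (α < 1 = subdiffusion).
- **Fixed-cell calibration** — two-stage mixture selection over (α, K_α)
  of noise-only trajectories, localization-error level ε from the joint
  KDE mode, and the mobility threshold from the 95th percentile of the
  scaled radius of gyration `sRg = sqrt(π/2)·Rg/⟨r⟩`, which is ≈ 1 for
  pure noise regardless of its magnitude.
- **Mobility classification** — mobile/immobile labels per trajectory
  and session-stratified treatment comparisons via Mantel-Haenszel and
  treated-weighted common odds ratios.
- **Mobile-class heterogeneity** — pooled RMS-scaled step distributions
  vs Gaussian mixtures, and per-trajectory Rayleigh mixtures
  `p(r) = Σ p_i (r/σ_i²) e^(−r²/2σ_i²)` with AIC + ΔAIC<4 parsimony
  selection and apparent diffusion coefficients `D_i = σ_i²/(2Δt)`.
- **Synthetic data** — seeded generators for immobile, Brownian,
  fractional-Brownian (exact fGn covariance), and two-state walkers, gap
  injection, and rendered 16-bit movies with ground-truth tables.

See `docs/methods.md` for the models, estimators, defaults, and their
rationale.

## Worked example

Classify a mixed ensemble against its own fixed-cell calibration:

```python
from piezospt.calibration import calibrate
from piezospt.mobility import classify
from piezospt.simulate import SimulationConfig, simulate_immobile, simulate_two_state

fixed = simulate_immobile(SimulationConfig(n_traj=500, n_points=200, loc_sigma=0.02, seed=11))
cal = calibrate(fixed.trajectories, seed=0)
print(f"epsilon = {cal.epsilon:.3e} um^2, threshold = {cal.sRg_threshold:.4f}")

live = (
    simulate_immobile(SimulationConfig(n_traj=200, n_points=200, loc_sigma=0.02, seed=12)).trajectories
    + simulate_two_state(SimulationConfig(n_traj=300, n_points=200, seed=13), 0.5, 0.03, 0.10).trajectories
)
results, _ = classify(live, cal.sRg_threshold)
mobile = sum(r.label == "mobile" for r in results)
print(f"{mobile}/{len(results)} mobile")
```

prints

```
epsilon = 1.467e-03 um^2, threshold = 1.0520
304/500 mobile
```

— the calibrated noise floor recovers the generative truth 4σ² =
1.6e-3 μm² within 10%, and the 60% simulated mobile fraction is recovered
(304/500) because noise-only trajectories sit below the sRg threshold by
construction.

The numbered scripts under `analysis/` run the same workflow as a
narrative: `01` simulates the fixed- and live-cell ensembles, `02`
benchmarks detection/linking on a rendered movie (12/12 tracks, 0.057 px
RMSE), `03` calibrates, `04` classifies (99.2% agreement with the
generative labels), `05` quantifies mobile-class heterogeneity (98% of
trajectories select the two-component Rayleigh mixture; recovered state
D's 0.0042 and 0.050 μm²/s vs truth 0.0045 and 0.050), `06` estimates the
corrected ensemble exponent (0.509 vs truth 0.5, naive 0.478), and `07`
computes stratified odds ratios. Each writes its tables under `results/`.

A thin CLI mirrors the stages
(`spt simulate|detect-track|calibrate|tamsd|classify|mobile-analysis|odds|pipeline`);
every invocation writes a JSON run manifest with parameters, seeds, and
input digests.

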