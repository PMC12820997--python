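"""Heterogeneity analysis of the mobile trajectory class.

Two complementary views:

* **Ensemble level** — pool the per-axis step components of all mobile
  trajectories after scaling each trajectory's components by their own
  root-mean-square value.  Homogeneous Brownian diffusers would pool to a
  standard normal; a two-Gaussian mixture fitting better than a single
  Gaussian signals heterogeneity across or within trajectories.

* **Single-trajectory level** — model each trajectory's 2D step lengths
  r = sqrt(dx^2 + dy^2) as a mixture of k = 1..4 Rayleigh components

      p(r) = sum_i p_i * (r / sigma_i^2) * exp(-r^2 / (2 sigma_i^2)),

  fit by EM with the closed-form M-step sigma_i^2 = sum(g r^2) / (2 sum(g)),
  and select k by AIC with a parsimony rule: starting from the minimum-AIC
  model, step down to the simpler model whenever its AIC is within 4 units.
  Each component maps to an apparent diffusion coefficient D = sigma^2/(2 dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .trajectory import Trajectory

__all__ = [
    "StepData",
    "StepGaussianModels",
    "RayleighMixtureFit",
    "extract_steps",
    "scale_steps",
    "fit_step_gaussians",
    "fit_rayleigh_mixture",
    "select_k",
    "population_summary",
]


@dataclass
class StepData:
    """Step vectors of one trajectory, optionally RMS-scaled per axis."""

    traj_id: object
    dxy: np.ndarray            # (n_steps, 2), um (or dimensionless if scaled)
    scaled: bool = False

    @property
    def n_steps(self) -> int:
        return self.dxy.shape[0]

    @property
    def lengths(self) -> np.ndarray:
        return np.linalg.norm(self.dxy, axis=1)


@dataclass
class StepGaussianModels:
    """Single-Gaussian vs two-Gaussian description of pooled scaled steps."""

    mean: float
    variance: float
    loglik_single: float
    mix_weights: np.ndarray
    mix_means: np.ndarray
    mix_variances: np.ndarray
    loglik_mixture: float


@dataclass
class RayleighMixtureFit:
    k: int
    proportions: np.ndarray     # ascending-sigma order
    sigmas: np.ndarray          # um
    apparent_D: np.ndarray      # um^2/s, sigma^2 / (2 dt)
    loglik: float
    aic: float
    n_steps: int
    selected: bool = False
    converged: bool = True


def extract_steps(traj: Trajectory) -> StepData:
    """Step vectors between consecutive non-gap frames."""
    return StepData(traj_id=traj.traj_id, dxy=traj.steps())


def scale_steps(steps: StepData) -> StepData:
    """Divide each axis by its own RMS so the scaled RMS is exactly 1.

    Removes per-trajectory diffusivity so steps from different trajectories
    can be pooled; an axis with zero RMS leaves nothing to scale and is an
    error (the trajectory is excluded upstream).
    """
    rms = np.sqrt(np.mean(steps.dxy**2, axis=0))
    if np.any(rms == 0):
        raise ValueError(f"trajectory {steps.traj_id}: zero-RMS axis, cannot scale")
    return StepData(traj_id=steps.traj_id, dxy=steps.dxy / rms, scaled=True)


def fit_step_gaussians(pooled: np.ndarray, seed: int = 0, n_init: int = 5) -> StepGaussianModels:
    """Fit the pooled 1D scaled-step sample as one Gaussian and as a
    two-Gaussian mixture; report both log-likelihoods for comparison.

    The single Gaussian uses the sample mean and (biased, MLE) variance; the
    mixture is fit by EM with multiple seeded restarts.
    """
    x = np.asarray(pooled, float).ravel()
    mu, var = float(x.mean()), float(x.var())
    ll1 = float(np.sum(stats.norm.logpdf(x, mu, np.sqrt(var))))
    gm = GaussianMixture(n_components=2, n_init=n_init, random_state=seed, covariance_type="full")
    gm.fit(x[:, None])
    ll2 = float(gm.score(x[:, None]) * x.size)
    weights, means, variances = gm.weights_.copy(), gm.means_.ravel().copy(), gm.covariances_.ravel().copy()
    if ll2 < ll1:
        # EM found a local optimum below the nested single-Gaussian solution
        # (possible on effectively unimodal data); the equal-components
        # mixture attains the single-Gaussian likelihood exactly
        weights = np.array([0.5, 0.5])
        means = np.array([mu, mu])
        variances = np.array([var, var])
        ll2 = ll1
    return StepGaussianModels(
        mean=mu,
        variance=var,
        loglik_single=ll1,
        mix_weights=weights,
        mix_means=means,
        mix_variances=variances,
        loglik_mixture=ll2,
    )


def _rayleigh_logpdf(r: np.ndarray, sigma: float) -> np.ndarray:
    return np.log(r) - 2 * np.log(sigma) - r**2 / (2 * sigma**2)


def _rayleigh_mixture_loglik(r: np.ndarray, p: np.ndarray, sig: np.ndarray) -> float:
    comp = np.log(p)[None, :] + np.stack([_rayleigh_logpdf(r, s) for s in sig], axis=1)
    m = comp.max(axis=1, keepdims=True)
    return float(np.sum(m.ravel() + np.log(np.exp(comp - m).sum(axis=1))))


def _em_rayleigh(r: np.ndarray, sig0: np.ndarray, tol: float = 1e-8, max_iter: int = 500):
    """One EM run; returns (p, sigma, loglik, converged).

    The E-step responsibilities use the normalized Rayleigh density; the
    M-step is closed form.  The log-likelihood is non-decreasing across
    iterations (asserted to numerical tolerance).
    """
    k = sig0.size
    p = np.full(k, 1.0 / k)
    sig = sig0.copy()
    ll_old = -np.inf
    for _ in range(max_iter):
        comp = np.log(p)[None, :] + np.stack([_rayleigh_logpdf(r, s) for s in sig], axis=1)
        m = comp.max(axis=1, keepdims=True)
        w = np.exp(comp - m)
        tot = w.sum(axis=1, keepdims=True)
        gamma = w / tot
        ll = float(np.sum(m.ravel() + np.log(tot.ravel())))
        assert ll >= ll_old - 1e-9 * max(1.0, abs(ll_old)), "EM log-likelihood decreased"
        p = gamma.mean(axis=0)
        denom = gamma.sum(axis=0)
        if np.any(denom < 1e-12):
            return p, sig, ll, False  # component collapse
        sig = np.sqrt((gamma * r[:, None] ** 2).sum(axis=0) / (2.0 * denom))
        if np.any(sig < 1e-12):
            return p, sig, ll, False
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            return p, sig, ll, True
        ll_old = ll
    return p, sig, ll, True


def fit_rayleigh_mixture(
    r: np.ndarray, k: int, dt: float, seed: int = 0, n_restarts: int = 10
) -> RayleighMixtureFit:
    """Maximum-likelihood Rayleigh mixture with k components on step lengths.

    ``k = 1`` uses the closed-form MLE sigma^2 = sum(r^2) / (2n).  For k > 1,
    EM runs from quantile-spread initial sigmas with seeded jitter and the
    best log-likelihood is kept.  A solution with a component supported by
    fewer than one expected step (p_i < 1/n) is refit with k-1 components.
    AIC counts 2k - 1 free parameters (k sigmas, k-1 proportions).
    """
    r = np.asarray(r, float)
    r = r[r > 0]
    n = r.size
    if n < 2:
        raise ValueError("need at least 2 positive step lengths")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        sig = float(np.sqrt(np.sum(r**2) / (2.0 * n)))
        ll = float(np.sum(_rayleigh_logpdf(r, sig)))
        return RayleighMixtureFit(
            k=1,
            proportions=np.array([1.0]),
            sigmas=np.array([sig]),
            apparent_D=np.array([sig**2 / (2.0 * dt)]),
            loglik=ll,
            aic=2.0 * 1 - 2.0 * ll,
            n_steps=n,
        )

    rng = np.random.default_rng(seed)
    qs = np.quantile(r, np.linspace(0.15, 0.85, k)) / np.sqrt(2.0)
    best = None
    for _ in range(n_restarts):
        sig0 = np.maximum(qs * rng.lognormal(0.0, 0.25, size=k), 1e-9)
        p, sig, ll, ok = _em_rayleigh(r, np.sort(sig0))
        if ok and (best is None or ll > best[2]):
            best = (p, sig, ll)
    if best is None or np.any(best[0] < 1.0 / n):
        # degenerate at this order: report the best (k-1)-component solution
        return fit_rayleigh_mixture(r, k - 1, dt, seed=seed, n_restarts=n_restarts)
    p, sig, ll = best
    order = np.argsort(sig)
    p, sig = p[order], sig[order]
    n_params = 2 * k - 1
    return RayleighMixtureFit(
        k=k,
        proportions=p,
        sigmas=sig,
        apparent_D=sig**2 / (2.0 * dt),
        loglik=ll,
        aic=2.0 * n_params - 2.0 * ll,
        n_steps=n,
    )


def select_k(fits: list[RayleighMixtureFit]) -> RayleighMixtureFit:
    """AIC selection with the delta-AIC < 4 parsimony step-down.

    Starting from the minimum-AIC model, repeatedly step to the next-simpler
    converged model while the simpler model's AIC exceeds the current one by
    less than 4; the procedure is deterministic.
    """
    fits = sorted((f for f in fits if f.converged), key=lambda f: f.k)
    if not fits:
        raise ValueError("no converged fits")
    by_k = {f.k: f for f in fits}
    ks = sorted(by_k)
    current = min(ks, key=lambda k: by_k[k].aic)
    while True:
        simpler = [k for k in ks if k < current]
        if not simpler:
            break
        j = max(simpler)
        if by_k[j].aic - by_k[current].aic < 4.0:
            current = j
        else:
            break
    chosen = by_k[current]
    chosen.selected = True
    return chosen


@dataclass
class PopulationSummary:
    """Joint density of (mixing proportion, apparent D) over two-state fits."""

    component: str
    points: np.ndarray          # (m, 2): proportion, log10 D
    grid_p: np.ndarray
    grid_log10D: np.ndarray
    density: np.ndarray
    mode: tuple[float, float]   # (proportion, D um^2/s) at the density mode
    frac_below_noise_D: float | None = None
    extra: dict = field(default_factory=dict)


def population_summary(
    selected_fits: list[RayleighMixtureFit],
    component: str = "slow",
    noise_equivalent_D: float | None = None,
    grid_size: int = 128,
) -> PopulationSummary:
    """Joint kernel density of (proportion, log10 apparent D) across the
    two-component trajectories, for the slow or fast mobility state.

    Components are labeled slow/fast by ascending sigma within each
    trajectory.  When ``noise_equivalent_D`` is given, the fraction of
    trajectories whose chosen-component D falls below it is reported —
    a measure of how much of that state is indistinguishable from
    localization noise.
    """
    if component not in ("slow", "fast"):
        raise ValueError("component must be 'slow' or 'fast'")
    idx = 0 if component == "slow" else 1
    pts = np.array(
        [(f.proportions[idx], np.log10(f.apparent_D[idx])) for f in selected_fits if f.k == 2]
    )
    if pts.shape[0] < 20:
        raise ValueError("need >= 20 two-component trajectories")
    kde = stats.gaussian_kde(pts.T)
    gp = np.linspace(pts[:, 0].min(), pts[:, 0].max(), grid_size)
    gd = np.linspace(pts[:, 1].min(), pts[:, 1].max(), grid_size)
    P, L = np.meshgrid(gp, gd, indexing="ij")
    dens = kde(np.vstack([P.ravel(), L.ravel()])).reshape(grid_size, grid_size)
    i, j = np.unravel_index(np.argmax(dens), dens.shape)
    frac = None
    if noise_equivalent_D is not None:
        frac = float(np.mean(10 ** pts[:, 1] < noise_equivalent_D))
    return PopulationSummary(
        component=component,
        points=pts,
        grid_p=gp,
        grid_log10D=gd,
        density=dens,
        mode=(float(gp[i]), float(10 ** gd[j])),
        frac_below_noise_D=frac,
        extra={"n_two_component": int(pts.shape[0]), "n_total": len(selected_fits)},
    )
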