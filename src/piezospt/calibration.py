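"""Fixed-cell calibration of the localization error and the mobility threshold.

Puncta in chemically fixed cells cannot move, so the apparent spread of their
trajectories is pure localization noise.  Calibration proceeds in stages:

1. Per-trajectory TAMSD over one decade of frame lags (1-10) and a power-law
   fit over frame lags 2-4 (lag 1 is the most noise-dominated).  For
   noise-only motion the expected exponent is ~0 and the level K_alpha equals
   the flat noise floor 4*sigma_loc^2.
2. A two-component Gaussian mixture over the fitted exponents; keep the
   lower-mean subpopulation (trajectories consistent with alpha ~ 0).
3. A two-component kernel-based (semiparametric) mixture over the fitted
   K_alpha values, on the log scale; keep the lower-mean subpopulation.
4. The localization-error level epsilon is the K_alpha coordinate of the mode
   of a joint (log K_alpha, alpha) Gaussian kernel density over the retained
   trajectories.
5. The mobility threshold is the 95th percentile of the retained
   trajectories' scaled radius of gyration — by construction independent of
   the noise magnitude.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .mobility import scaled_radius_of_gyration
from .tamsd import compute_tamsd, fit_power_law
from .trajectory import Trajectory

__all__ = [
    "CalibrationResult",
    "fit_alpha_gmm",
    "fit_kalpha_kernel_mixture",
    "estimate_localization_error",
    "compute_srg_threshold",
    "calibrate",
]

FIXED_CELL_N_MAX = 10
FIXED_CELL_FIT_RANGE = (2, 4)


@dataclass
class MixtureSelection:
    """Result of a two-component mixture fit plus the lower-mean subset."""

    means: np.ndarray
    weights: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray    # (n, 2), columns ordered by ascending mean
    selected: np.ndarray            # boolean mask of the lower-mean members
    fallback_single: bool = False


@dataclass
class CalibrationResult:
    epsilon: float                  # localization-error TAMSD level, um^2
    sRg_threshold: float
    alpha_mixture: dict
    kalpha_mixture: dict
    n_input: int
    n_selected: int
    settings: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "epsilon_um2": self.epsilon,
                    "sRg_threshold": self.sRg_threshold,
                    "alpha_mixture": self.alpha_mixture,
                    "kalpha_mixture": self.kalpha_mixture,
                    "n_input": self.n_input,
                    "n_selected": self.n_selected,
                    "settings": self.settings,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            epsilon=d["epsilon_um2"],
            sRg_threshold=d["sRg_threshold"],
            alpha_mixture=d.get("alpha_mixture", {}),
            kalpha_mixture=d.get("kalpha_mixture", {}),
            n_input=d.get("n_input", 0),
            n_selected=d.get("n_selected", 0),
            settings=d.get("settings", {}),
        )


def fit_alpha_gmm(alphas: np.ndarray, seed: int = 0, n_init: int = 20) -> MixtureSelection:
    """Two-component Gaussian mixture over fitted exponents; keep the
    lower-mean component's members (posterior >= 0.5 hard assignment).

    EM runs with multiple restarts keeping the best log-likelihood.  If the
    sample is degenerate (effectively constant), a single-component fallback
    keeps everything.
    """
    x = np.asarray(alphas, float)
    if x.size < 20:
        raise ValueError("need >= 20 exponent values")
    if np.ptp(x) < 1e-12:
        n = x.size
        return MixtureSelection(
            means=np.array([x[0], x[0]]),
            weights=np.array([1.0, 0.0]),
            variances=np.zeros(2),
            responsibilities=np.column_stack([np.ones(n), np.zeros(n)]),
            selected=np.ones(n, bool),
            fallback_single=True,
        )
    gm = GaussianMixture(
        n_components=2, n_init=n_init, random_state=seed, covariance_type="full",
        reg_covar=1e-10, tol=1e-8, max_iter=500,
    )
    gm.fit(x[:, None])
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    weights = gm.weights_[order]
    variances = gm.covariances_.ravel()[order]
    resp = gm.predict_proba(x[:, None])[:, order]
    selected = resp[:, 0] >= 0.5
    # Ashman's D < 2: the two components overlap so heavily the sample is
    # effectively one population — no subpopulation to discard
    if _ashman_d(means, variances) < 2.0 or not selected.any():
        selected = np.ones(x.size, bool)
        fallback = True
    else:
        fallback = False
    return MixtureSelection(
        means=means,
        weights=weights,
        variances=variances,
        responsibilities=resp,
        selected=selected,
        fallback_single=fallback,
    )


def _ashman_d(means: np.ndarray, variances: np.ndarray) -> float:
    """Ashman's D, the standard separation statistic for two Gaussians;
    values below ~2 indicate the mixture is effectively unimodal."""
    denom = np.sqrt((variances[0] + variances[1]) / 2.0)
    return abs(means[1] - means[0]) / denom if denom > 0 else np.inf


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = np.std(x)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    return max(0.9 * scale * n ** (-0.2), 1e-9)


def fit_kalpha_kernel_mixture(
    kalphas: np.ndarray, seed: int = 0, max_iter: int = 100, tol: float = 1e-6
) -> MixtureSelection:
    """Semiparametric two-component mixture on log K_alpha via kernel EM.

    Component densities are responsibility-weighted Gaussian kernel density
    estimates with a Silverman bandwidth on the working sample; the E-step
    draws responsibilities from those densities, the M-step reweights.  K_alpha
    is fit on the log scale (positive, right-skewed); members of the
    lower-mean component (responsibility >= 0.5) are selected.
    """
    k = np.asarray(kalphas, float)
    if np.any(k <= 0):
        raise ValueError("K_alpha values must be positive")
    if k.size < 20:
        raise ValueError("need >= 20 K_alpha values")
    x = np.log(k)
    n = x.size
    if np.ptp(x) < 1e-12:
        return MixtureSelection(
            means=np.array([x[0], x[0]]),
            weights=np.array([1.0, 0.0]),
            variances=np.zeros(2),
            responsibilities=np.column_stack([np.ones(n), np.zeros(n)]),
            selected=np.ones(n, bool),
            fallback_single=True,
        )
    h = _silverman_bandwidth(x)
    # initialize by a median split
    gamma = np.column_stack([(x <= np.median(x)).astype(float), (x > np.median(x)).astype(float)])
    gamma = np.clip(gamma, 0.05, 0.95)
    gamma /= gamma.sum(axis=1, keepdims=True)
    pi = gamma.mean(axis=0)
    kern = np.exp(-0.5 * ((x[:, None] - x[None, :]) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    for _ in range(max_iter):
        # E-step: weighted-KDE component densities evaluated at every point
        dens = kern @ gamma / gamma.sum(axis=0)        # (n, 2)
        num = pi[None, :] * dens
        new_gamma = num / num.sum(axis=1, keepdims=True)
        new_pi = new_gamma.mean(axis=0)
        delta = np.max(np.abs(new_gamma - gamma))
        gamma, pi = new_gamma, new_pi
        if delta < tol:
            break
    comp_means = (gamma * x[:, None]).sum(axis=0) / gamma.sum(axis=0)
    order = np.argsort(comp_means)
    gamma = gamma[:, order]
    comp_means = comp_means[order]
    pi = pi[order]
    comp_vars = (gamma * (x[:, None] - comp_means[None, :]) ** 2).sum(axis=0) / gamma.sum(axis=0)
    selected = gamma[:, 0] >= 0.5
    if _ashman_d(comp_means, comp_vars) < 2.0 or not selected.any():
        selected = np.ones(n, bool)
        fallback = True
    else:
        fallback = False
    return MixtureSelection(
        means=comp_means,            # on the log scale
        weights=pi,
        variances=comp_vars,
        responsibilities=gamma,
        selected=selected,
        fallback_single=fallback,
    )


def estimate_localization_error(
    kalphas: np.ndarray, alphas: np.ndarray, grid_size: int = 256
) -> float:
    """Localization-error level: the K_alpha at the mode of the joint
    (log K_alpha, alpha) Gaussian kernel density, in um^2.

    The density is evaluated on a regular grid spanning the data range padded
    by three bandwidths per axis; multimodal ties break toward lower K_alpha.
    """
    k = np.asarray(kalphas, float)
    a = np.asarray(alphas, float)
    if k.size != a.size or k.size < 20:
        raise ValueError("need >= 20 aligned (K_alpha, alpha) pairs")
    lk = np.log(k)
    if np.ptp(lk) < 1e-12 and np.ptp(a) < 1e-12:
        return float(k[0])
    data = np.vstack([lk, a])
    # jitter degenerate axes so the 2D KDE stays full rank
    for row in range(2):
        if np.ptp(data[row]) < 1e-12:
            data = data.copy()
            data[row] = data[row] + np.random.default_rng(0).normal(0, 1e-9, size=data.shape[1])
    kde = stats.gaussian_kde(data)
    bw = kde.covariance_factor() * data.std(axis=1)
    gx = np.linspace(data[0].min() - 3 * bw[0], data[0].max() + 3 * bw[0], grid_size)
    gy = np.linspace(data[1].min() - 3 * bw[1], data[1].max() + 3 * bw[1], grid_size)
    X, Y = np.meshgrid(gx, gy, indexing="ij")
    dens = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(grid_size, grid_size)
    flat_max = dens.max()
    ties = np.argwhere(dens >= flat_max * (1 - 1e-12))
    i = ties[np.argmin(ties[:, 0])][0]          # tie toward lower K_alpha
    return float(np.exp(gx[i]))


def compute_srg_threshold(srg_values: np.ndarray) -> float:
    """95th percentile (linear-interpolation quantile) of fixed-cell sRg."""
    v = np.asarray(srg_values, float)
    v = v[np.isfinite(v)]
    if v.size < 1:
        raise ValueError("no finite sRg values")
    return float(np.percentile(v, 95))


def calibrate(trajectories: list[Trajectory], seed: int = 0) -> CalibrationResult:
    """Full fixed-cell calibration pipeline.

    Runs TAMSD (lags 1-10) + power-law fits (lags 2-4), the exponent GMM
    selection, the K_alpha kernel-mixture selection, the joint-KDE
    localization-error estimate, and the sRg threshold, on the retained set.
    Selection stages only ever shrink the trajectory set.
    """
    if len(trajectories) < 20:
        raise ValueError("need >= 20 fixed-cell trajectories")
    fits = []
    usable = []
    for traj in trajectories:
        curve = compute_tamsd(traj, FIXED_CELL_N_MAX)
        try:
            fits.append(fit_power_law(curve, FIXED_CELL_FIT_RANGE))
            usable.append(traj)
        except ValueError:
            warnings.warn(f"trajectory {traj.traj_id}: unusable TAMSD in lags 2-4; skipped")
    alphas = np.array([f.alpha for f in fits])
    kalphas = np.array([f.K_alpha for f in fits])

    sel_a = fit_alpha_gmm(alphas, seed=seed)
    idx_a = np.flatnonzero(sel_a.selected)
    sel_k = fit_kalpha_kernel_mixture(kalphas[idx_a], seed=seed)
    idx = idx_a[sel_k.selected]

    if idx.size < 20:
        warnings.warn("fewer than 20 trajectories after selection; using the alpha-selected set")
        idx = idx_a
    epsilon = estimate_localization_error(kalphas[idx], alphas[idx])
    srg = np.array([scaled_radius_of_gyration(usable[i]).sRg for i in idx])
    threshold = compute_srg_threshold(srg)
    return CalibrationResult(
        epsilon=epsilon,
        sRg_threshold=threshold,
        alpha_mixture={
            "means": sel_a.means.tolist(),
            "weights": sel_a.weights.tolist(),
            "variances": sel_a.variances.tolist(),
            "fallback_single": sel_a.fallback_single,
        },
        kalpha_mixture={
            "log_means": sel_k.means.tolist(),
            "weights": sel_k.weights.tolist(),
            "log_variances": sel_k.variances.tolist(),
            "fallback_single": sel_k.fallback_single,
        },
        n_input=len(trajectories),
        n_selected=int(idx.size),
        settings={
            "tamsd_n_max": FIXED_CELL_N_MAX,
            "fit_lag_range": FIXED_CELL_FIT_RANGE,
            "kde_grid": 256,
            "seed": seed,
        },
    )
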