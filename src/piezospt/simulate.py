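"""Synthetic trajectory and movie generators.

Every generator is seeded and returns a :class:`GroundTruthEnsemble` whose
``true_params`` record the generative parameters, so downstream estimators can
be scored on parameter recovery.  The statistical models mirror what the
analysis assumes:

* immobile puncta — a fixed position plus i.i.d. isotropic 2D Gaussian
  localization noise, whose TAMSD is flat at ``4·loc_sigma²``;
* Brownian walkers — per-axis increments with variance ``2·D·dt``;
* subdiffusive walkers — fractional Gaussian noise scaled so the expected 2D
  MSD is ``K_alpha · Δ^alpha``;
* two-state walkers — each step drawn from a slow or fast Gaussian with a
  stationary mixing proportion, so step lengths follow a two-component
  Rayleigh mixture exactly.

Movies render each position as a diffraction-limited Gaussian spot on a noisy
background, with a per-frame truth table for scoring detection and linking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory import GroundTruthEnsemble, Trajectory

__all__ = [
    "SimulationConfig",
    "simulate_immobile",
    "simulate_brownian",
    "simulate_fbm",
    "simulate_two_state",
    "inject_gaps",
    "render_movie",
]

DEFAULT_PIXEL_SIZE_UM = 0.1092


@dataclass
class SimulationConfig:
    """Shared knobs for trajectory generation.

    ``loc_sigma`` is the per-axis localization-noise SD in micrometers; it is
    added to the *reported* positions only — the true path is kept separately
    in ``true_params`` so calibration can be checked against the known sigma.
    """

    n_traj: int = 100
    n_points: int = 200
    dt: float = 0.1
    loc_sigma: float = 0.0
    pixel_size: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.loc_sigma < 0:
            raise ValueError("loc_sigma must be non-negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _spread_centers(rng: np.random.Generator, n: int, spacing: float = 5.0) -> np.ndarray:
    """Well-separated anchor points so rendered spots rarely overlap."""
    side = int(np.ceil(np.sqrt(n)))
    grid = np.stack(np.meshgrid(np.arange(side), np.arange(side)), axis=-1).reshape(-1, 2)
    return spacing * (grid[:n] + 1.0) + rng.uniform(-0.5, 0.5, size=(n, 2))


def _build(trajs_xy: np.ndarray, cfg: SimulationConfig, label: str, params: list[dict]) -> GroundTruthEnsemble:
    frames = np.arange(cfg.n_points)
    trajectories = [
        Trajectory(traj_id=i, frames=frames.copy(), xy=trajs_xy[i], dt=cfg.dt)
        for i in range(trajs_xy.shape[0])
    ]
    return GroundTruthEnsemble(trajectories, [label] * len(trajectories), params)


def simulate_immobile(cfg: SimulationConfig) -> GroundTruthEnsemble:
    """Fixed true positions observed through localization noise.

    The expected 2D TAMSD is flat at ``4·loc_sigma²`` for every lag, and the
    scaled radius of gyration of such trajectories has ensemble mean ≈ 1
    independent of the noise magnitude.
    """
    rng = cfg.rng()
    centers = _spread_centers(rng, cfg.n_traj)
    noise = rng.normal(0.0, cfg.loc_sigma, size=(cfg.n_traj, cfg.n_points, 2))
    xy = centers[:, None, :] + noise
    params = [
        {"loc_sigma": cfg.loc_sigma, "center": centers[i], "true_xy": np.broadcast_to(centers[i], (cfg.n_points, 2)).copy()}
        for i in range(cfg.n_traj)
    ]
    return _build(xy, cfg, "immobile", params)


def simulate_brownian(cfg: SimulationConfig, D: float) -> GroundTruthEnsemble:
    """Unrestricted 2D Brownian motion, per-axis step variance ``2·D·dt``.

    The expected 2D MSD is ``4·D·Δ``; a log-log TAMSD fit therefore recovers
    exponent 1, the boundary between sub- and superdiffusion.
    """
    if D < 0:
        raise ValueError("D must be non-negative")
    rng = cfg.rng()
    centers = _spread_centers(rng, cfg.n_traj)
    steps = rng.normal(0.0, np.sqrt(2.0 * D * cfg.dt), size=(cfg.n_traj, cfg.n_points - 1, 2))
    true_xy = np.concatenate([np.zeros((cfg.n_traj, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    true_xy += centers[:, None, :]
    xy = true_xy + rng.normal(0.0, cfg.loc_sigma, size=true_xy.shape)
    params = [{"D": D, "loc_sigma": cfg.loc_sigma, "true_xy": true_xy[i]} for i in range(cfg.n_traj)]
    return _build(xy, cfg, "brownian", params)


def _fgn_cholesky(n_steps: int, alpha: float) -> np.ndarray:
    """Cholesky factor of the unit-variance fractional-Gaussian-noise covariance.

    Exact O(n²)–O(n³) synthesis; trajectories are at most a few hundred points
    so exactness is preferred over asymptotically faster approximate methods.
    """
    H = alpha / 2.0
    k = np.abs(np.subtract.outer(np.arange(n_steps), np.arange(n_steps))).astype(float)
    cov = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H) + np.abs(k - 1) ** (2 * H))
    # tiny jitter guards against numerically semi-definite cases near alpha→2
    return np.linalg.cholesky(cov + 1e-12 * np.eye(n_steps))


def simulate_fbm(cfg: SimulationConfig, K_alpha: float, alpha: float) -> GroundTruthEnsemble:
    """Fractional Brownian motion with expected 2D MSD ``K_alpha · Δ^alpha``.

    Each axis is fractional Gaussian noise generated by exact covariance
    factorization and scaled so the per-axis MSD is ``(K_alpha/2)·Δ^alpha``;
    ``alpha = 1`` reduces to Brownian motion (uncorrelated increments).
    """
    if not (0 < alpha < 2):
        raise ValueError("alpha must lie in (0, 2)")
    if K_alpha <= 0:
        raise ValueError("K_alpha must be positive")
    rng = cfg.rng()
    centers = _spread_centers(rng, cfg.n_traj)
    L = _fgn_cholesky(cfg.n_points - 1, alpha)
    scale = np.sqrt(0.5 * K_alpha * cfg.dt ** alpha)
    z = rng.standard_normal((cfg.n_traj, cfg.n_points - 1, 2))
    steps = scale * np.einsum("ij,njk->nik", L, z)
    true_xy = np.concatenate([np.zeros((cfg.n_traj, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    true_xy += centers[:, None, :]
    xy = true_xy + rng.normal(0.0, cfg.loc_sigma, size=true_xy.shape)
    params = [
        {"K_alpha": K_alpha, "alpha": alpha, "loc_sigma": cfg.loc_sigma, "true_xy": true_xy[i]}
        for i in range(cfg.n_traj)
    ]
    return _build(xy, cfg, "fbm", params)


def simulate_two_state(
    cfg: SimulationConfig, p_fast: float, sigma_slow: float, sigma_fast: float
) -> GroundTruthEnsemble:
    """Two-state step mixture with stationary mixing proportions.

    Each step independently draws its per-axis SD from {sigma_slow,
    sigma_fast} with probability ``p_fast`` of the fast state (i.i.d. per
    step, not Markov-persistent), so step lengths follow the two-component
    Rayleigh mixture exactly.
    """
    if not (0 <= p_fast <= 1):
        raise ValueError("p_fast must lie in [0, 1]")
    if not (sigma_fast > sigma_slow > 0):
        raise ValueError("require sigma_fast > sigma_slow > 0")
    rng = cfg.rng()
    centers = _spread_centers(rng, cfg.n_traj)
    fast = rng.random((cfg.n_traj, cfg.n_points - 1)) < p_fast
    sigmas = np.where(fast, sigma_fast, sigma_slow)
    steps = rng.standard_normal((cfg.n_traj, cfg.n_points - 1, 2)) * sigmas[..., None]
    xy = np.concatenate([np.zeros((cfg.n_traj, 1, 2)), np.cumsum(steps, axis=1)], axis=1)
    xy += centers[:, None, :]
    params = [
        {"p_fast": p_fast, "sigma_slow": sigma_slow, "sigma_fast": sigma_fast, "states_fast": fast[i]}
        for i in range(cfg.n_traj)
    ]
    return _build(xy, cfg, "two_state", params)


def inject_gaps(ensemble: GroundTruthEnsemble, gap_prob: float, seed: int) -> GroundTruthEnsemble:
    """Replace interior points with NaN gap placeholders, i.i.d. per point.

    First and last points are never gapped so trajectory endpoints stay
    defined; frame indices are preserved.
    """
    if not (0 <= gap_prob < 1):
        raise ValueError("gap_prob must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = []
    for traj in ensemble.trajectories:
        xy = traj.xy.copy()
        n = xy.shape[0]
        if n > 2 and gap_prob > 0:
            gapped = rng.random(n - 2) < gap_prob
            xy[1:-1][gapped] = np.nan
        out.append(Trajectory(traj.traj_id, traj.frames.copy(), xy, traj.dt, dict(traj.meta)))
    return GroundTruthEnsemble(out, list(ensemble.true_labels), list(ensemble.true_params))


def render_movie(
    ensemble: GroundTruthEnsemble,
    psf_sigma: float,
    amplitude: float,
    background: float,
    noise_sd: float,
    image_shape: tuple[int, int],
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render an ensemble as a 16-bit image stack plus a truth table.

    Each non-gap position becomes a symmetric 2D Gaussian of SD ``psf_sigma``
    pixels on a constant background with additive Gaussian noise.  Pixel
    centers sit at integer coordinates.  Out-of-bounds particles raise rather
    than being silently clipped.

    Returns
    -------
    stack : ndarray of uint16, shape (n_frames, H, W)
    truth : DataFrame with columns ``frame, traj_id, x_px, y_px``
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be positive")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    n_frames = 1 + max(int(t.frames[-1]) for t in ensemble.trajectories)
    rows = []
    for traj in ensemble.trajectories:
        v = traj.valid_mask
        px = traj.xy / pixel_size_um
        oob = v & ((px[:, 0] < 0) | (px[:, 0] > w - 1) | (px[:, 1] < 0) | (px[:, 1] > h - 1))
        if oob.any():
            bad = traj.frames[oob][:5].tolist()
            raise ValueError(
                f"trajectory {traj.traj_id} falls outside the {h}x{w} image at frames {bad}"
            )
        for f, (x, y) in zip(traj.frames[v], px[v]):
            rows.append((int(f), traj.traj_id, float(x), float(y)))
    truth = pd.DataFrame(rows, columns=["frame", "traj_id", "x_px", "y_px"])

    yy, xx = np.mgrid[0:h, 0:w]
    stack = np.full((n_frames, h, w), float(background))
    for f, sub in truth.groupby("frame"):
        for _, r in sub.iterrows():
            d2 = (xx - r.x_px) ** 2 + (yy - r.y_px) ** 2
            stack[f] += amplitude * np.exp(-d2 / (2.0 * psf_sigma**2))
    if noise_sd > 0:
        stack += rng.normal(0.0, noise_sd, size=stack.shape)
    stack = np.clip(np.round(stack), 0, 65535).astype(np.uint16)
    return stack, truth
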