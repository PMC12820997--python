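"""Spot detection and trajectory assembly for diffraction-limited puncta.

The pipeline follows the classic single-particle-tracking recipe: a
difference-of-Gaussians (DoG) spatial bandpass enhances spots, a threshold
produces a binary mask, connected components become candidate particles, a
symmetric 2D Gaussian least-squares fit on the raw image refines each
centroid to sub-pixel precision, and detections within a fixed radius in
consecutive frames are linked greedily into trajectories.  Skipped frames up
to a configurable bound are bridged with NaN gap placeholders; trajectories
shorter than a minimum duration are discarded.

Conventions: pixel centers sit at integer coordinates, frames are 0-based,
and micron coordinates are pixel coordinates times ``pixel_size_um``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, spatial
from skimage import measure

from .trajectory import Trajectory

__all__ = [
    "DetectionParams",
    "Detection",
    "dog_filter",
    "auto_threshold",
    "detect",
    "link",
    "filter_min_duration",
    "id_switch_diagnostic",
]


@dataclass
class DetectionParams:
    dog_sigma_small: float = 1.0
    dog_sigma_large: float = 3.0
    threshold: float | None = None       # None -> auto (mean + k*SD of DoG frame)
    auto_threshold_k: float = 5.0
    link_radius: float = 3.0             # pixels, consecutive frames
    max_gap_frames: int = 1
    min_duration_s: float = 20.0
    dt: float = 0.1
    pixel_size_um: float = 0.1092
    connectivity: int = 2                # skimage: 2 = 8-connectivity, 1 = 4
    fit_on_filtered: bool = False

    def __post_init__(self) -> None:
        if not self.dog_sigma_small < self.dog_sigma_large:
            raise ValueError("dog_sigma_small must be < dog_sigma_large")
        if self.link_radius <= 0:
            raise ValueError("link_radius must be positive")
        if self.min_duration_s <= 0:
            raise ValueError("min_duration_s must be positive")

    @property
    def patch_radius(self) -> int:
        return int(np.ceil(3 * self.dog_sigma_small))


@dataclass
class Detection:
    frame: int
    x_px: float
    y_px: float
    cluster_size: int
    amplitude: float
    fit_ok: bool = True


def dog_filter(stack: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Per-frame difference of Gaussians (small minus large blur).

    A spatial bandpass: DC background cancels exactly and structures much
    larger than ``dog_sigma_large`` are suppressed, while spots near the PSF
    scale are enhanced.  Linear in the input.
    """
    stack = np.asarray(stack, float)
    if stack.ndim == 2:
        stack = stack[None]
    if not np.all(np.isfinite(stack)):
        raise ValueError("stack contains non-finite pixels")
    out = np.empty_like(stack)
    for i, frame in enumerate(stack):
        out[i] = ndimage.gaussian_filter(frame, params.dog_sigma_small) - ndimage.gaussian_filter(
            frame, params.dog_sigma_large
        )
    return out


def auto_threshold(filtered_frame: np.ndarray, k: float) -> float:
    """Reproducible stand-in for a manually picked threshold: mean + k*SD."""
    return float(filtered_frame.mean() + k * filtered_frame.std())


def _gauss2d(params, xx, yy):
    a, x0, y0, s, off = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * s**2)) + off


def _fit_gaussian_patch(img: np.ndarray, cy: int, cx: int, radius: int):
    """Symmetric-2D-Gaussian least squares on a patch around (cy, cx).

    Returns (x, y, amplitude, ok); falls back to the intensity-weighted
    centroid when the optimizer fails or wanders outside the patch.
    """
    h, w = img.shape
    y0, y1 = max(0, cy - radius), min(h, cy + radius + 1)
    x0, x1 = max(0, cx - radius), min(w, cx + radius + 1)
    patch = img[y0:y1, x0:x1].astype(float)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    off0 = patch.min()
    a0 = patch.max() - off0
    p0 = (max(a0, 1e-6), cx, cy, max(radius / 3.0, 0.5), off0)

    def resid(p):
        return (_gauss2d(p, xx, yy) - patch).ravel()

    try:
        sol = optimize.least_squares(resid, p0, max_nfev=200)
        a, xf, yf, s, _ = sol.x
        if sol.success and x0 - 1 <= xf <= x1 and y0 - 1 <= yf <= y1 and a > 0:
            return float(xf), float(yf), float(a), True
    except Exception:
        pass
    wsum = patch - off0
    wsum = np.clip(wsum, 0, None)
    tot = wsum.sum()
    if tot <= 0:
        return float(cx), float(cy), float(a0), False
    return float((wsum * xx).sum() / tot), float((wsum * yy).sum() / tot), float(a0), False


def detect(
    filtered_frame: np.ndarray,
    raw_frame: np.ndarray,
    params: DetectionParams,
    frame_index: int = 0,
) -> list[Detection]:
    """Detect particles in one frame.

    Spatially continuous (8-connected by default) pixels above the threshold
    form one particle each; the centroid comes from a symmetric 2D Gaussian
    fit on the raw image around the component's peak (on the DoG image when
    ``fit_on_filtered``), with an intensity-weighted-centroid fallback that
    flags the detection.
    """
    thr = params.threshold if params.threshold is not None else auto_threshold(
        filtered_frame, params.auto_threshold_k
    )
    mask = filtered_frame > thr
    labels = measure.label(mask, connectivity=params.connectivity)
    fit_img = filtered_frame if params.fit_on_filtered else raw_frame
    detections = []
    for region in measure.regionprops(labels, intensity_image=filtered_frame):
        ys, xs = region.coords[:, 0], region.coords[:, 1]
        peak = np.argmax(filtered_frame[ys, xs])
        cy, cx = int(ys[peak]), int(xs[peak])
        x, y, amp, ok = _fit_gaussian_patch(fit_img, cy, cx, params.patch_radius)
        detections.append(
            Detection(frame=frame_index, x_px=x, y_px=y, cluster_size=int(region.area), amplitude=amp, fit_ok=ok)
        )
    return detections


class _Track:
    __slots__ = ("frames", "xs", "ys", "last_frame")

    def __init__(self, det: Detection):
        self.frames = [det.frame]
        self.xs = [det.x_px]
        self.ys = [det.y_px]
        self.last_frame = det.frame

    def append(self, det: Detection):
        self.frames.append(det.frame)
        self.xs.append(det.x_px)
        self.ys.append(det.y_px)
        self.last_frame = det.frame


def link(detections_per_frame: dict[int, list[Detection]], params: DetectionParams) -> list[Trajectory]:
    """Greedy nearest-neighbor linking of detections into trajectories.

    Between consecutive frames, candidate (track, detection) pairs within
    ``link_radius`` pixels are accepted in ascending distance order; each
    track and each detection matches at most once, so the result does not
    depend on the detection order within a frame.  A track missing up to
    ``max_gap_frames`` consecutive frames stays alive and the skipped frames
    become NaN placeholders; longer absences terminate it.  Unmatched
    detections start new tracks.  Output coordinates are in micrometers.
    """
    frames = sorted(detections_per_frame)
    active: list[_Track] = []
    done: list[_Track] = []
    for f in frames:
        dets = detections_per_frame[f]
        still, expired = [], []
        for tr in active:
            (still if f - tr.last_frame - 1 <= params.max_gap_frames else expired).append(tr)
        done.extend(expired)
        active = still
        matched_tr: set[int] = set()
        matched_de: set[int] = set()
        if active and dets:
            tpos = np.array([[t.xs[-1], t.ys[-1]] for t in active])
            dpos = np.array([[d.x_px, d.y_px] for d in dets])
            dist = spatial.distance.cdist(tpos, dpos)
            ti, di = np.nonzero(dist <= params.link_radius)
            order = np.argsort(dist[ti, di], kind="stable")
            for t_idx, d_idx in zip(ti[order], di[order]):
                if t_idx in matched_tr or d_idx in matched_de:
                    continue
                active[t_idx].append(dets[d_idx])
                matched_tr.add(t_idx)
                matched_de.add(d_idx)
        for j, det in enumerate(dets):
            if j not in matched_de:
                active.append(_Track(det))
    done.extend(active)

    trajectories = []
    next_id = 0
    for tr in done:
        f0, f1 = tr.frames[0], tr.frames[-1]
        n = f1 - f0 + 1
        xy = np.full((n, 2), np.nan)
        for f, x, y in zip(tr.frames, tr.xs, tr.ys):
            xy[f - f0] = (x * params.pixel_size_um, y * params.pixel_size_um)
        if np.isfinite(xy).all(axis=1).sum() < 2:
            continue
        trajectories.append(Trajectory(next_id, np.arange(f0, f1 + 1), xy, params.dt))
        next_id += 1
    return trajectories


def filter_min_duration(trajectories: list[Trajectory], params: DetectionParams) -> list[Trajectory]:
    """Keep trajectories spanning at least ``min_duration_s`` (inclusive).

    Duration counts frame slots inclusively: (last - first + 1) * dt.  At the
    default 0.1 s interval and 20 s cutoff, every retained trajectory has at
    least 200 positions.
    """
    return [t for t in trajectories if t.duration_s >= params.min_duration_s]


@dataclass
class IdSwitchReport:
    """Density diagnostic for linking reliability.

    ID switches are plausible when particles approach within the linking
    radius of one another; the report gives the per-frame mean nearest-
    neighbor distance, the pooled step sizes, and the fraction of frames
    whose median nearest-neighbor distance falls below twice the link radius.
    """

    frame_mean_nn_px: dict[int, float] = field(default_factory=dict)
    step_sizes_px: np.ndarray = field(default_factory=lambda: np.empty(0))
    risk_fraction: float = float("nan")
    note: str = ""


def id_switch_diagnostic(
    detections_per_frame: dict[int, list[Detection]],
    trajectories: list[Trajectory],
    params: DetectionParams,
) -> IdSwitchReport:
    mean_nn: dict[int, float] = {}
    med_nn = []
    for f, dets in sorted(detections_per_frame.items()):
        if len(dets) < 2:
            continue
        pos = np.array([[d.x_px, d.y_px] for d in dets])
        dist = spatial.distance.cdist(pos, pos)
        np.fill_diagonal(dist, np.inf)
        nn = dist.min(axis=1)
        mean_nn[f] = float(nn.mean())
        med_nn.append(float(np.median(nn)))
    steps = [np.linalg.norm(t.steps(), axis=1) / params.pixel_size_um for t in trajectories]
    pooled = np.concatenate(steps) if steps else np.empty(0)
    if not mean_nn:
        return IdSwitchReport(step_sizes_px=pooled, note="insufficient density: no frame with >= 2 detections")
    risk = float(np.mean(np.asarray(med_nn) < 2 * params.link_radius))
    return IdSwitchReport(frame_mean_nn_px=mean_nn, step_sizes_px=pooled, risk_fraction=risk)
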