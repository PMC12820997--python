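"""Mobility classification by scaled radius of gyration, and treatment
comparisons as stratified common odds ratios.

The scaled radius of gyration of a 2D trajectory is

    sRg = sqrt(pi/2) * Rg / <r>

where Rg is the root-mean-square distance of the positions from their
centroid and <r> is the mean length of steps between consecutive observed
frames.  For positions that are pure i.i.d. isotropic Gaussian localization
noise, Rg/<r> concentrates at sqrt(2/pi), so sRg ≈ 1 regardless of the noise
magnitude — which is what makes it a noise-magnitude-free mobility statistic.
Trajectories are labeled mobile when sRg exceeds a threshold calibrated as
the 95th percentile of the fixed-cell (noise-only) sRg distribution.

Treatment effects on the mobile/immobile partition are quantified per
experimental session with 2x2 contingency tables, combined either by the
Mantel-Haenszel common odds ratio (sessions with matched controls) or by a
treated-count-weighted mean of per-session log odds ratios against a pooled
control (treatments whose solvent controls come from other sessions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .trajectory import Trajectory

__all__ = [
    "SRgResult",
    "ContingencyStratum",
    "OddsRatioResult",
    "scaled_radius_of_gyration",
    "classify",
    "mantel_haenszel_or",
    "weighted_or",
]

SRG_SCALE = np.sqrt(np.pi / 2.0)


@dataclass
class SRgResult:
    traj_id: object
    Rg: float
    mean_step: float
    sRg: float                      # NaN when degenerate (all points identical)
    label: Literal["mobile", "immobile", None] = None

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.sRg)


@dataclass
class ContingencyStratum:
    """Mobile/immobile counts for one experimental session."""

    session_id: object
    treated_mobile: int
    treated_immobile: int
    control_mobile: int
    control_immobile: int

    def __post_init__(self) -> None:
        cells = (self.treated_mobile, self.treated_immobile, self.control_mobile, self.control_immobile)
        if any(c < 0 for c in cells):
            raise ValueError("counts must be non-negative")
        if sum(cells) == 0:
            raise ValueError("stratum has no observations")

    @property
    def total(self) -> int:
        return self.treated_mobile + self.treated_immobile + self.control_mobile + self.control_immobile


@dataclass
class OddsRatioResult:
    common_or: float
    ci95: tuple[float, float]
    p_value: float
    method: str
    n_strata: int


def scaled_radius_of_gyration(traj: Trajectory) -> SRgResult:
    """Compute sRg = sqrt(pi/2) * Rg / <r> for one trajectory.

    The centroid and Rg use all non-gap positions; the mean step length uses
    only steps between consecutive non-gap frames (a displacement spanning a
    gap conflates several physical steps).  When every point coincides the
    mean step is zero and sRg is undefined; such trajectories are flagged and
    treated as immobile downstream.
    """
    pos = traj.valid_positions()
    centroid = pos.mean(axis=0)
    Rg = float(np.sqrt(np.mean(np.sum((pos - centroid) ** 2, axis=1))))
    steps = traj.steps()
    if steps.shape[0] < 1:
        raise ValueError("trajectory has no valid consecutive step")
    mean_step = float(np.mean(np.linalg.norm(steps, axis=1)))
    srg = SRG_SCALE * Rg / mean_step if mean_step > 0 else np.nan
    return SRgResult(traj_id=traj.traj_id, Rg=Rg, mean_step=mean_step, sRg=float(srg))


def classify(
    trajectories: list[Trajectory], srg_threshold: float
) -> tuple[list[SRgResult], dict]:
    """Label each trajectory mobile (sRg > threshold) or immobile (<=).

    The boundary is assigned immobile: the threshold is the 95th percentile
    of noise-only spread, so matching it is consistent with immobility.
    Degenerate trajectories (undefined sRg) are labeled immobile.  Returns the
    labeled results and per-session mobile/immobile counts keyed by the
    trajectory ``session_id`` metadata (None when absent).
    """
    results: list[SRgResult] = []
    counts: dict = {}
    for traj in trajectories:
        r = scaled_radius_of_gyration(traj)
        r.label = "mobile" if (np.isfinite(r.sRg) and r.sRg > srg_threshold) else "immobile"
        results.append(r)
        key = traj.meta.get("session_id")
        c = counts.setdefault(key, {"mobile": 0, "immobile": 0})
        c[r.label] += 1
    return results, counts


def _mh_components(strata: list[ContingencyStratum]):
    a = np.array([s.treated_mobile for s in strata], float)
    b = np.array([s.treated_immobile for s in strata], float)
    c = np.array([s.control_mobile for s in strata], float)
    d = np.array([s.control_immobile for s in strata], float)
    n = a + b + c + d
    return a, b, c, d, n


def mantel_haenszel_or(strata: list[ContingencyStratum]) -> OddsRatioResult:
    """Mantel-Haenszel common odds ratio across session strata.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i) with a = treated mobile,
    b = treated immobile, c = control mobile, d = control immobile.  The 95%
    CI uses the Robins-Breslow-Greenland variance of log OR; the p value is
    the Mantel-Haenszel chi-square test (1 df, no continuity correction).
    """
    if not strata:
        raise ValueError("need at least one stratum")
    a, b, c, d, n = _mh_components(strata)
    R_i, S_i = a * d / n, b * c / n
    R, S = R_i.sum(), S_i.sum()
    if S == 0:
        return OddsRatioResult(np.inf, (np.nan, np.inf), np.nan, "session-stratified MH", len(strata))
    or_mh = R / S

    # Robins-Breslow-Greenland variance of log(OR_MH)
    P, Q = (a + d) / n, (b + c) / n
    var_log = (
        (P * R_i).sum() / (2 * R**2)
        + ((P * S_i + Q * R_i)).sum() / (2 * R * S)
        + (Q * S_i).sum() / (2 * S**2)
    )
    se = np.sqrt(var_log)
    z975 = stats.norm.ppf(0.975)
    lo, hi = np.exp(np.log(or_mh) + np.array([-z975, z975]) * se)

    # Mantel-Haenszel chi-square on the treated-mobile cell
    e = (a + b) * (a + c) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
    v = np.where(np.isfinite(v), v, 0.0)
    chi2 = (a.sum() - e.sum()) ** 2 / v.sum() if v.sum() > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))

    return OddsRatioResult(
        common_or=float(or_mh),
        ci95=(float(lo), float(hi)),
        p_value=p,
        method="session-stratified MH",
        n_strata=len(strata),
    )


def weighted_or(
    treated_strata: list[tuple[object, int, int]],
    pooled_control: tuple[int, int],
) -> OddsRatioResult:
    """Treated-count-weighted common OR against a pooled control group.

    Used when treated sessions lack matched same-session controls: each
    session's odds ratio is its treated mobile:immobile odds over the pooled
    control odds; the common estimate is exp of the mean of per-session log
    ORs weighted by each session's total treated trajectory count, with a
    delta-method variance (1/a + 1/b + 1/c + 1/d per session) propagated
    through the weights.  A session with a zero cell gets the Haldane +0.5
    continuity correction applied to all four of its cells.

    Parameters
    ----------
    treated_strata : list of (session_id, mobile, immobile)
    pooled_control : (mobile, immobile)
    """
    cm, ci = pooled_control
    if cm + ci == 0 or not treated_strata:
        raise ValueError("need nonzero pooled control counts and >= 1 treated session")
    logs, var_treat, var_ctrl, weights = [], [], [], []
    for _sid, tm, ti in treated_strata:
        a, b, c, d = float(tm), float(ti), float(cm), float(ci)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        logs.append(np.log((a * d) / (b * c)))
        var_treat.append(1 / a + 1 / b)
        var_ctrl.append(1 / c + 1 / d)
        weights.append(tm + ti)
    logs, var_treat, var_ctrl, weights = map(np.asarray, (logs, var_treat, var_ctrl, weights))
    w = weights / weights.sum()
    mean_log = float(w @ logs)
    # the pooled-control term is the same random quantity in every session's
    # log OR, so its contribution is perfectly correlated across sessions
    var = float(w**2 @ var_treat) + float(w @ np.sqrt(var_ctrl)) ** 2
    se = np.sqrt(var)
    z975 = stats.norm.ppf(0.975)
    lo, hi = np.exp(mean_log + np.array([-z975, z975]) * se)
    z = mean_log / se if se > 0 else 0.0
    return OddsRatioResult(
        common_or=float(np.exp(mean_log)),
        ci95=(float(lo), float(hi)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        method="treated-weighted",
        n_strata=len(treated_strata),
    )
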