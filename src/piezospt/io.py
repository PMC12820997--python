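"""Trajectory CSV I/O, run manifests, and the staged pipeline driver.

Shared trajectory schema (one row per frame slot)::

    traj_id,frame,x_um,y_um,cell_id,session_id,condition

Empty ``x_um``/``y_um`` fields encode gap placeholders; frames are 0-based
contiguous integers within a trajectory; coordinates are micrometers.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .trajectory import Trajectory

__all__ = ["read_trajectories", "write_trajectories", "RunManifest", "run_pipeline"]

SCHEMA = ["traj_id", "frame", "x_um", "y_um", "cell_id", "session_id", "condition"]


def write_trajectories(trajectories: list[Trajectory], path) -> None:
    rows = []
    for t in trajectories:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append(
                {
                    "traj_id": t.traj_id,
                    "frame": int(f),
                    "x_um": x if np.isfinite(x) else None,
                    "y_um": y if np.isfinite(y) else None,
                    "cell_id": t.meta.get("cell_id"),
                    "session_id": t.meta.get("session_id"),
                    "condition": t.meta.get("condition"),
                }
            )
    pd.DataFrame(rows, columns=SCHEMA).to_csv(path, index=False)


def read_trajectories(path, dt: float) -> list[Trajectory]:
    """Parse the shared CSV schema into trajectories.

    Empty coordinate fields become NaN gaps.  Duplicate (traj_id, frame) rows
    and non-monotone frames are rejected with the offending row numbers
    (1-based, counting the header as row 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in ("traj_id", "frame", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    dup = df.duplicated(subset=["traj_id", "frame"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]
        raise ValueError(f"duplicate (traj_id, frame) rows at file rows {rows}")
    trajectories = []
    for tid, sub in df.groupby("traj_id", sort=False):
        frames = sub["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            bad = int(sub.index[np.argmax(np.diff(frames) <= 0) + 1]) + 2
            raise ValueError(f"non-monotone frames for trajectory {tid} at file row {bad}")
        xy = sub[["x_um", "y_um"]].to_numpy(float)
        meta = {
            k: sub[k].iloc[0]
            for k in ("cell_id", "session_id", "condition")
            if k in sub.columns and pd.notna(sub[k].iloc[0])
        }
        trajectories.append(Trajectory(tid, frames, xy, dt, meta))
    return trajectories


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Audit record tying outputs to inputs, parameters, and seeds."""

    command: str
    parameters: dict
    seeds: dict
    inputs: dict = field(default_factory=dict)     # path -> sha256
    version: str = __version__
    python: str = platform.python_version()
    timestamp: str = ""

    def write(self, path) -> None:
        self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)

    @classmethod
    def for_run(cls, command: str, parameters: dict, seeds: dict, input_paths: list = ()) -> "RunManifest":
        return cls(
            command=command,
            parameters=parameters,
            seeds=seeds,
            inputs={str(p): _digest(p) for p in input_paths},
        )


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the staged live-cell analysis end to end, writing per-stage outputs.

    Stage order: read trajectories -> minimum-duration filter -> TAMSD ->
    sub-noise removal -> sRg classification -> mobile-class step/mixture
    analysis.  Calibration (epsilon, sRg threshold) must be supplied either
    inline (``epsilon``, ``srg_threshold``) or via ``calibration_json``.
    Every stage logs the trajectory counts in and out; failures abort with
    the stage name.

    Required config keys: ``tracks`` (CSV path), ``dt``; calibration as
    above.  Optional: ``n_max`` (default 20), ``fit_lag_range`` (default
    [1, 20]), ``min_duration_s`` (default 20), ``seed``.
    """
    from .calibration import CalibrationResult
    from .heterogeneity import extract_steps, fit_rayleigh_mixture, select_k
    from .mobility import classify
    from .tamsd import compute_tamsd, fit_power_law, remove_subnoise_trajectories

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": []}
    stage = "configure"
    try:
        dt = float(config["dt"])
        n_max = int(config.get("n_max", 20))
        fit_range = tuple(config.get("fit_lag_range", (1, 20)))
        min_dur = float(config.get("min_duration_s", 20.0))
        seed = int(config.get("seed", 0))
        if "calibration_json" in config:
            calib = CalibrationResult.from_json(config["calibration_json"])
            epsilon, threshold = calib.epsilon, calib.sRg_threshold
        elif "epsilon" in config and "srg_threshold" in config:
            epsilon, threshold = float(config["epsilon"]), float(config["srg_threshold"])
        else:
            raise ValueError(
                "classification needs calibration: pass 'calibration_json' or both 'epsilon' and 'srg_threshold'"
            )

        stage = "read"
        trajs = read_trajectories(config["tracks"], dt)
        log["stages"].append({"stage": stage, "n_out": len(trajs)})

        stage = "duration_filter"
        trajs = [t for t in trajs if t.duration_s >= min_dur]
        log["stages"].append({"stage": stage, "n_out": len(trajs)})

        stage = "tamsd"
        curves = [compute_tamsd(t, n_max) for t in trajs]
        tamsd_rows = [
            {"traj_id": c.traj_id, "lag_frames": int(n), "lag_s": n * c.dt, "tamsd_um2": v, "valid_pairs": int(vp)}
            for c in curves
            for n, v, vp in zip(c.lags, c.values, c.valid_pairs)
        ]
        pd.DataFrame(tamsd_rows).to_csv(out_dir / "tamsd.csv", index=False)
        log["stages"].append({"stage": stage, "n_out": len(curves)})

        stage = "subnoise_removal"
        trajs, curves, n_removed = remove_subnoise_trajectories(trajs, curves, epsilon, fit_range)
        log["stages"].append({"stage": stage, "n_out": len(trajs), "n_removed": n_removed})

        stage = "classify"
        results, session_counts = classify(trajs, threshold)
        pd.DataFrame(
            [{"traj_id": r.traj_id, "sRg": r.sRg, "label": r.label} for r in results]
        ).to_csv(out_dir / "labels.csv", index=False)
        n_mobile = sum(r.label == "mobile" for r in results)
        log["stages"].append(
            {"stage": stage, "n_mobile": n_mobile, "n_immobile": len(results) - n_mobile,
             "session_counts": {str(k): v for k, v in session_counts.items()}}
        )

        stage = "mobile_analysis"
        fit_rows = []
        alpha_rows = []
        for traj, curve, res in zip(trajs, curves, results):
            if res.label != "mobile":
                continue
            r = np.linalg.norm(extract_steps(traj).dxy, axis=1)
            fits = [fit_rayleigh_mixture(r, k, dt, seed=seed) for k in range(1, 5)]
            best = select_k(fits)
            fit_rows.append(
                {"traj_id": traj.traj_id, "k_selected": best.k,
                 **{f"p_{i+1}": p for i, p in enumerate(best.proportions)},
                 **{f"sigma_{i+1}_um": s for i, s in enumerate(best.sigmas)},
                 **{f"D_{i+1}_um2_s": d for i, d in enumerate(best.apparent_D)},
                 **{f"aic_{f.k}": f.aic for f in fits}}
            )
            try:
                alpha_rows.append({"traj_id": traj.traj_id, **vars(fit_power_law(curve, fit_range))})
            except ValueError:
                pass
        pd.DataFrame(fit_rows).to_csv(out_dir / "rayleigh_fits.csv", index=False)
        pd.DataFrame(alpha_rows).to_csv(out_dir / "powerlaw_fits.csv", index=False)
        log["stages"].append({"stage": stage, "n_mobile_analyzed": len(fit_rows)})

        RunManifest.for_run(
            "pipeline",
            {**config, "epsilon": epsilon, "srg_threshold": threshold},
            {"seed": seed},
            [config["tracks"]],
        ).write(out_dir / "manifest.json")
        with open(out_dir / "pipeline_log.json", "w") as fh:
            json.dump(log, fh, indent=2)
        return log
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc
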