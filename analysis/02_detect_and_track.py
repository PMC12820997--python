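"""Render a short movie from known walkers, then run detection and linking
and score the recovery against the ground truth.

Demonstrates that the DoG + threshold + Gaussian-centroid + 3-px greedy
linking chain recovers the simulated tracks with sub-0.15-px localization.
Writes results/detection_benchmark.json.
"""

import json
from pathlib import Path

import numpy as np

from piezospt.detect import DetectionParams, detect, dog_filter, filter_min_duration, id_switch_diagnostic, link
from piezospt.simulate import SimulationConfig, render_movie, simulate_brownian

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

ens = simulate_brownian(SimulationConfig(n_traj=12, n_points=40, dt=0.1, seed=21), D=0.02)
stack, truth = render_movie(ens, psf_sigma=1.3, amplitude=400, background=100,
                            noise_sd=20, image_shape=(224, 224), seed=22)
params = DetectionParams(dog_sigma_small=1.0, dog_sigma_large=3.0, auto_threshold_k=5.0, min_duration_s=2.0)
filtered = dog_filter(stack, params)
dets = {f: detect(filtered[f], stack[f].astype(float), params, f) for f in range(stack.shape[0])}
trajs = filter_min_duration(link(dets, params), params)

errs = []
for f in range(stack.shape[0]):
    sub = truth[truth.frame == f]
    for d in dets[f]:
        errs.append(float(np.sqrt((sub.x_px - d.x_px) ** 2 + (sub.y_px - d.y_px) ** 2).min()))
rmse = float(np.sqrt(np.mean(np.square(errs))))
report = id_switch_diagnostic(dets, trajs, params)

summary = {
    "n_true_tracks": len(ens.trajectories),
    "n_recovered_tracks": len(trajs),
    "n_detections": int(sum(len(v) for v in dets.values())),
    "localization_rmse_px": rmse,
    "id_switch_risk_fraction": report.risk_fraction,
    "mean_nn_distance_px": float(np.mean(list(report.frame_mean_nn_px.values()))),
}
with open(OUT / "detection_benchmark.json", "w") as fh:
    json.dump(summary, fh, indent=2)
print(json.dumps(summary, indent=2))
assert summary["n_recovered_tracks"] == summary["n_true_tracks"], "track recovery failed"
assert rmse < 0.15, "localization accuracy regression"
print("detection/linking recovers every simulated track with sub-0.15-px accuracy")
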