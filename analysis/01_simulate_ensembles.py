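"""Generate the study's synthetic datasets: a fixed-cell (noise-only)
ensemble for calibration and a live-cell ensemble mixing immobile puncta with
two-state mobile walkers across three simulated imaging sessions.

Writes trajectory CSVs and a truth-label table under results/data/.
"""

from pathlib import Path

import pandas as pd

from piezospt.io import write_trajectories
from piezospt.simulate import SimulationConfig, inject_gaps, simulate_immobile, simulate_two_state

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

DT = 0.1            # s, frame interval
N_POINTS = 200      # >= 20 s at 10 Hz, the minimum-duration cutoff
LOC_SIGMA = 0.02    # um, per-axis localization noise

# fixed cells: immobile puncta, apparent motion is localization noise only
fixed = simulate_immobile(SimulationConfig(n_traj=500, n_points=N_POINTS, dt=DT, loc_sigma=LOC_SIGMA, seed=11))
for t in fixed.trajectories:
    t.meta.update(condition="fixed", session_id="fix1")
write_trajectories(fixed.trajectories, OUT / "fixed_cells.csv")

# live cells: 40% immobile, 60% mobile two-state walkers (slow/fast step SDs
# 0.03/0.10 um, stationary mixing 0.5), spread over three sessions, with 5%
# skipped frames
n_imm, n_mob = 200, 300
imm = simulate_immobile(SimulationConfig(n_traj=n_imm, n_points=N_POINTS, dt=DT, loc_sigma=LOC_SIGMA, seed=12))
mob = simulate_two_state(
    SimulationConfig(n_traj=n_mob, n_points=N_POINTS, dt=DT, seed=13),
    p_fast=0.5, sigma_slow=0.03, sigma_fast=0.10,
)
mob = inject_gaps(mob, gap_prob=0.05, seed=14)
live, labels = [], []
for i, (t, lab) in enumerate(
    [(t, "immobile") for t in imm.trajectories] + [(t, "mobile") for t in mob.trajectories]
):
    t.traj_id = f"live{i:04d}"
    t.meta.update(condition="untreated", session_id=f"s{i % 3 + 1}")
    live.append(t)
    labels.append({"traj_id": t.traj_id, "true_label": lab, "session_id": t.meta["session_id"]})
write_trajectories(live, OUT / "live_cells.csv")
pd.DataFrame(labels).to_csv(OUT / "live_truth.csv", index=False)

print(f"fixed-cell ensemble : {len(fixed.trajectories)} trajectories -> {OUT / 'fixed_cells.csv'}")
print(f"live-cell ensemble  : {len(live)} trajectories ({n_imm} immobile + {n_mob} mobile) "
      f"-> {OUT / 'live_cells.csv'}")
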