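"""Generate the synthetic five-task MEG dataset and its stimulus protocol.

Builds the desk-scale dataset for one simulated participant — 500 cortical
dipoles, 64 sensors, 40 trials per task — applies the 95%-of-range trial
rejection, and writes the trial schedules, the sensor layout, and the full
run container.  Reports the stimulus amplitudes and the retention rate.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pursuitdecode import neurosim, protocol, workbench

OUT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    for frequency in (0.5, 0.8):
        traj = protocol.make_target_trajectory(frequency, 20.0)
        print(f"target {frequency} Hz: peak amplitude {traj.amplitude:.2f} deg")

    frames = []
    for k, task in enumerate(protocol.TASKS):
        schedules = protocol.make_trial_schedule(task, 100, seed=seed + k)
        frames.append(protocol.schedules_to_frame(schedules))
    schedule = pd.concat(frames, ignore_index=True)
    schedule.to_csv(OUT / "01_schedules.csv", index=False)
    print(f"wrote {len(schedule)} trial schedules "
          f"(pre-motion hold {schedule.pre_motion_s.min():.2f}-{schedule.pre_motion_s.max():.2f} s)")

    space = neurosim.make_source_space(500, seed=seed)
    spec = neurosim.make_default_subpopulations(space, seed=seed + 1)
    fm = neurosim.make_forward_model(space, 64, seed=seed + 2)
    pd.DataFrame(fm.sensor_positions, columns=["x", "y", "z"]).rename_axis(
        "sensor"
    ).to_csv(OUT / "01_sensor_layout.csv")

    rates = {}
    for k, task in enumerate(protocol.TASKS):
        sim = neurosim.simulate_task(task, space, spec, fm, n_trials=40,
                                     seed=seed + 100 + k)
        rejected = neurosim.reject_trials(sim.trials, recordable_range=5e4)
        rates[task] = rejected.retention_rate
    print("retention after 95%-range rejection:",
          {t: f"{r:.0%}" for t, r in rates.items()})


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
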