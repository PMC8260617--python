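"""Cross-task generalization of the trained decoders.

Builds the 5x5 train-task x test-task matrix of determination coefficients
over several seeded replicates, normalises each cell by its same-task
(diagonal) value, classifies cells as high/middle/low generalization, flags
permutation-significant cells with Benjamini-Hochberg control, and
categorises the dipoles shared between the tasks' selected sets.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pursuitdecode import evaluate, slir, workbench
from pursuitdecode.protocol import TASKS

OUT = Path(__file__).resolve().parent.parent / "results"
N_REPLICATES = 6


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)
    mats, frames, sharing_frames = [], [], []
    for rep in range(N_REPLICATES):
        task_data, _, _ = workbench.simulate_replicate_task_data(
            seed=seed + rep, n_dipoles=60, n_trials=10
        )
        m = evaluate.build_generalization_matrix(
            task_data, folds=10, seed=seed + rep, row_stride=3,
            n_perm=199 if rep == 0 else 0,
        )
        mats.append(m.R2)
        df = m.to_frame()
        df["replicate"] = rep
        frames.append(df)
        selected = {t: m.models[t].selected("position") for t in TASKS}
        sharing_frames.append(evaluate.categorize_shared_dipoles(selected)["fraction"])

    raw = pd.concat(frames, ignore_index=True)
    raw.to_csv(OUT / "04_matrix.csv", index=False)

    norm = evaluate.normalize_scores(mats, mode="by-test")
    rows = []
    for a, train in enumerate(TASKS):
        for b, test in enumerate(TASKS):
            pooled = norm.mean[a, b].mean()
            rows.append(
                {
                    "train": train, "test": test,
                    "nR2_mean": pooled,
                    "nR2_sd": norm.sd[a, b].mean(),
                    "class": evaluate.classify_generalization(pooled),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "04_normalized.csv", index=False)

    print(f"normalized determination coefficients (mean of {N_REPLICATES} replicates, "
          "position+velocity pooled):")
    grid = table.pivot(index="train", columns="test", values="nR2_mean").loc[
        list(TASKS), list(TASKS)]
    print(grid.round(2))
    cls = table.pivot(index="train", columns="test", values="class").loc[
        list(TASKS), list(TASKS)]
    print("\nclassification (high >= 0.6, middle >= 0.2, low < 0.2):")
    print(cls)

    first = frames[0]
    reject, _ = evaluate.bh_correct(first["p_R2"].to_numpy(), alpha=0.05)
    print(f"\npermutation-significant cells (BH, replicate 0): "
          f"{reject.sum()}/{len(reject)}")

    sharing = pd.concat(sharing_frames, axis=1).mean(axis=1)
    sharing.index = evaluate.SHARING_CATEGORIES
    sharing.rename("mean_fraction").to_csv(OUT / "04_sharing.csv")
    shared = 1.0 - sharing[[c for c in sharing.index if c.startswith("exclusive-")]].sum()
    print(f"\nfraction of selected dipoles shared by >= 2 tasks: {shared:.0%}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
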