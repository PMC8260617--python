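"""Within-subject ANOVA of current intensities and decoding coefficients.

Treats seeded replicates as blocks: a one-way randomized-block ANOVA with
Tukey HSD asks whether precentral current intensities differ between the five
tasks (they should — eye-movement currents are present only under overt
pursuit), and a two-way block ANOVA on the determination coefficients tests
the train-task x test-task interaction behind the generalization asymmetry.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from pursuitdecode import evaluate, groupstats, inverse, neurosim, workbench
from pursuitdecode.protocol import TASKS

OUT = Path(__file__).resolve().parent.parent / "results"
N_BLOCKS = 6


def main(seed: int = 1) -> None:
    OUT.mkdir(exist_ok=True)

    # regional intensities per replicate (block) x task, from ground-truth currents
    intensities = np.zeros((N_BLOCKS, len(TASKS)))
    for blk in range(N_BLOCKS):
        task_data, space, spec = workbench.simulate_replicate_task_data(
            seed=seed + blk, n_dipoles=60, n_trials=6
        )
        pre = space.region_indices("PreCC")
        for k, task in enumerate(TASKS):
            cur = np.stack(task_data[task].currents)
            intensities[blk, k] = np.abs(cur[:, pre]).mean()

    tab = groupstats.rb_anova1(intensities).set_index("effect")
    tab.to_csv(OUT / "05_anova_precc.csv")
    F, p = tab.loc["treatment", "F"], tab.loc["treatment", "p"]
    df1, df2 = int(tab.loc["treatment", "df"]), int(tab.loc["error", "df"])
    print(f"PreCC intensity, one-way block ANOVA: F({df1}, {df2}) = {F:.2f}, p = {p:.4g}")

    tukey = groupstats.tukey_hsd(
        intensities.mean(axis=0), tab.loc["error", "MS"], df2, N_BLOCKS
    )
    tukey["pair"] = [f"{TASKS[a]} vs {TASKS[b]}"
                     for a, b in zip(tukey.level_a, tukey.level_b)]
    tukey.to_csv(OUT / "05_tukey_precc.csv", index=False)
    sig = tukey[tukey.p < 0.05]
    print("Tukey HSD pairs with p < 0.05:")
    print(sig[["pair", "diff", "p"]].round(4).to_string(index=False))

    # two-way block ANOVA on determination coefficients (train x test)
    R2 = np.zeros((N_BLOCKS, len(TASKS), len(TASKS)))
    for blk in range(N_BLOCKS):
        task_data, _, _ = workbench.simulate_replicate_task_data(
            seed=seed + blk, n_dipoles=60, n_trials=10
        )
        m = evaluate.build_generalization_matrix(
            task_data, folds=10, seed=seed + blk, row_stride=3
        )
        R2[blk] = m.R2.mean(axis=2)
    tab2 = groupstats.rb_anova2(R2).set_index("effect")
    tab2.to_csv(OUT / "05_anova_generalization.csv")
    print("\ndetermination coefficients, two-way block ANOVA (A=train, B=test):")
    print(tab2.loc[["A", "B", "A:B"], ["df", "F", "p"]].round(4))

    simple = groupstats.simple_main_effects(R2, fix="B")
    rows = [
        {"test_task": TASKS[lvl],
         "F": t.set_index('effect').loc['treatment', 'F'],
         "p": t.set_index('effect').loc['treatment', 'p']}
        for lvl, t in simple.items()
    ]
    se = pd.DataFrame(rows)
    se.to_csv(OUT / "05_simple_effects.csv", index=False)
    print("\nsimple main effect of training task at each test task:")
    print(se.round(4).to_string(index=False))


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
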