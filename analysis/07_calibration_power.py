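"""Calibration and power of the screen's statistics over generator seeds:
resampling null/planted, knockdown recovery, flank chi-square, and kernel
type-I error."""

import os

import numpy as np
import pandas as pd

from runcommon import RESULTS
from circscreen.experiments import (flank_experiment, kd_experiment,
                                    resampling_experiment, type_i_error_study)

if __name__ == "__main__":
    rows = []
    power = [resampling_experiment(s, 3.0)["empirical_p"] for s in range(100)]
    rows.append(("resampling_power_pct_p_le_0.01",
                 100 * float(np.mean(np.array(power) <= 0.01)), 100))
    null = [resampling_experiment(s, 1.0)["empirical_p"] for s in range(200)]
    rows.append(("resampling_null_pct_p_le_0.1",
                 100 * float(np.mean(np.array(null) <= 0.1)), 200))
    kd = [kd_experiment(s) for s in range(100)]
    rows.append(("kd_mean_decrease_pct",
                 -100 * float(np.mean([r["flanked_relative_change"] for r in kd])), 100))
    rows.append(("kd_pct_complement_nonsignificant",
                 100 * float(np.mean([r["complement_p"] >= 0.05 for r in kd])), 100))
    flank = [flank_experiment(s) for s in range(10)]
    rows.append(("flank_rbp_mean_fold", float(np.mean([r["fold"] for r in flank])), 10))
    t1 = type_i_error_study(seed=0)
    for key in ("chi_square_2x2", "fisher_one_tailed", "wilcoxon_rank_sum", "welch_t_test"):
        rows.append((f"type_i_error_{key}", t1[key], 2000))
    table = pd.DataFrame(rows, columns=["quantity", "value", "n"])
    os.makedirs(RESULTS, exist_ok=True)
    table.to_csv(os.path.join(RESULTS, "07_calibration_power.tsv"), sep="\t", index=False)
    print(table.to_string(index=False))
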