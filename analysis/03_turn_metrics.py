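#!/usr/bin/env python
"""Per-turn kinetics and kinematics for every conditioned trial.

Computes the Level-0 quantities per turn (total/outside/inside limb
force, limb difference, arc-fit radius, radial force, ratio of force
application, velocity-normalized energy dissipation, path length, turn
time) and averages them at course and section level.

Writes per-athlete turn_metrics.csv / run_summary.json next to the
trial data and results/tables/course_sectional_means.csv with the
cohort mean +/- SD per variable and dataset.
"""
import argparse
from pathlib import Path

import pandas as pd

from gsforce import process_run, segment_run
from gsforce.io import read_raw_run, write_run_summary, write_turn_metrics
from gsforce.metrics import process_metrics
from gsforce.stats import SECTION_VARIABLES, cohort_table

DATASETS = ("course", "speed", "overspeed", "flat")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    summaries = []
    for rdir in sorted(args.scratch.glob("athlete_*/raw")):
        base = rdir.parent
        synced = process_run(read_raw_run(rdir))
        summary = process_metrics(synced, segment_run(synced))
        write_turn_metrics(summary, base / "turn_metrics.csv")
        write_run_summary(summary, base / "run_summary.json")
        summaries.append(summary)

    table = cohort_table(summaries)
    rows = []
    for var in ["T"] + SECTION_VARIABLES:
        row = {"variable": var}
        for ds in DATASETS:
            col = var if var == "T" else f"{var}_{ds}"
            if col in table:
                row[f"{ds}_mean"] = table[col].mean()
                row[f"{ds}_sd"] = table[col].std(ddof=1)
        rows.append(row)
    out = args.results / "tables"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).set_index("variable").to_csv(
        out / "course_sectional_means.csv", float_format="%.4f"
    )

    print(f"Summarized {len(summaries)} athletes.")
    print(
        "Course means: F_tot {:.2f} BW, F_out {:.2f} BW, F_ins {:.2f} BW, "
        "F_r {:.2f} BW, RF {:.2f}, de_mech/v_in {:.2f} J*s/kg/m, T {:.2f} s".format(
            table["f_tot_course"].mean(), table["f_out_course"].mean(),
            table["f_ins_course"].mean(), table["f_r_course"].mean(),
            table["rf_course"].mean(), table["de_mech_per_vin_course"].mean(),
            table["T"].mean(),
        )
    )


if __name__ == "__main__":
    main()
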