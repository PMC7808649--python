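#!/usr/bin/env python
"""Fit the stepped statistical model on the processed cohort.

Level 1: stepwise regression of course time on sectional performance
parameters (de_mech/v_in, L).  Level 2: correlations of radial force
with course time and energy dissipation.  Level 3: stepwise regression
of radial force on total force and the ratio of force application.
Level 4: stepwise regression of total force on outside-limb force and
limb imbalance.  Each level runs on the course dataset and the three
sections.

Writes results/stepped_report.json plus one CSV per level under
results/tables/ and prints the headline numbers.
"""
import argparse
from pathlib import Path

import pandas as pd

from gsforce.io import dump_json, read_run_summary
from gsforce.stats import DATASETS, run_stepped_model


def _stepwise_frame(level: dict) -> pd.DataFrame:
    rows = []
    for ds, res in level.items():
        if res.empty:
            rows.append({"dataset": ds, "predictor": "(no clear model prediction)"})
            continue
        for name in res.entered:
            rows.append({
                "dataset": ds, "predictor": name,
                "std_beta": res.std_beta[name], "p": res.p_values[name],
                "r2_change": res.r2_change[name], "F": res.f_stat,
                "df": f"{res.df[0]},{res.df[1]}", "model_adj_r2": res.adj_r2,
            })
    return pd.DataFrame(rows)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--scratch", type=Path, default=Path("scratch/cohort"))
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    summaries = [read_run_summary(p)
                 for p in sorted(args.scratch.glob("athlete_*/run_summary.json"))]
    report = run_stepped_model(summaries)

    out = args.results / "tables"
    out.mkdir(parents=True, exist_ok=True)
    dump_json(report.to_dict(), args.results / "stepped_report.json")
    _stepwise_frame(report.level1).to_csv(out / "level1_course_time.csv", index=False)
    pd.DataFrame([
        {"dataset": ds, "against": key, "r": c.r, "ci_low": c.ci_low,
         "ci_high": c.ci_high, "p": c.p, "magnitude": c.magnitude}
        for ds, cs in report.level2.items() for key, c in cs.items()
    ]).to_csv(out / "level2_radial_force_correlations.csv", index=False)
    _stepwise_frame(report.level3).to_csv(out / "level3_radial_force.csv", index=False)
    _stepwise_frame(report.level4).to_csv(out / "level4_total_force.csv", index=False)

    print(f"Stepped model on {report.n_athletes} athletes, datasets: {', '.join(DATASETS)}.")
    l1 = report.level1["course"]
    if not l1.empty:
        print(f"Level 1 (course): T predicted by {l1.entered} "
              f"(std beta {l1.std_beta[l1.entered[0]]:+.2f}, adj R2 {l1.adj_r2:.3f}).")
    l2 = report.level2["course"]
    print(f"Level 2 (course): r(F_r, T) = {l2['T'].r:+.3f} [{l2['T'].magnitude}], "
          f"r(F_r, de_mech/v_in) = {l2['de_mech_per_vin'].r:+.3f} "
          f"[{l2['de_mech_per_vin'].magnitude}].")
    l3 = report.level3["course"]
    print(f"Level 3 (course): F_r = f(F_tot, RF), model R2 {l3.model_r2:.4f} "
          f"(adj {l3.adj_r2:.4f}); betas "
          + ", ".join(f"{k} {v:+.2f}" for k, v in l3.std_beta.items()) + ".")
    l4 = report.level4["course"]
    print(f"Level 4 (course): F_tot = f(F_out, F_diff); betas "
          + ", ".join(f"{k} {v:+.2f}" for k, v in l4.std_beta.items())
          + f"; adj R2 {l4.adj_r2:.4f}.")


if __name__ == "__main__":
    main()
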