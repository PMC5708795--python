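"""Preset calibration report: measured cohort summaries vs. published targets.

The generator presets in ektopo.synthetic were tuned once against the
published group-level summaries (posterior color grade means, total
spherical aberration at 6 mm, BSCVA, and the pooled BSCVA-grade
correlation) by iterating this measurement:

    python scripts/calibrate.py [--n 200] [--seed 20170]

Knobs used during tuning, in decreasing order of leverage:
  * posterior_R / posterior_Q          -> control and baseline band structure
  * bump_amplitude + time_decay[bump]  -> group grade trajectories
  * posterior_steepening (+ decay)     -> early-postop DMEK background
  * anterior_q_shift (+ decay)         -> group total SA at 6 mm
  * hoa_* scales (+ decay)             -> HOA magnitudes / SA dispersion
  * BscvaModel coefficients            -> BSCVA means and pooled correlation

The shipped values are frozen; this script only reports how a cohort
generated by them compares with the targets. Run it after any preset
change.
"""

from __future__ import annotations

import argparse

import numpy as np

from ektopo.pipeline import annotate_records, cohort_table
from ektopo.stats import pearson_r
from ektopo.synthetic import CohortConfig, sample_cohort

# Published group-level summaries used as calibration targets.
TARGETS = {
    ("control", "pre"): {"grade": 0.44, "sa_total_6mm": 0.13, "bscva_logmar": -0.03},
    ("DMEK", "1m"): {"grade": 2.3},
    ("DMEK", "3m"): {"grade": 1.4, "sa_total_6mm": 0.23},
    ("DMEK", "6m"): {"grade": 1.2, "sa_total_6mm": 0.19, "bscva_logmar": 0.03},
    ("DSAEK", "1m"): {"grade": 4.4},
    ("DSAEK", "3m"): {"grade": 3.6, "sa_total_6mm": 0.42},
    ("DSAEK", "6m"): {"grade": 2.8, "sa_total_6mm": 0.34, "bscva_logmar": 0.25},
}
POOLED_R_TARGET = 0.664


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n", type=int, default=200, help="eyes per group")
    ap.add_argument("--seed", type=int, default=20170)
    args = ap.parse_args()

    cfg = CohortConfig(sizes={"control": args.n, "DMEK": args.n, "DSAEK": args.n}, seed=args.seed)
    records = sample_cohort(cfg)
    annotate_records(records, bscva_model=cfg.bscva_model)
    df = cohort_table(records)

    print(f"{'group':8s} {'tp':4s} {'quantity':16s} {'measured':>9s} {'target':>7s} {'2*SE':>6s}")
    for (group, tp), targets in TARGETS.items():
        sub = df[(df.group == group) & (df.timepoint == tp)]
        for col, target in targets.items():
            vals = sub[col].to_numpy()
            se2 = 2 * vals.std(ddof=1) / np.sqrt(len(vals))
            print(f"{group:8s} {tp:4s} {col:16s} {vals.mean():9.3f} {target:7.2f} {se2:6.3f}")

    pooled = df[df.group.isin(["DMEK", "DSAEK"]) & df.timepoint.isin(["1m", "3m", "6m"])]
    r = pearson_r(pooled["grade"], pooled["bscva_logmar"]).r
    print(f"\npooled postop r(BSCVA, grade) = {r:.3f}  (target {POOLED_R_TARGET})")

    print("\nposterior SA ordering (6 m):",
          " < ".join(f"{g}={df[(df.group == g) & (df.timepoint == t)]['sa_posterior_6mm'].mean():.3f}"
                     for g, t in (("control", "pre"), ("DMEK", "6m"), ("DSAEK", "6m"))))


if __name__ == "__main__":
    main()
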