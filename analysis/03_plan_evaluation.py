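#!/usr/bin/env python
"""Build gradient-based and CT-based plans per case and compare dosimetry.

For each phantom the gradient GTV and the CT GTV are expanded to CTV
(3 cm craniocaudal, 1 cm lateral/AP) and PTV (+0.5 cm) on a 2.5 mm
planning grid, a 60 Gy synthetic conformal dose is generated, and the
organ-at-risk dose-volume metrics are recorded.  Writes
``results/plan_metrics.csv``.
"""

from pathlib import Path

import pandas as pd

from petgtv.phantoms import make_cohort, make_oar_set
from petgtv.segmentation import emulate_ct_delineation, segment_gradient
from petgtv.study import StudyConfig, plan_for_gtv, planning_grid_for

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = StudyConfig()
    cases = make_cohort(cfg.n_cases, cfg.length_range_cm,
                        template=cfg.phantom_template(), seed=cfg.seed,
                        radius_range_mm=cfg.radius_range_mm)
    grid = planning_grid_for(cases[0].pet, cfg.planning_spacing_mm)
    oars = make_oar_set(grid)
    rows = []
    for case in cases:
        gtvs = {"GRAD": segment_gradient(case.pet, case.pet.center()),
                "CT": emulate_ct_delineation(case.ct_like)}
        row = {"case": case.case_id}
        for plan_name, gtv in gtvs.items():
            _, _, _, pm = plan_for_gtv(gtv, grid, oars, cfg)
            for metric, value in pm.as_dict().items():
                row[f"{metric}_{plan_name}"] = value
        rows.append(row)
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "plan_metrics.csv", index=False, float_format="%.5g")

    print("Per-plan means over the cohort (GRAD vs CT):")
    for m in ("lung_v5", "lung_v10", "lung_v20", "lung_v30", "mld",
              "heart_v30", "heart_v40", "mhd", "cord_dmax", "ci", "hi"):
        g, c = df[f"{m}_GRAD"], df[f"{m}_CT"]
        print(f"  {m:<10s} {g.mean():7.2f} ± {g.std(ddof=1):5.2f}   "
              f"{c.mean():7.2f} ± {c.std(ddof=1):5.2f}")
    ok = all((df[f"{m}_GRAD"] <= df[f"{m}_CT"] + 1e-9).all()
             for m in ("lung_v5", "lung_v10", "lung_v20", "lung_v30",
                       "lung_v40", "mld", "heart_v30", "heart_v40", "mhd"))
    print(f"\nEvery plan covers >=95% of its PTV at 60 Gy "
          f"(min {df[['ptv_coverage_pct_GRAD','ptv_coverage_pct_CT']].min().min():.2f}%) "
          f"with hotspot < 66 Gy "
          f"(max {df[['dmax_gy_GRAD','dmax_gy_CT']].max().max():.2f} Gy).")
    print("Gradient-based plans spare lung and heart on every case:", ok)


if __name__ == "__main__":
    main()
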