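#!/usr/bin/env python
"""Forward-simulate the three strain presets across the lignin series.

For each strain archetype and each fermentation lignin level (0-3.75 g/L)
the cofermentation model is integrated for 72 h; the script reports the
fermentation time (first time total residual sugar < 0.5 g/L), maximum
biomass and lactate, and the derived performance metrics, and writes the
table to results/simulated_performance.csv plus one example trajectory
per strain under results/trajectories/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from coferm.metrics import RunSummary, yields
from coferm.model import FermentState, fermentation_time, simulate
from coferm.synth import FERMENT_LIGNIN_LEVELS, STRAIN_PRESETS, SUGAR_PRESETS

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    (RESULTS / "trajectories").mkdir(parents=True, exist_ok=True)
    s0 = SUGAR_PRESETS["AM"]
    rows = []
    for strain, params in STRAIN_PRESETS.items():
        for lignin in FERMENT_LIGNIN_LEVELS:
            init = FermentState(0.0, 0.03, s0[0], s0[1], s0[2], 0.0, lignin)
            traj = simulate(params, init, np.arange(0.0, 72.01, 0.5))
            d = traj.data
            ft = fermentation_time(traj)
            at_ft = d[d.t_h <= ft]
            summary = RunSummary(
                d.X_gL.min(), at_ft.X_gL.max(),
                at_ft.glc_gL.min(), d.glc_gL.max(),
                at_ft.xyl_gL.min(), d.xyl_gL.max(),
                at_ft.ara_gL.min(), d.ara_gL.max(),
                at_ft.la_gL.max(), ft,
            )
            row = {"strain": strain, "lignin_gL": lignin, "FT_h": ft,
                   "X_max_gL": round(at_ft.X_gL.max(), 3),
                   "LA_max_gL": round(at_ft.la_gL.max(), 2)}
            row.update({k: round(v, 4) for k, v in yields(summary).items()})
            rows.append(row)
            if lignin == 0.0:
                d.to_csv(RESULTS / "trajectories" / f"{strain}_lignin0.csv",
                         index=False)
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "simulated_performance.csv", index=False)
    print(table.to_string(index=False))
    fast = table[(table.strain == "dsm2314") & (table.lignin_gL == 0.0)].iloc[0]
    print(
        f"\nFast strain without lignin: FT {fast.FT_h:g} h, "
        f"{fast.LA_max_gL:.1f} g/L lactate, P = {fast.P:.3f} g/L/h — the "
        "scale of the reference fermentations. Lignin lengthens FT and "
        "lowers productivity monotonically for the sensitive strains."
    )


if __name__ == "__main__":
    sys.exit(main())
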