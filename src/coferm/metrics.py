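"""Derived fermentation performance quantities.

From a run summary (min/max concentrations of biomass, sugars and lactate
plus the fermentation time FT) the module derives:

* volumetric productivity  P = C_LA,max / FT               (g/L/h)
* lactate yield on sugar   Y_LA/Sub = C_LA,max / sum_i C_i,max
* biomass yield on sugar   Y_BM/Sub = C_BM,max / sum_i C_i,max
* lactate yield on biomass Y_LA/BM = C_LA,max / C_BM,max

Substrate-based yields use the total *supplied* sugar (sum of per-sugar
maxima) as the denominator, and biomass yields the biomass maximum rather
than the baseline-subtracted increment — both conventions verified
arithmetically against the fully-consumed reference runs. Because runs
with residual sugar admit a consumed-sugar convention instead, yields on
consumed sugar (sum of max - min) are reported alongside.

Also included: the linear total-cell-count regression TCC = 1.66e12 * BM
relating plate turbidimetry to dry biomass, with its inverse.

Optical purity (% L-(+)-lactate) is measured chirally upstream and is a
passthrough field here.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

TCC_PER_GRAM = 1.66e12  # cells per g biomass, from the TCC-vs-BM regression

#: RunSummary CSV schema (one row per fermentation)
SUMMARY_COLUMNS = [
    "run_id", "lignin_gL",
    "C_BM_min", "C_BM_max",
    "C_Glc_min", "C_Glc_max",
    "C_Xyl_min", "C_Xyl_max",
    "C_Ara_min", "C_Ara_max",
    "C_LA_max", "FT_h", "purity_L_pct",
]


@dataclass
class RunSummary:
    """Initial/stop conditions of one fermentation (concentrations g/L, FT h)."""

    C_BM_min: float
    C_BM_max: float
    C_Glc_min: float
    C_Glc_max: float
    C_Xyl_min: float
    C_Xyl_max: float
    C_Ara_min: float
    C_Ara_max: float
    C_LA_max: float
    FT: float
    purity_L: float = float("nan")
    run_id: str = ""
    lignin_gL: float = 0.0

    def __post_init__(self) -> None:
        for s in ("BM", "Glc", "Xyl", "Ara"):
            lo = getattr(self, f"C_{s}_min")
            hi = getattr(self, f"C_{s}_max")
            if hi < lo:
                raise ValueError(f"C_{s}_max < C_{s}_min in run {self.run_id!r}")
        if self.FT <= 0:
            raise ValueError("FT must be > 0")


def productivity(C_LA_max: float, FT: float) -> float:
    """Volumetric lactate productivity P = C_LA,max / FT (g/L/h)."""
    if FT <= 0:
        raise ValueError("FT must be > 0")
    if C_LA_max < 0:
        raise ValueError("C_LA_max must be >= 0")
    return C_LA_max / FT


def yields(summary: RunSummary) -> dict:
    """Yield coefficients and sugar bookkeeping for one run."""
    supplied = summary.C_Glc_max + summary.C_Xyl_max + summary.C_Ara_max
    consumed = (
        (summary.C_Glc_max - summary.C_Glc_min)
        + (summary.C_Xyl_max - summary.C_Xyl_min)
        + (summary.C_Ara_max - summary.C_Ara_min)
    )
    if supplied <= 0:
        raise ValueError("no sugar supplied; substrate yields undefined")
    out = {
        "P": productivity(summary.C_LA_max, summary.FT),
        "sugar_supplied_total": supplied,
        "sugar_consumed_total": consumed,
        "Y_LA_Sub": summary.C_LA_max / supplied,
        "Y_BM_Sub": summary.C_BM_max / supplied,
        "Y_LA_Sub_consumed": summary.C_LA_max / consumed if consumed > 0 else float("nan"),
        "Y_BM_Sub_consumed": summary.C_BM_max / consumed if consumed > 0 else float("nan"),
    }
    if summary.C_BM_max > 0:
        out["Y_LA_BM"] = summary.C_LA_max / summary.C_BM_max
    else:
        out["Y_LA_BM"] = 0.0 if summary.C_LA_max == 0 else float("nan")
    if summary.C_LA_max == 0:
        out["Y_LA_Sub"] = 0.0
        out["Y_LA_BM"] = 0.0
    return out


def performance_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Apply productivity/yields to a RunSummary table (SUMMARY_COLUMNS)."""
    rows = []
    for _, r in summaries.iterrows():
        s = RunSummary(
            r.C_BM_min, r.C_BM_max, r.C_Glc_min, r.C_Glc_max,
            r.C_Xyl_min, r.C_Xyl_max, r.C_Ara_min, r.C_Ara_max,
            r.C_LA_max, r.FT_h, r.get("purity_L_pct", float("nan")),
            str(r.get("run_id", "")), float(r.get("lignin_gL", 0.0)),
        )
        row = {"run_id": s.run_id, "lignin_gL": s.lignin_gL}
        row.update(yields(s))
        row["purity_L_pct"] = s.purity_L
        rows.append(row)
    return pd.DataFrame(rows)


def tcc_from_biomass(BM: float) -> float:
    """Total cell count (cells/L) from biomass (g/L): TCC = 1.66e12 * BM."""
    if BM < 0:
        raise ValueError("biomass must be >= 0")
    return TCC_PER_GRAM * BM


def biomass_from_tcc(TCC: float) -> float:
    """Inverse of :func:`tcc_from_biomass`."""
    if TCC < 0:
        raise ValueError("TCC must be >= 0")
    return TCC / TCC_PER_GRAM
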