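"""Degree Heating Months (DHM) from monthly sea-surface temperature.

A DHM is a month whose mean SST strictly exceeds the regional coral
bleaching threshold (30.38 degC for Southeast Sulawesi). Years with at
least one DHM are flagged as thermal-stress years.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

DEFAULT_BLEACHING_THRESHOLD_C = 30.38


@dataclass
class ThermalStressResult:
    threshold_c: float
    dhm_by_year: dict[int, int] = field(default_factory=dict)

    @property
    def flagged_years(self) -> list[int]:
        return sorted(y for y, n in self.dhm_by_year.items() if n >= 1)

    def to_dict(self) -> dict:
        return {
            "threshold_c": self.threshold_c,
            "dhm_by_year": {int(y): int(n) for y, n in sorted(self.dhm_by_year.items())},
            "flagged_years": self.flagged_years,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)


def compute_dhm(sst: pd.DataFrame, threshold_c: float = DEFAULT_BLEACHING_THRESHOLD_C) -> ThermalStressResult:
    """Count, per year, the months whose mean SST exceeds the threshold.

    Ties at the threshold do not count ("exceeded" read strictly). Missing
    months contribute nothing; years with fewer than 12 months trigger a
    warning. Duplicate (year, month) rows are an error.
    """
    for col in ("year", "month", "sst_c"):
        if col not in sst.columns:
            raise ValueError(f"sst table missing column {col!r}")
    if sst.duplicated(subset=["year", "month"]).any():
        dup = sst[sst.duplicated(subset=["year", "month"], keep=False)]
        raise ValueError(f"duplicate (year, month) rows: {sorted(set(map(tuple, dup[['year','month']].values)))}")
    if not pd.api.types.is_numeric_dtype(sst["sst_c"]) or not sst["sst_c"].map(pd.notna).all() \
            or not pd.Series(sst["sst_c"]).apply(lambda v: abs(v) != float("inf")).all():
        raise ValueError("sst_c must be finite")

    months_per_year = sst.groupby("year")["month"].size()
    if (months_per_year > 12).any():
        raise ValueError("more than 12 months in a year")
    short = sorted(months_per_year.index[months_per_year < 12].tolist())
    if short:
        warnings.warn(f"years with fewer than 12 months of SST: {short}", stacklevel=2)

    exceed = sst.assign(hot=sst["sst_c"] > threshold_c).groupby("year")["hot"].sum()
    return ThermalStressResult(
        threshold_c=float(threshold_c),
        dhm_by_year={int(y): int(n) for y, n in exceed.items()},
    )
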