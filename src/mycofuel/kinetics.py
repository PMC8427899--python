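"""Fermentation time-course summaries and wastewater decontamination accounting.

Covers the bookkeeping side of an oleaginous fermentation: per-day lipid
content (% of dry cell weight), substrate-to-lipid yield coefficient
Y_L/C (g lipid per g substrate consumed), and, for effluent-grown cultures,
the percentage removal of each physicochemical wastewater parameter after
treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "KineticsError",
    "FermentationSeries",
    "WastewaterRecord",
    "WastewaterPanel",
    "lipid_content",
    "yield_coefficient",
    "series_summary",
    "removal_efficiency",
    "treatment_report",
]


class KineticsError(ValueError):
    """Invalid fermentation series or wastewater panel."""


@dataclass
class FermentationSeries:
    """Daily fermentation records plus the initial substrate level.

    ``data`` columns: ``day`` (int), ``biomass``, ``lipid``, ``starch``
    (residual substrate), all g/L, and optionally ``amylase`` (IU/mL).
    """

    data: pd.DataFrame
    initial_substrate: float

    def __post_init__(self) -> None:
        required = {"day", "biomass", "lipid", "starch"}
        missing = required - set(self.data.columns)
        if missing:
            raise KineticsError(f"missing columns: {sorted(missing)}")
        days = self.data["day"].to_numpy()
        if len(days) and not np.all(np.diff(days) > 0):
            raise KineticsError("days must be strictly increasing")
        for col in ("biomass", "lipid", "starch"):
            if (self.data[col] < 0).any():
                raise KineticsError(f"negative values in column {col!r}")
        if self.initial_substrate <= 0:
            raise KineticsError("initial substrate must be positive")
        # residual substrate cannot exceed what was supplied
        if (self.data["starch"] > self.initial_substrate + 1e-9).any():
            raise KineticsError(
                "residual substrate exceeds initial substrate"
            )

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple],
        initial_substrate: float,
        columns: Sequence[str] = ("day", "biomass", "lipid", "starch"),
    ) -> "FermentationSeries":
        df = pd.DataFrame(list(records), columns=list(columns))
        return cls(data=df, initial_substrate=initial_substrate)


def lipid_content(lipid: float, biomass: float) -> float:
    """Lipid content as % of dry cell weight: 100 * lipid / biomass.

    Reported values are conventionally rounded to 1 decimal; the exact
    ratio is returned here.
    """
    if biomass <= 0:
        raise KineticsError("biomass must be positive")
    if lipid < 0:
        raise KineticsError("lipid must be >= 0")
    return 100.0 * lipid / biomass


def yield_coefficient(
    lipid_produced: float, substrate_consumed: float, ndigits: int = 2
) -> float:
    """Substrate-to-lipid yield Y_L/C, g lipid per g substrate consumed.

    Rounded half-up to ``ndigits`` (2 by convention); pass ``ndigits=None``
    for the exact ratio.
    """
    if substrate_consumed <= 0:
        raise KineticsError("substrate consumed must be positive")
    if lipid_produced < 0:
        raise KineticsError("lipid produced must be >= 0")
    ratio = lipid_produced / substrate_consumed
    return ratio if ndigits is None else round_half_up(ratio, ndigits)


@dataclass
class SeriesSummary:
    """Per-day derived table and the argmax rows of a fermentation series."""

    table: pd.DataFrame
    peaks: dict


def series_summary(series: FermentationSeries) -> SeriesSummary:
    """Per-day lipid content, substrate consumption and Y_L/C with peaks.

    Days with zero (or negative) cumulative consumption get ``NaN`` yield
    and a ``zero_consumption`` flag rather than raising.  ``peaks`` reports
    the argmax day and value for biomass, lipid, lipid content and Y_L/C.
    """
    df = series.data
    if len(df) < 2:
        raise KineticsError("need at least 2 records to summarize kinetics")
    out = df.copy()
    out["substrate_consumed"] = series.initial_substrate - out["starch"]
    out["lipid_content_pct"] = [
        lipid_content(l, x) if x > 0 else np.nan
        for l, x in zip(out["lipid"], out["biomass"])
    ]
    ylc, flags = [], []
    for l, c in zip(out["lipid"], out["substrate_consumed"]):
        if c > 0:
            ylc.append(yield_coefficient(l, c))
            flags.append("")
        else:
            ylc.append(np.nan)
            flags.append("zero_consumption")
    out["y_lc"] = ylc
    out["flag"] = flags

    peaks: dict = {}
    for col, name in (
        ("biomass", "biomass"),
        ("lipid", "lipid"),
        ("lipid_content_pct", "lipid_content"),
        ("y_lc", "y_lc"),
    ):
        col_vals = out[col]
        if col_vals.notna().any():
            i = col_vals.idxmax()
            peaks[name] = {
                "day": int(out.loc[i, "day"]),
                "value": float(col_vals.loc[i]),
            }
        else:
            peaks[name] = {"day": None, "value": None}
    # yield at the lipid peak: the estimator reported for fermentations
    # ("maximum yield on the day of maximum lipid"); far more stable under
    # measurement noise than the raw per-day maximum, which is dominated by
    # early days with near-zero consumption
    if peaks["lipid"]["day"] is not None:
        i = out.index[out["day"] == peaks["lipid"]["day"]][0]
        v = out.loc[i, "y_lc"]
        peaks["y_lc_at_lipid_peak"] = {
            "day": peaks["lipid"]["day"],
            "value": None if pd.isna(v) else float(v),
        }
    return SeriesSummary(table=out, peaks=peaks)


@dataclass(frozen=True)
class WastewaterRecord:
    """One wastewater parameter before and after treatment."""

    parameter: str
    raw: float
    treated: float
    unit: str = "g/L"

    def __post_init__(self) -> None:
        if self.raw < 0 or self.treated < 0:
            raise KineticsError(
                f"{self.parameter}: raw/treated values must be >= 0"
            )


WastewaterPanel = list  # list[WastewaterRecord]


def removal_efficiency(raw: float, treated: float) -> float:
    """Percentage reduction of a parameter: 100 * (raw - treated) / raw.

    Equals 100 exactly when the parameter is removed completely; a treated
    value above raw yields a negative efficiency with a warning (the
    parameter increased during treatment, e.g. pH-coupled species).
    """
    if raw <= 0:
        raise KineticsError("raw value must be positive")
    if treated < 0:
        raise KineticsError("treated value must be >= 0")
    if treated > raw:
        warnings.warn(
            f"treated value {treated} exceeds raw {raw}; "
            "parameter increased during treatment",
            stacklevel=2,
        )
    return 100.0 * (raw - treated) / raw


def treatment_report(panel: Iterable[WastewaterRecord]) -> pd.DataFrame:
    """Removal-efficiency table for a raw/treated wastewater panel.

    ``reduction_pct`` is rounded half-up to 1 decimal as effluent reports
    print it; ``reduction_exact`` keeps full precision.
    """
    rows = []
    for rec in panel:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            eff = removal_efficiency(rec.raw, rec.treated)
        rows.append(
            {
                "parameter": rec.parameter,
                "unit": rec.unit,
                "raw": rec.raw,
                "treated": rec.treated,
                "reduction_exact": eff,
                "reduction_pct": round_half_up(eff, 1),
                "increased": rec.treated > rec.raw,
            }
        )
    if not rows:
        raise KineticsError("empty wastewater panel")
    return pd.DataFrame(rows)
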