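"""Empirical biodiesel fuel-property prediction from FAME composition.

Twelve properties are predicted from the weight-percent composition of a
FAME mixture using the mixing correlations in common use for microbial and
vegetable-oil biodiesel:

* kinematic viscosity (KV, mm^2/s at 40 degC), density (rho, g/cm^3 at
  20 degC) and higher heating value (HHV, MJ/kg) — per-ester closed forms of
  Ramirez-Verduzco type mixed linearly (log-linearly for KV) in the weight
  fraction,
* saponification value (SV, mg KOH/g), iodine value (IV, g I2/100 g) and the
  cetane number correlation CN = 46.3 + 5458/SV - 0.225*IV,
* degree of unsaturation DU = MUFA + 2*PUFA and oxidative stability
  OS = 117.9295 / (C18:2% + C18:3% + 2.5905),
* cold-flow set: long-chain saturated factor
  LCSF = 0.1*C16:0 + 0.5*C18:0 + 1*C20:0 + 1.5*C22:0 + 2*C24:0 and the
  linear predictors CFPP, CP, PP built on it / on C16:0.

Conventions
-----------
KV, rho and HHV consume the weight *fraction* (wt%/100); SV, IV, DU, OS,
LCSF, CP and PP consume raw weight-percent.  Under the default
``as_reported`` profile mode, a table whose identified species sum to less
than 100 % yields proportionally scaled KV/rho/HHV — intentional, so that
predictions computed from partially identified GC reports reproduce the
values such reports conventionally print.  Switch the profile to
``renormalized`` for closure to 100 %.

The cetane correlation is implemented with numerator 5458 (Krisnangkura's
constant): the value printed as "5.458" in some secondary sources is a
typographical slip which fails to reproduce any tabulated CN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .fame import FAMEProfile, FameError

__all__ = [
    "FuelPropertyReport",
    "StandardLimits",
    "kinematic_viscosity",
    "density",
    "higher_heating_value",
    "saponification_value",
    "iodine_value",
    "cetane_number",
    "degree_of_unsaturation",
    "oxidative_stability",
    "long_chain_saturated_factor",
    "cold_filter_plugging_point",
    "cloud_point",
    "pour_point",
    "compute_report",
    "load_standard_limits",
    "check_compliance",
]

# Cetane correlation numerator; see module docstring.
CN_NUMERATOR = 5458.0

_LCSF_WEIGHTS = {
    "C16:0": 0.1,
    "C18:0": 0.5,
    "C20:0": 1.0,
    "C22:0": 1.5,
    "C24:0": 2.0,
}


def _require_nonempty(profile: FAMEProfile) -> None:
    if not profile.entries:  # pragma: no cover - blocked by FAMEProfile
        raise FameError("no FAME entries")


def kinematic_viscosity(profile: FAMEProfile) -> float:
    """Kinematic viscosity at 40 degC, mm^2/s.

    ln(KV) = sum_i N_i * (-12.503 + 2.496*ln(Mw_i) - 0.178*D_i), with N_i
    the weight fraction of ester i, Mw_i its molecular weight and D_i its
    double-bond count.
    """
    _require_nonempty(profile)
    frac = profile.fractions()
    ln_v = sum(
        frac[fa.code]
        * (-12.503 + 2.496 * math.log(fa.mw_fame) - 0.178 * fa.double_bonds)
        for fa, _ in profile.entries
    )
    return math.exp(ln_v)


def density(profile: FAMEProfile) -> float:
    """Density at 20 degC, g/cm^3: sum_i N_i*(0.8463 + 4.9/Mw_i + 0.0118*D_i)."""
    _require_nonempty(profile)
    frac = profile.fractions()
    return sum(
        frac[fa.code]
        * (0.8463 + 4.9 / fa.mw_fame + 0.0118 * fa.double_bonds)
        for fa, _ in profile.entries
    )


def higher_heating_value(profile: FAMEProfile) -> float:
    """Higher heating value, MJ/kg: sum_i N_i*(46.19 - 1794/Mw_i - 0.21*D_i)."""
    _require_nonempty(profile)
    frac = profile.fractions()
    return sum(
        frac[fa.code]
        * (46.19 - 1794.0 / fa.mw_fame - 0.21 * fa.double_bonds)
        for fa, _ in profile.entries
    )


def saponification_value(profile: FAMEProfile) -> float:
    """Saponification value, mg KOH/g: sum_i 560*N_i/Mw_i with N_i in wt%."""
    _require_nonempty(profile)
    pct = profile.percentages()
    return sum(560.0 * pct[fa.code] / fa.mw_fame for fa, _ in profile.entries)


def iodine_value(profile: FAMEProfile) -> float:
    """Iodine value, g I2 per 100 g: sum_i 254*D_i*N_i/Mw_i with N_i in wt%."""
    _require_nonempty(profile)
    pct = profile.percentages()
    return sum(
        254.0 * fa.double_bonds * pct[fa.code] / fa.mw_fame
        for fa, _ in profile.entries
    )


def cetane_number(sv: float, iv: float) -> float:
    """Cetane number from SV and IV: CN = 46.3 + 5458/SV - 0.225*IV."""
    if sv <= 0:
        raise FameError("saponification value must be positive")
    return 46.3 + CN_NUMERATOR / sv - 0.225 * iv


def degree_of_unsaturation(mufa: float, pufa: float) -> float:
    """Degree of unsaturation, %: DU = MUFA + 2*PUFA (weight-percent)."""
    return mufa + 2.0 * pufa


def oxidative_stability(c18_2: float, c18_3: float) -> float:
    """Oxidative stability (induction time), h.

    OS = 117.9295 / (wt% C18:2 + wt% C18:3 + 2.5905); the offset keeps the
    prediction finite for fully saturated oils.
    """
    if c18_2 < 0 or c18_3 < 0:
        raise FameError("weight-percent arguments must be >= 0")
    return 117.9295 / (c18_2 + c18_3 + 2.5905)


def long_chain_saturated_factor(profile: FAMEProfile) -> float:
    """Long-chain saturated factor from C16..C24 saturated wt%.

    LCSF = 0.1*C16:0 + 0.5*C18:0 + 1*C20:0 + 1.5*C22:0 + 2*C24:0; species
    absent from the profile contribute zero.
    """
    _require_nonempty(profile)
    return sum(
        w * profile.wt_percent(code) for code, w in _LCSF_WEIGHTS.items()
    )


def cold_filter_plugging_point(lcsf: float) -> float:
    """Cold filter plugging point, degC: CFPP = 3.1417*LCSF - 16.477."""
    return 3.1417 * lcsf - 16.477


def cloud_point(c16_0: float) -> float:
    """Cloud point, degC, from palmitate wt%: CP = 0.526*C16:0 - 4.992."""
    return 0.526 * c16_0 - 4.992


def pour_point(c16_0: float) -> float:
    """Pour point, degC, from palmitate wt%: PP = 0.571*C16:0 - 12.24."""
    return 0.571 * c16_0 - 12.24


_PROPERTY_UNITS = {
    "kv": "mm^2/s",
    "density": "g/cm^3",
    "hhv": "MJ/kg",
    "sv": "mg/g",
    "iv": "g I2/100 g",
    "cn": "-",
    "du": "%",
    "os": "h",
    "lcsf": "-",
    "cfpp": "degC",
    "cp": "degC",
    "pp": "degC",
    "c18_3_percent": "%",
    "fame_ge4_db_percent": "%",
}


@dataclass
class FuelPropertyReport:
    """The twelve predicted fuel properties of one FAME profile.

    ``c18_3_percent`` (linolenate content) and ``fame_ge4_db_percent``
    (esters with >= 4 double bonds) are carried along because European
    biodiesel specifications bound them directly.

    ``notes`` records the conventions in force (normalization mode, cetane
    constant); ``flags`` records per-property computation failures instead
    of aborting the whole report.
    """

    label: str
    kv: float | None = None
    density: float | None = None
    hhv: float | None = None
    sv: float | None = None
    iv: float | None = None
    cn: float | None = None
    du: float | None = None
    os: float | None = None
    lcsf: float | None = None
    cfpp: float | None = None
    cp: float | None = None
    pp: float | None = None
    c18_3_percent: float | None = None
    fame_ge4_db_percent: float | None = None
    notes: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _PROPERTY_UNITS}
        d["label"] = self.label
        return d

    def as_series(self) -> pd.Series:
        return pd.Series(
            {k: getattr(self, k) for k in _PROPERTY_UNITS}, name=self.label
        )

    def rounded(self, ndigits: int = 2) -> dict:
        """Display form: values rounded, None preserved."""
        from ._util import round_half_up

        return {
            k: (None if getattr(self, k) is None
                else round_half_up(getattr(self, k), ndigits))
            for k in _PROPERTY_UNITS
        }


def compute_report(profile: FAMEProfile) -> FuelPropertyReport:
    """Predict all twelve fuel properties of a profile.

    CN is chained from the report's own SV and IV; DU from the profile's
    MUFA/PUFA aggregates; OS from its C18:2/C18:3 entries.  A property whose
    computation fails is left ``None`` with the reason in ``flags``.
    """
    report = FuelPropertyReport(label=profile.label)
    report.notes = {
        "normalization_mode": profile.normalization_mode,
        "cetane_constant": CN_NUMERATOR,
        "total_identified_percent": profile.total_percent,
    }

    def attempt(name, fn, *args):
        try:
            setattr(report, name, float(fn(*args)))
        except (FameError, ValueError, ZeroDivisionError) as exc:
            report.flags[name] = str(exc)

    attempt("kv", kinematic_viscosity, profile)
    attempt("density", density, profile)
    attempt("hhv", higher_heating_value, profile)
    attempt("sv", saponification_value, profile)
    attempt("iv", iodine_value, profile)
    if report.sv is not None and report.iv is not None:
        attempt("cn", cetane_number, report.sv, report.iv)
    attempt("du", degree_of_unsaturation, profile.mufa, profile.pufa)
    attempt(
        "os",
        oxidative_stability,
        profile.wt_percent("C18:2"),
        profile.wt_percent("C18:3"),
    )
    attempt("lcsf", long_chain_saturated_factor, profile)
    if report.lcsf is not None:
        attempt("cfpp", cold_filter_plugging_point, report.lcsf)
    attempt("cp", cloud_point, profile.wt_percent("C16:0"))
    attempt("pp", pour_point, profile.wt_percent("C16:0"))
    report.c18_3_percent = profile.wt_percent("C18:3")
    report.fame_ge4_db_percent = float(
        sum(
            profile.percentages()[fa.code]
            for fa, _ in profile.entries
            if fa.double_bonds >= 4
        )
    )
    return report


@dataclass(frozen=True)
class StandardLimits:
    """Per-property bounds of one biodiesel standard.

    ``bounds`` maps report field names to ``{"min": x}`` / ``{"max": y}`` /
    both; properties absent from the mapping are not specified by the
    standard.
    """

    standard_id: str
    bounds: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        for prop, b in self.bounds.items():
            lo, hi = b.get("min"), b.get("max")
            if lo is not None and hi is not None and lo > hi:
                raise ValueError(
                    f"{self.standard_id}/{prop}: min {lo} > max {hi}"
                )


def load_standard_limits(path: str | None = None) -> dict[str, StandardLimits]:
    """Load the shipped (or a user-supplied) standards-limits YAML.

    The shipped file transcribes the property bounds of ASTM D6751,
    EN 14214 and IS 15607 relevant to FAME-predicted properties.
    """
    if path is None:
        text = (
            resources.files("mycofuel").joinpath("data/standards.yaml")
            .read_text(encoding="utf-8")
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {
        sid: StandardLimits(standard_id=sid, bounds=props or {})
        for sid, props in raw["standards"].items()
    }


def check_compliance(
    report: FuelPropertyReport, limits: StandardLimits
) -> pd.DataFrame:
    """Verdict table of a report against one standard.

    One row per property with columns ``property, value, unit, minimum,
    maximum, verdict``; verdict is ``pass``, ``fail``, ``not_specified``
    (standard silent on the property) or ``not_computed`` (property flagged
    in the report).
    """
    rows = []
    for prop, unit in _PROPERTY_UNITS.items():
        value = getattr(report, prop)
        bound = limits.bounds.get(prop)
        if bound is None:
            verdict = "not_specified"
            lo = hi = None
        elif value is None:
            verdict = "not_computed"
            lo, hi = bound.get("min"), bound.get("max")
        else:
            lo, hi = bound.get("min"), bound.get("max")
            ok = (lo is None or value >= lo) and (hi is None or value <= hi)
            verdict = "pass" if ok else "fail"
        rows.append(
            {
                "property": prop,
                "value": value,
                "unit": unit,
                "minimum": lo,
                "maximum": hi,
                "verdict": verdict,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["standard_id"] = limits.standard_id
    return df
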