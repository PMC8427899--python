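"""Fatty-acid methyl ester (FAME) data model and GC-FID quantification.

Fatty acids are named in the chromatographer's ``Cn:d`` shorthand (``n``
acyl carbons, ``d`` double bonds).  Because biodiesel is the *methyl ester*
of the fatty acid, the molecular weight carried by :class:`FattyAcid` is the
mass of the methyl ester C_{n+1}H_{2(n+1)-2d}O2, not of the free acid: the
empirical fuel-property correlations downstream are parameterised on ester
masses.

A :class:`FAMEProfile` is a set of (species, weight-percent) pairs as a
GC-FID report prints them.  Microbial FAME tables routinely sum to less than
100 % (unidentified peaks are dropped), so the profile keeps the raw numbers
and exposes two conventions:

``as_reported``
    percentages are consumed exactly as printed (default);
``renormalized``
    percentages are rescaled so the identified species sum to 100 %.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "FameError",
    "FattyAcid",
    "FAMEProfile",
    "QuantStandard",
    "fame_formula_mass",
    "parse_fatty_acid",
    "build_profile",
    "quantify_fame",
    "FAME_REGISTRY",
]

# Standard atomic weights (IUPAC 2021, abridged).
_MASS_C = 12.011
_MASS_H = 1.008
_MASS_O = 15.999


class FameError(ValueError):
    """Invalid fatty-acid code or FAME profile."""


def fame_formula_mass(carbons: int, double_bonds: int) -> float:
    """Formula mass in g/mol of the methyl ester C_{n+1}H_{2(n+1)-2d}O2."""
    n_c = carbons + 1
    n_h = 2 * (carbons + 1) - 2 * double_bonds
    if n_h <= 0:
        raise FameError(
            f"C{carbons}:{double_bonds} has no valid methyl-ester formula"
        )
    return n_c * _MASS_C + n_h * _MASS_H + 2 * _MASS_O


@dataclass(frozen=True)
class FattyAcid:
    """One FAME species.

    Attributes
    ----------
    code : str
        ``Cn:d`` notation, e.g. ``"C18:1"``.
    carbons : int
        Acyl carbon count ``n``.
    double_bonds : int
        Number of C=C double bonds ``d``.
    mw_fame : float
        Molecular weight of the methyl ester, g/mol.
    common_name : str | None
        Trivial name of the ester where one exists.
    """

    code: str
    carbons: int
    double_bonds: int
    mw_fame: float
    common_name: str | None = None

    def __post_init__(self) -> None:
        if self.carbons <= 0:
            raise FameError(f"{self.code}: carbon count must be positive")
        if self.double_bonds < 0:
            raise FameError(f"{self.code}: double-bond count must be >= 0")
        # the carboxyl carbon cannot carry a chain C=C, so 2d < n
        if 2 * self.double_bonds >= self.carbons:
            raise FameError(
                f"{self.code}: {self.double_bonds} double bonds exceed "
                f"the n/2 bound for an acyl chain of {self.carbons} carbons"
            )
        if self.mw_fame <= 0:
            raise FameError(f"{self.code}: mw_fame must be positive")

    @property
    def saturation_class(self) -> str:
        """``SFA`` (d=0), ``MUFA`` (d=1) or ``PUFA`` (d>=2)."""
        if self.double_bonds == 0:
            return "SFA"
        if self.double_bonds == 1:
            return "MUFA"
        return "PUFA"


# Curated registry of the species seen in fungal single-cell oils.  Masses
# are formula-derived and agree with vendor certificates to < 0.1 g/mol.
_REGISTRY_SEED: Sequence[tuple[str, float, str]] = (
    ("C14:0", 242.40, "methyl myristate"),
    ("C16:0", 270.45, "methyl palmitate"),
    ("C16:1", 268.43, "methyl palmitoleate"),
    ("C17:1", 282.46, "methyl heptadecenoate"),
    ("C18:0", 298.50, "methyl stearate"),
    ("C18:1", 296.49, "methyl oleate"),
    ("C18:2", 294.47, "methyl linoleate"),
    ("C18:3", 292.46, "methyl linolenate"),
    ("C20:0", 326.56, "methyl arachidate"),
    ("C22:0", 354.61, "methyl behenate"),
    ("C24:0", 382.66, "methyl lignocerate"),
)

_CODE_RE = re.compile(r"^C(\d{1,2}):(\d{1,2})$")


def _make_registry() -> dict[str, FattyAcid]:
    reg: dict[str, FattyAcid] = {}
    for code, mw, name in _REGISTRY_SEED:
        m = _CODE_RE.match(code)
        assert m is not None
        reg[code] = FattyAcid(
            code=code,
            carbons=int(m.group(1)),
            double_bonds=int(m.group(2)),
            mw_fame=mw,
            common_name=name,
        )
    return reg


FAME_REGISTRY: dict[str, FattyAcid] = _make_registry()


def parse_fatty_acid(code: str) -> FattyAcid:
    """Parse a ``Cn:d`` code into a :class:`FattyAcid`.

    Known species come from the registry (with common name); unknown but
    chemically valid codes get a formula-derived methyl-ester mass.

    Both gamma- and alpha-linolenate map onto ``C18:3``: positional isomers
    share carbon count, unsaturation and molecular weight, which is all the
    property correlations see.

    Raises
    ------
    FameError
        If the code is malformed, outside C4..C24, or over-unsaturated.
    """
    code = code.strip()
    m = _CODE_RE.match(code)
    if m is None:
        raise FameError(
            f"malformed fatty-acid code {code!r}: expected 'Cn:d' "
            "(e.g. 'C18:1')"
        )
    carbons = int(m.group(1))
    double_bonds = int(m.group(2))
    if not 4 <= carbons <= 24:
        raise FameError(f"{code}: acyl carbon count must be in 4..24")
    if code in FAME_REGISTRY:
        return FAME_REGISTRY[code]
    return FattyAcid(
        code=code,
        carbons=carbons,
        double_bonds=double_bonds,
        mw_fame=fame_formula_mass(carbons, double_bonds),
    )


# Weight-percent totals may exceed 100 by at most this much in as_reported
# mode: printed tables carry 2-decimal rounding per species.
_TOTAL_SLACK = 0.5

_MODES = ("as_reported", "renormalized")


@dataclass
class FAMEProfile:
    """A FAME composition: (species, weight-percent) pairs plus provenance.

    ``wt_percent`` values are stored exactly as supplied; the active
    ``normalization_mode`` only changes what :meth:`percentages` and
    :meth:`fractions` hand to consumers.
    """

    entries: list[tuple[FattyAcid, float]]
    label: str = ""
    normalization_mode: str = "as_reported"

    def __post_init__(self) -> None:
        if self.normalization_mode not in _MODES:
            raise FameError(
                f"unknown normalization_mode {self.normalization_mode!r}"
            )
        if not self.entries:
            raise FameError("no FAME entries")
        seen: set[str] = set()
        for fa, wt in self.entries:
            if wt < 0:
                raise FameError(f"{fa.code}: negative weight-percent {wt}")
            if fa.code in seen:
                raise FameError(f"duplicate fatty-acid code {fa.code}")
            seen.add(fa.code)
        if self.total_percent > 100 + _TOTAL_SLACK:
            raise FameError(
                f"weight-percent total {self.total_percent:.4f} exceeds 100"
            )

    @property
    def total_percent(self) -> float:
        return float(sum(wt for _, wt in self.entries))

    def percentages(self) -> dict[str, float]:
        """Per-species weight-percent under the active normalization mode."""
        if self.normalization_mode == "renormalized":
            scale = 100.0 / self.total_percent
        else:
            scale = 1.0
        return {fa.code: wt * scale for fa, wt in self.entries}

    def fractions(self) -> dict[str, float]:
        """Per-species weight fraction (percent / 100)."""
        return {c: p / 100.0 for c, p in self.percentages().items()}

    def wt_percent(self, code: str) -> float:
        """Weight-percent of one species (0 if absent), active mode."""
        return self.percentages().get(code, 0.0)

    def _class_sum(self, cls: str) -> float:
        pct = self.percentages()
        return float(
            sum(pct[fa.code] for fa, _ in self.entries
                if fa.saturation_class == cls)
        )

    @property
    def sfa(self) -> float:
        """Saturated fatty-acid total, weight-percent."""
        return self._class_sum("SFA")

    @property
    def mufa(self) -> float:
        """Monounsaturated fatty-acid total, weight-percent."""
        return self._class_sum("MUFA")

    @property
    def pufa(self) -> float:
        """Polyunsaturated fatty-acid total, weight-percent."""
        return self._class_sum("PUFA")

    def with_mode(self, mode: str) -> "FAMEProfile":
        """Same composition under a different normalization convention."""
        return FAMEProfile(list(self.entries), self.label, mode)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "normalization_mode": self.normalization_mode,
            "entries": [
                {"fatty_acid": fa.code, "wt_percent": wt}
                for fa, wt in self.entries
            ],
        }

    def to_json(self) -> str:
        # repr-based float formatting in json round-trips bit-exact
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FAMEProfile":
        return build_profile(
            [(e["fatty_acid"], e["wt_percent"]) for e in d["entries"]],
            label=d.get("label", ""),
            mode=d.get("normalization_mode", "as_reported"),
        )

    @classmethod
    def from_json(cls, s: str) -> "FAMEProfile":
        return cls.from_dict(json.loads(s))


def build_profile(
    rows: Iterable[tuple[str, float]],
    label: str = "",
    mode: str = "as_reported",
) -> FAMEProfile:
    """Build a :class:`FAMEProfile` from (code, weight-percent) rows."""
    entries = [(parse_fatty_acid(code), float(wt)) for code, wt in rows]
    return FAMEProfile(entries=entries, label=label, normalization_mode=mode)


@dataclass(frozen=True)
class QuantStandard:
    """External-standard calibration for GC-FID FAME quantification."""

    std_conc: float
    std_area: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.std_conc <= 0:
            raise FameError("standard concentration must be positive")
        if self.std_area <= 0:
            raise FameError("standard peak area must be positive")
        if self.dilution_factor < 1:
            raise FameError("dilution factor must be >= 1")


def quantify_fame(
    std: QuantStandard, sample_area: float, sample_mass_mg: float
) -> float:
    """External-standard FAME weight-percent from GC-FID peak areas.

    Implements the single-point calibration

        wt% = (std_conc/std_area * sample_area/sample_mass_mg * DF) / 10000

    with ``DF`` the dilution factor.  Linear in both sample area and
    dilution factor.
    """
    if sample_mass_mg <= 0:
        raise FameError("sample mass must be positive (mg)")
    if sample_area < 0:
        raise FameError("sample peak area must be >= 0")
    return (
        std.std_conc / std.std_area
        * sample_area / sample_mass_mg
        * std.dilution_factor
    ) / 10000.0
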