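"""Schema-validated readers and writers for the package's CSV dialects.

All tables are plain UTF-8 CSV with dot decimals:

* FAME:        ``fatty_acid,wt_percent``
* kinetics:    ``day,biomass,lipid,starch[,amylase]``
* wastewater:  ``parameter,raw,treated,unit``
* spectrum:    ``wavenumber,absorbance`` (plus a minimal JCAMP-DX reader)

Schema violations raise :class:`SchemaError` naming the offending column or
row, so a CLI run fails with an actionable message instead of a traceback
deep inside pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fame import FAMEProfile, build_profile
from .ftir import Spectrum
from .kinetics import FermentationSeries, WastewaterRecord

__all__ = [
    "SchemaError",
    "read_fame_csv",
    "write_fame_csv",
    "read_kinetics_csv",
    "write_kinetics_csv",
    "read_wastewater_csv",
    "write_wastewater_csv",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcamp",
    "read_spectrum",
]


class SchemaError(ValueError):
    """Input table does not match its declared schema."""


def _read_csv(path: str | Path, required: tuple[str, ...],
              optional: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    unknown = [c for c in df.columns if c not in required + optional]
    if unknown:
        raise SchemaError(f"{path.name}: unexpected column(s) {unknown}")
    if df.empty:
        raise SchemaError(f"{path.name}: no data rows")
    return df


def _numeric(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(
                f"{name}: non-numeric value {df.loc[row, col]!r} "
                f"in column {col!r}, row {row}"
            )
        if vals.isna().any():
            row = int(vals.isna().idxmax())
            raise SchemaError(
                f"{name}: missing value in column {col!r}, row {row}"
            )
        df[col] = vals


def read_fame_csv(
    path: str | Path, label: str = "", mode: str = "as_reported"
) -> FAMEProfile:
    """Read a ``fatty_acid,wt_percent`` table into a FAMEProfile."""
    df = _read_csv(path, ("fatty_acid", "wt_percent"))
    _numeric(df, ("wt_percent",), Path(path).name)
    return build_profile(
        list(zip(df["fatty_acid"], df["wt_percent"])),
        label=label or Path(path).stem,
        mode=mode,
    )


def write_fame_csv(profile: FAMEProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "fatty_acid": [fa.code for fa, _ in profile.entries],
            "wt_percent": [wt for _, wt in profile.entries],
        }
    ).to_csv(path, index=False)


def read_kinetics_csv(
    path: str | Path, initial_substrate: float | None = None
) -> FermentationSeries:
    """Read a ``day,biomass,lipid,starch[,amylase]`` fermentation table.

    If ``initial_substrate`` is not given, the first row's residual starch
    is taken as the starting level (valid when sampling starts at
    inoculation).
    """
    df = _read_csv(
        path, ("day", "biomass", "lipid", "starch"), optional=("amylase",)
    )
    cols = tuple(c for c in df.columns)
    _numeric(df, cols, Path(path).name)
    if initial_substrate is None:
        initial_substrate = float(df["starch"].iloc[0])
    return FermentationSeries(data=df, initial_substrate=initial_substrate)


def write_kinetics_csv(series: FermentationSeries, path: str | Path) -> None:
    series.data.to_csv(path, index=False)


def read_wastewater_csv(path: str | Path) -> list[WastewaterRecord]:
    """Read a ``parameter,raw,treated,unit`` wastewater panel."""
    df = _read_csv(path, ("parameter", "raw", "treated", "unit"))
    _numeric(df, ("raw", "treated"), Path(path).name)
    return [
        WastewaterRecord(
            str(r.parameter), float(r.raw), float(r.treated), str(r.unit)
        )
        for r in df.itertuples()
    ]


def write_wastewater_csv(
    panel: list[WastewaterRecord], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "parameter": [r.parameter for r in panel],
            "raw": [r.raw for r in panel],
            "treated": [r.treated for r in panel],
            "unit": [r.unit for r in panel],
        }
    ).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, label: str = "") -> Spectrum:
    """Read a two-column ``wavenumber,absorbance`` spectrum."""
    df = _read_csv(path, ("wavenumber", "absorbance"))
    _numeric(df, ("wavenumber", "absorbance"), Path(path).name)
    if len(df) < 2:
        raise SchemaError(f"{Path(path).name}: need at least 2 points")
    return Spectrum(
        wavenumbers=df["wavenumber"].to_numpy(),
        absorbance=df["absorbance"].to_numpy(),
        label=label or Path(path).stem,
    )


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"wavenumber": s.wavenumbers, "absorbance": s.absorbance}
    ).to_csv(path, index=False)


def read_jcamp(path: str | Path, label: str = "") -> Spectrum:
    """Minimal JCAMP-DX reader: ##XYDATA=(X++(Y..Y)) and ##XYPOINTS=(XY..XY).

    Honors XFACTOR/YFACTOR scaling; ignores compression schemes beyond
    plain space/comma-separated AFFN numbers.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"input file not found: {path}")
    xfactor = yfactor = 1.0
    deltax: float | None = None
    title = ""
    mode = None  # "xydata" | "xypoints"
    xy_lines: list[list[float]] = []  # raw XYDATA lines: [x, y1, y2, ...]
    xs: list[float] = []
    ys: list[float] = []
    for line in path.read_text(encoding="utf-8", errors="replace").splitlines():
        line = line.split("$$", 1)[0].strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "TITLE":
                title = value
            elif key == "XFACTOR":
                xfactor = float(value)
            elif key == "YFACTOR":
                yfactor = float(value)
            elif key == "DELTAX":
                deltax = float(value)
            elif key == "XYDATA":
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                mode = None
            continue
        if mode is None:
            continue
        tokens = [t for t in line.replace(",", " ").replace(";", " ").split()]
        try:
            nums = [float(t) for t in tokens]
        except ValueError as exc:
            raise SchemaError(
                f"{path.name}: unparseable data line {line!r}"
            ) from exc
        if mode == "xydata":
            if len(nums) < 2:
                raise SchemaError(
                    f"{path.name}: XYDATA line with fewer than 2 numbers"
                )
            xy_lines.append(nums)
        else:  # xypoints
            if len(nums) % 2 != 0:
                raise SchemaError(
                    f"{path.name}: odd number of values in XYPOINTS line"
                )
            for x, y in zip(nums[::2], nums[1::2]):
                xs.append(x * xfactor)
                ys.append(y * yfactor)
    if xy_lines:
        # (X++(Y..Y)) form: the first number of each line anchors its Y run;
        # the abscissa step comes from DELTAX or from consecutive anchors.
        if deltax is None:  # DELTAX (actual units) inferred from anchors
            if len(xy_lines) >= 2:
                deltax = (
                    (xy_lines[1][0] - xy_lines[0][0]) * xfactor
                    / (len(xy_lines[0]) - 1)
                )
            else:
                raise SchemaError(
                    f"{path.name}: cannot infer DELTAX from a single "
                    "XYDATA line; add a ##DELTAX record"
                )
        for nums in xy_lines:
            x0 = nums[0] * xfactor
            for j, y in enumerate(nums[1:]):
                xs.append(x0 + j * deltax)
                ys.append(y * yfactor)
    if len(xs) < 2:
        raise SchemaError(f"{path.name}: fewer than 2 spectral points")
    order = np.argsort(xs)
    return Spectrum(
        wavenumbers=np.asarray(xs)[order],
        absorbance=np.asarray(ys)[order],
        label=label or title or path.stem,
    )


def read_spectrum(path: str | Path, label: str = "") -> Spectrum:
    """Dispatch on extension: ``.jdx``/``.dx`` -> JCAMP, else CSV."""
    if str(path).lower().endswith((".jdx", ".dx", ".jcamp")):
        return read_jcamp(path, label=label)
    return read_spectrum_csv(path, label=label)
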