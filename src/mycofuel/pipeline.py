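"""End-to-end report assembly: FAME -> fuel properties -> compliance,
FTIR -> second derivative -> PCA, kinetics -> yields, wastewater ->
removal efficiencies.

The bundle produced by :func:`run_full_analysis` is a plain nested dict of
JSON-serializable values with no timestamps, so the same config on the same
inputs yields byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .ftir import assign_bands, find_bands, pca_window, second_derivative
from .fuel import check_compliance, compute_report, load_standard_limits
from .kinetics import series_summary, treatment_report

logger = logging.getLogger("mycofuel")

__all__ = ["RunConfig", "run_full_analysis", "write_report"]

DEFAULT_WINDOWS = ((2800.0, 3050.0), (1350.0, 1500.0))


@dataclass
class RunConfig:
    """Inputs and toggles for one full analysis run."""

    fame_path: str | None = None
    kinetics_path: str | None = None
    wastewater_path: str | None = None
    spectra_paths: tuple[str, ...] = ()
    normalization_mode: str = "as_reported"
    standards: tuple[str, ...] = ("ASTM D6751", "EN 14214", "IS 15607")
    windows: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS
    d2_width: int = 25
    band_prominence: float = 5e-4
    initial_substrate: float | None = None

    def __post_init__(self) -> None:
        for lo, hi in self.windows:
            if not (400 <= lo < hi <= 4000):
                raise ValueError(
                    f"window [{lo}, {hi}] outside the 400-4000 cm^-1 range"
                )


def _fuel_section(cfg: RunConfig) -> dict:
    assert cfg.fame_path is not None
    limits = load_standard_limits()
    section: dict = {}
    # both normalization conventions side by side; the as_reported panel is
    # the one matching raw GC reports with open mass balance
    for mode in ("as_reported", "renormalized"):
        profile = mio.read_fame_csv(cfg.fame_path, mode=mode)
        logger.info(
            "fuel properties: profile %s, mode=%s, total=%.2f%%",
            profile.label, mode, profile.total_percent,
        )
        report = compute_report(profile)
        entry = {
            "properties": report.as_dict(),
            "rounded": report.rounded(2),
            "notes": report.notes,
            "flags": report.flags,
            "compliance": {},
        }
        for sid in cfg.standards:
            verdicts = check_compliance(report, limits[sid])
            entry["compliance"][sid] = verdicts.to_dict(orient="records")
        section[mode] = entry
    section["primary_mode"] = cfg.normalization_mode
    return section


def _kinetics_section(cfg: RunConfig) -> dict:
    assert cfg.kinetics_path is not None
    series = mio.read_kinetics_csv(
        cfg.kinetics_path, initial_substrate=cfg.initial_substrate
    )
    logger.info(
        "kinetics: %d records, initial substrate %.2f g/L",
        len(series.data), series.initial_substrate,
    )
    summary = series_summary(series)
    return {
        "initial_substrate": series.initial_substrate,
        "table": summary.table.to_dict(orient="records"),
        "peaks": summary.peaks,
    }


def _wastewater_section(cfg: RunConfig) -> dict:
    assert cfg.wastewater_path is not None
    panel = mio.read_wastewater_csv(cfg.wastewater_path)
    logger.info("wastewater: %d parameters", len(panel))
    report = treatment_report(panel)
    return {"table": report.to_dict(orient="records")}


def _ftir_section(cfg: RunConfig) -> dict:
    spectra = [mio.read_spectrum(p) for p in cfg.spectra_paths]
    logger.info(
        "ftir: %d spectra, d2 width %d, windows %s",
        len(spectra), cfg.d2_width, cfg.windows,
    )
    section: dict = {"spectra": [s.label for s in spectra], "bands": {},
                     "pca": {}}
    for s in spectra:
        d2 = second_derivative(s, width=cfg.d2_width)
        peaks = find_bands(d2, prominence=cfg.band_prominence)
        section["bands"][s.label] = [
            {
                "peak": a.peak,
                "mode": a.mode,
                "biomolecule": a.biomolecule,
                "matched": a.matched,
            }
            for a in assign_bands(peaks)
        ]
    if len(spectra) >= 3:
        for lo, hi in cfg.windows:
            res = pca_window(spectra, lo=lo, hi=hi)
            section["pca"][f"{lo:g}-{hi:g}"] = {
                "explained_variance_ratio":
                    [float(v) for v in res.explained_variance_ratio[:3]],
                "scores_pc1": {
                    lab: float(v)
                    for lab, v in zip(res.labels, res.scores[:, 0])
                },
            }
    return section


def run_full_analysis(cfg: RunConfig) -> dict:
    """Run every stage for which the config names inputs.

    Raises ``ValueError`` if no input class is configured; per-stage input
    problems surface as :class:`~mycofuel.io.SchemaError` naming the stage
    file.
    """
    if not (
        cfg.fame_path or cfg.kinetics_path or cfg.wastewater_path
        or cfg.spectra_paths
    ):
        raise ValueError(
            "no inputs configured: provide at least one of fame_path, "
            "kinetics_path, wastewater_path, spectra_paths"
        )
    bundle: dict = {"config": {
        "normalization_mode": cfg.normalization_mode,
        "standards": list(cfg.standards),
        "windows": [list(w) for w in cfg.windows],
        "d2_width": cfg.d2_width,
    }}
    if cfg.fame_path:
        bundle["fuel_properties"] = _fuel_section(cfg)
    if cfg.kinetics_path:
        bundle["kinetics"] = _kinetics_section(cfg)
    if cfg.wastewater_path:
        bundle["wastewater"] = _wastewater_section(cfg)
    if cfg.spectra_paths:
        bundle["ftir"] = _ftir_section(cfg)
    return bundle


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(bundle: dict, outdir: str | Path) -> list[Path]:
    """Write the bundle as report.json plus per-stage CSVs and a Markdown
    summary; returns the files written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    jpath = outdir / "report.json"
    jpath.write_text(
        json.dumps(_jsonable(bundle), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    written.append(jpath)

    if "fuel_properties" in bundle:
        rows = []
        for mode in ("as_reported", "renormalized"):
            entry = bundle["fuel_properties"][mode]
            for k, v in entry["properties"].items():
                if k == "label":
                    continue
                rows.append({"mode": mode, "property": k, "value": v})
        p = outdir / "fuel_properties.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
    if "kinetics" in bundle:
        p = outdir / "kinetics_summary.csv"
        pd.DataFrame(bundle["kinetics"]["table"]).to_csv(p, index=False)
        written.append(p)
    if "wastewater" in bundle:
        p = outdir / "wastewater_report.csv"
        pd.DataFrame(bundle["wastewater"]["table"]).to_csv(p, index=False)
        written.append(p)

    md = ["# mycofuel analysis report", ""]
    if "fuel_properties" in bundle:
        primary = bundle["fuel_properties"]["as_reported"]
        md.append("## Predicted fuel properties (as-reported wt%)")
        md.append("")
        md.append("| property | value |")
        md.append("|---|---|")
        for k, v in primary["rounded"].items():
            md.append(f"| {k} | {'' if v is None else v} |")
        md.append("")
    if "kinetics" in bundle:
        md.append("## Fermentation peaks")
        md.append("")
        for name, peak in bundle["kinetics"]["peaks"].items():
            md.append(f"- {name}: {peak['value']} on day {peak['day']}")
        md.append("")
    if "wastewater" in bundle:
        md.append("## Wastewater removal efficiencies")
        md.append("")
        for row in bundle["wastewater"]["table"]:
            md.append(f"- {row['parameter']}: {row['reduction_pct']}%")
        md.append("")
    mpath = outdir / "report.md"
    mpath.write_text("\n".join(md), encoding="utf-8")
    written.append(mpath)
    return written
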