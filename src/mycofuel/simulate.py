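"""Synthetic-data generators with known ground truth.

Every input class the analysis stages consume can be generated here with
its generating parameters recorded, so each pipeline stage is testable as a
recovery problem:

* FAME profiles — Dirichlet-distributed weight-percents over a configured
  species list, scaled to a target identified total;
* FTIR day series — sums of Gaussian bands at the canonical lipid band
  positions whose lipid-band amplitudes follow a latent lipid-accumulation
  trajectory, on a linear baseline with additive Gaussian noise;
* fermentation time courses — logistic biomass growth, substrate drawdown
  proportional to growth, lipid formation at a fixed true yield Y_L/C after
  an onset day;
* wastewater panels — treated = raw * (1 - removal fraction), so the
  removal-efficiency computation inverts the generator exactly.

All randomness flows from the ``seed`` in each config through a single
``numpy.random.default_rng`` stream per call; the same (config, seed) pair
always reproduces the same output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fame import FAMEProfile, build_profile
from .ftir import Spectrum
from .kinetics import FermentationSeries, WastewaterRecord

__all__ = [
    "FameProfileConfig",
    "FtirSeriesConfig",
    "KineticsConfig",
    "WastewaterConfig",
    "gen_fame_profile",
    "gen_ftir_series",
    "gen_kinetics",
    "gen_wastewater",
    "sm_day6_config",
    "sww_day6_config",
    "table_panel_config",
]


# ---------------------------------------------------------------------------
# FAME profiles


@dataclass(frozen=True)
class FameProfileConfig:
    """Dirichlet FAME-profile generator settings.

    ``alpha`` are per-species Dirichlet concentrations; the default is the
    day-6 sago-wastewater composition itself (stearate-dominant), so the
    generator's mean profile is that composition and its total Dirichlet
    concentration (~93) gives realistic between-replicate scatter.
    ``total_percent`` is the identified-FAME total the sample is scaled to
    (GC reports rarely close to 100 %).
    """

    seed: int = 0
    species: tuple[str, ...] = (
        "C16:0", "C16:1", "C18:0", "C18:1", "C18:2", "C20:0",
    )
    alpha: tuple[float, ...] = (0.95, 0.32, 64.77, 14.11, 12.81, 0.02)
    total_percent: float = 92.98
    label: str = "synthetic FAME profile"


def gen_fame_profile(
    cfg: FameProfileConfig,
) -> tuple[FAMEProfile, dict]:
    """Draw one FAME profile; returns (profile, ground-truth aggregates)."""
    if not cfg.species:
        raise ValueError("species list must not be empty")
    if len(cfg.alpha) != len(cfg.species):
        raise ValueError("alpha must have one entry per species")
    if not 0 < cfg.total_percent <= 100:
        raise ValueError("total_percent must be in (0, 100]")
    rng = np.random.default_rng(cfg.seed)
    w = rng.dirichlet(np.asarray(cfg.alpha, dtype=float))
    wt = w * cfg.total_percent
    profile = build_profile(
        list(zip(cfg.species, wt)), label=cfg.label, mode="as_reported"
    )
    truth = {
        "wt_percent": dict(zip(cfg.species, wt)),
        "sfa": profile.sfa,
        "mufa": profile.mufa,
        "pufa": profile.pufa,
        "du": profile.mufa + 2.0 * profile.pufa,
        "total_percent": cfg.total_percent,
    }
    return profile, truth


def sm_day6_config(seed: int = 0) -> FameProfileConfig:
    """Config whose mean is the day-6 synthetic-medium composition."""
    return FameProfileConfig(
        seed=seed,
        species=("C14:0", "C18:0", "C18:1", "C18:2", "C18:3"),
        alpha=(2.60, 32.22, 17.29, 19.12, 9.09),
        total_percent=80.32,
        label="synthetic SM-like profile",
    )


def sww_day6_config(seed: int = 0) -> FameProfileConfig:
    """Config whose mean is the day-6 sago-wastewater composition."""
    return FameProfileConfig(seed=seed, label="synthetic SWW-like profile")


# ---------------------------------------------------------------------------
# FTIR day series


@dataclass(frozen=True)
class FtirSeriesConfig:
    """Gaussian-band FTIR series generator settings.

    Band centres are the canonical microbial-lipid positions; bands marked
    ``lipid`` scale with the latent lipid trajectory, the 1415 cm^-1
    protein band stays constant.  The default latent trajectory is a
    logistic rise over the fermentation (growth phase days 1-3, lipid
    accumulation days 4-7, plateau thereafter).  Amplitudes are absorbance
    units; ``noise_sd`` is typical ATR-FTIR detector noise.
    """

    seed: int = 0
    days: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10)
    wn_start: float = 400.0
    wn_stop: float = 4000.0
    wn_step: float = 0.5  # typical FT-IR data spacing after zero-filling
    band_centers: tuple[float, ...] = (
        3008.0, 2953.0, 2924.0, 2853.0, 1745.0, 1465.0, 1415.0, 1377.0, 720.0,
    )
    band_widths: tuple[float, ...] = (
        8.0, 8.0, 9.0, 8.0, 10.0, 8.0, 8.0, 8.0, 9.0,
    )
    band_amplitudes: tuple[float, ...] = (
        0.05, 0.25, 0.45, 0.30, 0.55, 0.18, 0.08, 0.12, 0.10,
    )
    lipid_band: tuple[bool, ...] = (
        True, True, True, True, True, True, False, True, True,
    )
    latent: tuple[float, ...] | None = None  # default: logistic in day
    baseline_offset: float = 0.02
    baseline_slope: float = -2e-6
    noise_sd: float = 2e-4  # scan-averaged ATR detector noise, AU

    def latent_trajectory(self) -> np.ndarray:
        if self.latent is not None:
            if len(self.latent) != len(self.days):
                raise ValueError("latent must have one value per day")
            return np.asarray(self.latent, dtype=float)
        t = np.asarray(self.days, dtype=float)
        return 0.15 + 0.85 / (1.0 + np.exp(-(t - 4.0)))


def gen_ftir_series(
    cfg: FtirSeriesConfig,
) -> tuple[list[Spectrum], dict]:
    """Generate one spectrum per day; returns (spectra, ground truth)."""
    k = len(cfg.band_centers)
    if not (len(cfg.band_widths) == len(cfg.band_amplitudes)
            == len(cfg.lipid_band) == k):
        raise ValueError("band parameter tuples must have equal length")
    rng = np.random.default_rng(cfg.seed)
    wn = np.arange(cfg.wn_start, cfg.wn_stop + cfg.wn_step / 2, cfg.wn_step)
    latent = cfg.latent_trajectory()
    spectra = []
    for day, level in zip(cfg.days, latent):
        ab = cfg.baseline_offset + cfg.baseline_slope * wn
        for c, w, a, is_lipid in zip(
            cfg.band_centers, cfg.band_widths, cfg.band_amplitudes,
            cfg.lipid_band,
        ):
            amp = a * level if is_lipid else a
            ab = ab + amp * np.exp(-0.5 * ((wn - c) / w) ** 2)
        if cfg.noise_sd > 0:
            ab = ab + rng.normal(0.0, cfg.noise_sd, wn.size)
        spectra.append(
            Spectrum(wavenumbers=wn, absorbance=ab, label=f"day {day}")
        )
    truth = {
        "band_centers": np.asarray(cfg.band_centers),
        "lipid_band": np.asarray(cfg.lipid_band),
        "latent": latent,
        "days": np.asarray(cfg.days),
    }
    return spectra, truth


# ---------------------------------------------------------------------------
# Fermentation kinetics


@dataclass(frozen=True)
class KineticsConfig:
    """Logistic fermentation generator settings.

    Defaults emulate a 10-day starch fermentation of an oleaginous fungus
    in synthetic medium: 30 g/L initial starch, biomass plateauing at
    6.93 g/L, ~23 g/L starch consumed by day 10, lipid formed at a true
    yield of 0.22 g lipid per g starch consumed once growth is under way.
    """

    seed: int = 0
    days: int = 10
    x0: float = 0.15
    x_max: float = 6.93
    mu: float = 0.9
    initial_substrate: float = 30.0
    consumed_max: float = 23.07
    y_true: float = 0.22
    onset_day: int = 1
    amylase_max: float = 48.0
    noise_sd: float = 0.0


def gen_kinetics(
    cfg: KineticsConfig,
) -> tuple[FermentationSeries, dict]:
    """Generate a daily fermentation record; returns (series, truth).

    Biomass follows the logistic X(t) = Xmax / (1 + ((Xmax-X0)/X0) e^{-mu t});
    substrate consumption tracks biomass formation linearly up to
    ``consumed_max``; lipid = y_true * consumed from the onset day on, so
    with zero noise the per-day yield coefficient recovers ``y_true``
    exactly.  Gaussian noise of sd ``noise_sd`` (g/L) is added to biomass,
    lipid and residual substrate, clipped to the physical ranges.
    """
    if cfg.days < 2:
        raise ValueError("need at least 2 days")
    if not 0 < cfg.x0 < cfg.x_max:
        raise ValueError("require 0 < x0 < x_max")
    if cfg.consumed_max >= cfg.initial_substrate:
        raise ValueError("consumed_max must be below initial substrate")
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(1, cfg.days + 1, dtype=float)
    a = (cfg.x_max - cfg.x0) / cfg.x0
    x = cfg.x_max / (1.0 + a * np.exp(-cfg.mu * t))
    consumed = cfg.consumed_max * (x - cfg.x0) / (cfg.x_max - cfg.x0)
    consumed = np.clip(consumed, 0.0, cfg.consumed_max)
    lipid = np.where(t >= cfg.onset_day, cfg.y_true * consumed, 0.0)
    starch = cfg.initial_substrate - consumed
    amylase = cfg.amylase_max * (x - cfg.x0) / (cfg.x_max - cfg.x0)
    if cfg.noise_sd > 0:
        x = np.clip(x + rng.normal(0, cfg.noise_sd, t.size), 1e-6, None)
        lipid = np.clip(lipid + rng.normal(0, cfg.noise_sd, t.size), 0, None)
        starch = np.clip(
            starch + rng.normal(0, cfg.noise_sd, t.size),
            0.0, cfg.initial_substrate,
        )
    df = pd.DataFrame(
        {
            "day": t.astype(int),
            "biomass": x,
            "lipid": lipid,
            "starch": starch,
            "amylase": amylase,
        }
    )
    series = FermentationSeries(
        data=df, initial_substrate=cfg.initial_substrate
    )
    truth = {
        "y_true": cfg.y_true,
        "onset_day": cfg.onset_day,
        "x_max": cfg.x_max,
        "consumed_max": cfg.consumed_max,
    }
    return series, truth


# ---------------------------------------------------------------------------
# Wastewater panels


@dataclass(frozen=True)
class WastewaterConfig:
    """Wastewater-panel generator: raw levels and true removal fractions.

    Defaults are the raw sago-wastewater levels with the removal fractions
    achieved by the fungal treatment; ``rel_noise_sd`` (relative, applied
    to the treated values) is zero by default so that
    ``removal_efficiency`` inverts the generator exactly.
    """

    seed: int = 0
    parameters: tuple[tuple[str, float, float, str], ...] = (
        ("Total dissolved solids (TDS)", 4.07, 0.352, "g/L"),
        ("Total suspended solids (TSS)", 6.67, 0.530, "g/L"),
        ("Total solids (TS)", 6.90, 0.586, "g/L"),
        ("Total phosphate (TP)", 1.06, 0.945, "g/L"),
        ("Total nitrogen (TN)", 0.44, 0.893, "g/L"),
        ("Dissolved oxygen (DO)", 7.84, 0.913, "g/L"),
        ("Biochemical oxygen demand (BOD)", 2.56, 0.740, "g/L"),
        ("Chemical oxygen demand (COD)", 76.00, 0.470, "g/L"),
        ("Starch", 30.00, 0.629, "g/L"),
        ("Cyanide", 5.2, 0.538, "mg/L"),
    )
    rel_noise_sd: float = 0.0


def gen_wastewater(
    cfg: WastewaterConfig,
) -> tuple[list[WastewaterRecord], dict]:
    """Generate a raw/treated panel; returns (records, true fractions)."""
    rng = np.random.default_rng(cfg.seed)
    records, truth = [], {}
    for name, raw, frac, unit in cfg.parameters:
        if not 0 <= frac <= 1:
            raise ValueError(f"{name}: removal fraction must be in [0, 1]")
        treated = raw * (1.0 - frac)
        if cfg.rel_noise_sd > 0:
            treated = max(
                0.0, treated * (1.0 + rng.normal(0.0, cfg.rel_noise_sd))
            )
        records.append(WastewaterRecord(name, raw, treated, unit))
        truth[name] = frac
    return records, truth


def table_panel_config(seed: int = 0) -> WastewaterConfig:
    """The default sago-wastewater panel config (alias for readability)."""
    return WastewaterConfig(seed=seed)
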