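"""Published reference measurements for *Aspergillus caespitosus* ASEF14.

Desk-scale input data from the GC-FID, fermentation and wastewater
characterization of the sago-wastewater-grown oleaginous fungus
*A. caespitosus* ASEF14: day-6 FAME compositions in synthetic medium (SM)
and sago-processing wastewater (SWW), the isolate lipid screen, the
raw/treated effluent panel, and the reported fuel-property summary values
used for cross-checking the predictive correlations.

These are printed experimental values used as *inputs*; everything derived
from them in this package is recomputed.
"""

from __future__ import annotations

from .fame import FAMEProfile, build_profile
from .kinetics import WastewaterRecord

__all__ = [
    "sm_day6_profile",
    "sww_day6_profile",
    "sago_wastewater_panel",
    "isolate_lipid_screen",
    "reported_fuel_summary",
    "reported_kinetics",
]


def sm_day6_profile(mode: str = "as_reported") -> FAMEProfile:
    """Day-6 FAME profile of ASEF14 grown in synthetic medium (wt%)."""
    return build_profile(
        [
            ("C14:0", 2.60),
            ("C18:0", 32.22),
            ("C18:1", 17.29),
            ("C18:2", 19.12),
            ("C18:3", 9.09),
        ],
        label="SM day 6",
        mode=mode,
    )


def sww_day6_profile(mode: str = "as_reported") -> FAMEProfile:
    """Day-6 FAME profile of ASEF14 grown in sago wastewater (wt%)."""
    return build_profile(
        [
            ("C16:0", 0.95),
            ("C16:1", 0.32),
            ("C18:0", 64.77),
            ("C18:1", 14.11),
            ("C18:2", 12.81),
            ("C20:0", 0.02),
        ],
        label="SWW day 6",
        mode=mode,
    )


def sago_wastewater_panel() -> list[WastewaterRecord]:
    """Raw vs. fungus-treated sago wastewater physicochemical panel.

    Starch appears at its adjusted initial level (30 g/L, matched to the
    synthetic medium) with the end-of-fermentation residual as treated
    value.  pH is excluded: a percentage reduction is meaningless for it.
    """
    return [
        WastewaterRecord("Electrical conductivity", 6.21, 4.11, "dS/m"),
        WastewaterRecord("Salinity", 4.53, 3.15, "ppt"),
        WastewaterRecord("Total dissolved solids (TDS)", 4.07, 2.64),
        WastewaterRecord("Total suspended solids (TSS)", 6.67, 3.14),
        WastewaterRecord("Total solids (TS)", 6.90, 2.86),
        WastewaterRecord("Total phosphate (TP)", 1.06, 0.06),
        WastewaterRecord("Total nitrogen (TN)", 0.44, 0.05),
        WastewaterRecord("Dissolved oxygen (DO)", 7.84, 0.68),
        WastewaterRecord("Biochemical oxygen demand (BOD)", 2.56, 0.67),
        WastewaterRecord("Chemical oxygen demand (COD)", 76.00, 40.27),
        WastewaterRecord("Starch", 30.00, 11.12),
        WastewaterRecord("Cyanide", 5.2, 2.4, "mg/L"),
    ]


def isolate_lipid_screen() -> dict[str, dict[str, float]]:
    """Biomass / lipid yield (g/L) of the screened fungal isolates."""
    return {
        "ASEF1": {"biomass": 6.66, "lipid": 1.04},
        "ASEF14": {"biomass": 6.06, "lipid": 3.31},
        "ASEF18": {"biomass": 9.01, "lipid": 1.60},
        "ASEF17": {"biomass": 4.10, "lipid": 0.95},
        "ASEF24": {"biomass": 4.73, "lipid": 0.67},
        "ASEF25": {"biomass": 5.33, "lipid": 1.52},
    }


def reported_fuel_summary() -> dict[str, dict[str, float]]:
    """Reported day-6 fuel-property summary for SM- and SWW-grown oil.

    SV (mg/g), IV (g I2/100 g), MUFA/PUFA (wt%) are the published inputs
    used to cross-check the cetane-number and degree-of-unsaturation
    correlations.
    """
    return {
        "SM": {"sv": 142.10, "iv": 27.85, "mufa": 16.23, "pufa": 4.82},
        "SWW": {"sv": 127.25, "iv": 30.52, "mufa": 9.62, "pufa": 10.87},
    }


def reported_kinetics() -> dict[str, dict[str, float]]:
    """Peak fermentation observations for the yield bookkeeping.

    In SM the lipid peak (3.50 g/L) coincided with 16.01 g/L starch
    consumed on day 6; the ASEF14 screen flask reached 3.31 g/L lipid at
    6.06 g/L dry biomass.
    """
    return {
        "SM": {
            "max_lipid": 3.50,
            "starch_consumed_at_max": 16.01,
            "max_biomass": 6.93,
            "initial_starch": 30.0,
        },
        "SWW": {
            "max_lipid": 1.39,
            "max_biomass": 4.73,
            "initial_starch": 30.0,
            "residual_starch_final": 11.12,
        },
    }
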