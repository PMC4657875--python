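"""Conversion of raw plate-reader signals into normalized enzyme activities.

The colorimetric lipase/phospholipase C assays (NPB, NPP, NPPC substrates)
release nitrophenol, read as absorbance at 410 nm; Beer–Lambert with the
nitrophenol extinction coefficient (17,700 per M per cm) converts the
blank-corrected absorbance delta into product concentration. Protease
activity uses FITC-casein fluorescence with per-sample t=0 autofluorescence
as the baseline. Liposome lysis is normalized between a heat-denatured
supernatant negative control (0%) and a Triton X-100 positive control
(100%).

The canonical internal activity unit is nmol product/ml/min/OD600; the
mass-based views (ng, ug per ml/min/OD600) are derived by multiplying with
the nitrophenol molecular weight. The optical pathlength of the reading is
not part of the assay chemistry and defaults to 1.0 cm; it is the dominant
systematic unknown when comparing absolute activity scales between
instruments, so it is an explicit constant rather than a buried factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AssayConstants",
    "LysisResult",
    "absorbance_to_activity",
    "protease_activity",
    "percent_lysis",
    "nmol_to_ng",
    "nmol_to_ug",
    "convert_signal_table",
]

#: Enzyme classes read out as A410 nitrophenol release.
COLORIMETRIC_CLASSES = ("NPB", "NPP", "NPPC")
#: Enzyme class read out as FITC-casein fluorescence.
FLUOROMETRIC_CLASS = "protease"


@dataclass(frozen=True)
class AssayConstants:
    """Physical constants of the colorimetric readout."""

    epsilon_nitrophenol: float = 17700.0  # per M per cm
    pathlength_cm: float = 1.0
    nitrophenol_mw: float = 139.11  # g/mol, for mass-unit reporting only

    def __post_init__(self) -> None:
        if self.epsilon_nitrophenol <= 0 or self.pathlength_cm <= 0:
            raise ValueError("extinction coefficient and pathlength must be positive")


def _clip_negative(value: float, what: str) -> float:
    if value < 0:
        warnings.warn(
            f"negative blank-corrected {what} ({value:.4g}) clipped to 0",
            stacklevel=3,
        )
        return 0.0
    return value


def absorbance_to_activity(
    delta_a410: float,
    minutes: float,
    od600: float,
    constants: AssayConstants = AssayConstants(),
) -> float:
    """Convert a blank-corrected A410 delta into nmol/ml/min/OD600.

    Beer–Lambert: concentration [M] = dA / (epsilon * pathlength); 1 M is
    1e6 nmol/ml, then normalized by elapsed minutes and culture OD600.
    Small negative deltas (blank noise) clip to zero with a warning.
    """
    if minutes <= 0:
        raise ValueError("elapsed minutes must be positive")
    if od600 <= 0:
        raise ValueError("od600 must be positive")
    delta_a410 = _clip_negative(float(delta_a410), "A410 delta")
    molar = delta_a410 / (constants.epsilon_nitrophenol * constants.pathlength_cm)
    nmol_per_ml = molar * 1e6
    return nmol_per_ml / minutes / od600


def protease_activity(
    f_end: float, f_baseline: float, hours: float, od600: float
) -> float:
    """FITC-casein protease activity in RFU/h/OD600.

    ``f_baseline`` is the same sample's autofluorescence immediately after
    assay start; negative differences clip to zero with a warning.
    """
    if hours <= 0:
        raise ValueError("elapsed hours must be positive")
    if od600 <= 0:
        raise ValueError("od600 must be positive")
    delta = _clip_negative(float(f_end) - float(f_baseline), "fluorescence delta")
    return delta / hours / od600


@dataclass(frozen=True)
class LysisResult:
    """Percent liposome lysis, unclipped, with an out-of-range flag."""

    percent: float
    out_of_range: bool


def percent_lysis(f_sample: float, f_negative: float, f_triton: float) -> LysisResult:
    """Liposome lysis as percent of the Triton X-100 full-lysis control.

    0% is the heat-denatured-supernatant negative control. Values outside
    [0, 100] are reported unclipped and flagged, not an error — supernatant
    components can destabilize liposomes beyond either control.
    """
    span = float(f_triton) - float(f_negative)
    if span == 0:
        raise ValueError("positive and negative controls are identical: uninformative")
    pct = 100.0 * (float(f_sample) - float(f_negative)) / span
    return LysisResult(percent=pct, out_of_range=not (0.0 <= pct <= 100.0))


def nmol_to_ng(activity_nmol: float, constants: AssayConstants = AssayConstants()) -> float:
    """nmol/ml/min/OD -> ng/ml/min/OD as nitrophenol mass equivalents."""
    return activity_nmol * constants.nitrophenol_mw


def nmol_to_ug(activity_nmol: float, constants: AssayConstants = AssayConstants()) -> float:
    """nmol/ml/min/OD -> ug/ml/min/OD as nitrophenol mass equivalents."""
    return nmol_to_ng(activity_nmol, constants) / 1000.0


def convert_signal_table(
    signals: pd.DataFrame, constants: AssayConstants = AssayConstants()
) -> pd.DataFrame:
    """Convert a raw signal table into canonical activity records.

    Expects columns design_id, enzyme, replicate, signal_start, signal_end,
    minutes, od600. Colorimetric rows (NPB/NPP/NPPC) are treated as
    blank-corrected A410 deltas (signal_end - signal_start); protease rows
    as fluorescence with signal_start the t=0 autofluorescence and minutes
    converted to hours. Returns design_id, enzyme, replicate, value, units.
    """
    required = {"design_id", "enzyme", "replicate", "signal_start", "signal_end", "minutes", "od600"}
    missing = required - set(signals.columns)
    if missing:
        raise ValueError(f"signal table missing columns: {sorted(missing)}")

    records = []
    for row in signals.itertuples(index=False):
        if row.enzyme in COLORIMETRIC_CLASSES:
            value = absorbance_to_activity(
                row.signal_end - row.signal_start, row.minutes, row.od600, constants
            )
            units = "nmol/ml/min/OD600"
        elif row.enzyme == FLUOROMETRIC_CLASS:
            value = protease_activity(
                row.signal_end, row.signal_start, row.minutes / 60.0, row.od600
            )
            units = "RFU/h/OD600"
        else:
            raise ValueError(f"unknown enzyme class {row.enzyme!r}")
        records.append(
            (row.design_id, row.enzyme, row.replicate, value, units, row.od600)
        )
    return pd.DataFrame(
        records,
        columns=["design_id", "enzyme", "replicate", "value", "units", "od600"],
    )
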