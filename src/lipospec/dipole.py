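"""Membrane dipole potential from di-8-ANEPPS excitation ratiometry.

The voltage-sensitive styryl dye di-8-ANEPPS reports the membrane dipole
potential psi_d through a spectral shift of its excitation band.  The
standard readout is the blank-corrected excitation intensity ratio

    R_ex = I(420 nm) / I(520 nm)        (emission at 635 nm)

which maps linearly onto psi_d.  Two calibrations are carried here:

* absolute:   psi_d [mV] = (R_ex + b) / m      with b = 0.3 +/- 0.4 and
              m = 4.3e-3 +/- 1.2e-3 per mV (dual-wavelength ratiometric
              calibration on PC vesicles);
* differential (rescaled slope):  delta_psi_d [mV] = k * delta_R_ex with
              k = 365 +/- 102 mV per ratio unit, appropriate for the
              420/520-excitation, 635-emission configuration.

Uncertainties on shifts combine the replicate scatter of the two R_ex
means with the slope uncertainty in independent quadrature:

    sd(delta_psi) = sqrt( (k * sigma_dR)^2 + (k_sd * delta_R)^2 ),
    sigma_dR = sqrt(sd_sample^2 + sd_control^2).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import (
    Compound,
    LipidSystem,
    Spectrum,
    RATIO_DEN_NM,
    RATIO_NUM_NM,
)

__all__ = [
    "RexResult",
    "CalibrationLinear",
    "RescaledSlope",
    "DipoleShift",
    "compute_rex",
    "aggregate_rex",
    "psi_from_rex",
    "rescale_slope",
    "delta_psi",
    "dipole_table",
]

logger = logging.getLogger(__name__)

BLANK_FRACTION_LIMIT = 0.007  # blank must stay below 0.7% of labelled peak


@dataclass(frozen=True)
class RexResult:
    """Replicate-aggregated 420/520 excitation ratio for one condition."""

    mean_rex: float
    sd_rex: float
    n: int
    condition: tuple[LipidSystem, Compound]

    def __post_init__(self):
        if self.mean_rex <= 0:
            raise ValueError(f"mean_rex must be positive, got {self.mean_rex}")
        if self.sd_rex < 0:
            raise ValueError("sd_rex must be non-negative")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.n == 1 and self.sd_rex != 0:
            raise ValueError("sd_rex must be 0 when n = 1")


@dataclass(frozen=True)
class CalibrationLinear:
    """Linear R_ex -> psi_d calibration: psi_d = (R_ex + b) / m."""

    intercept_b: float = 0.3
    intercept_sd: float = 0.4
    slope_m_per_mV: float = 4.3e-3
    slope_sd: float = 1.2e-3

    def __post_init__(self):
        if self.slope_m_per_mV <= 0:
            raise ValueError("slope_m_per_mV must be positive")


@dataclass(frozen=True)
class RescaledSlope:
    """Proportionality constant k in delta_psi_d = k * delta_R_ex [mV/ratio]."""

    k_mV_per_ratio: float = 365.0
    k_sd: float = 102.0
    provenance: str = "fixed constant"

    def __post_init__(self):
        if self.k_mV_per_ratio <= 0:
            raise ValueError("k_mV_per_ratio must be positive")
        if self.k_sd < 0:
            raise ValueError("k_sd must be non-negative")


@dataclass(frozen=True)
class DipoleShift:
    """Calibrated dipole-potential change for one compound/system cell."""

    delta_psi_mV: float
    sd_mV: float
    delta_rex: float
    condition: tuple[LipidSystem, Compound]

    def __post_init__(self):
        if self.sd_mV < 0:
            raise ValueError("sd_mV must be non-negative")


def compute_rex(
    labelled: Spectrum,
    blank: Spectrum | None,
    num_nm: float = RATIO_NUM_NM,
    den_nm: float = RATIO_DEN_NM,
) -> float:
    """Blank-corrected excitation intensity ratio I(num_nm)/I(den_nm).

    Intensities are read by linear interpolation on each spectrum's own
    grid; the blank (unlabelled vesicle) trace is subtracted pointwise at
    the two wavelengths.  A blank exceeding 0.7% of the labelled peak is
    logged as a warning (the acquisition contract keeps it below that).
    """
    for s, role in ((labelled, "labelled"), (blank, "blank")):
        if s is None:
            continue
        if not (s.wavelength_nm[0] <= num_nm and s.wavelength_nm[-1] >= den_nm):
            raise ValueError(
                f"{role} spectrum range does not cover ratio wavelengths "
                f"[{num_nm:g}, {den_nm:g}] nm"
            )
    if blank is not None:
        frac = float(blank.intensity.max() / max(labelled.intensity.max(), 1e-300))
        logger.info("blank/labelled peak fraction: %.4f%%", 100 * frac)
        if frac > BLANK_FRACTION_LIMIT:
            logger.warning(
                "blank peak is %.2f%% of labelled peak (limit %.1f%%)",
                100 * frac,
                100 * BLANK_FRACTION_LIMIT,
            )
    num = labelled.intensity_at(num_nm)
    den = labelled.intensity_at(den_nm)
    if blank is not None:
        num -= blank.intensity_at(num_nm)
        den -= blank.intensity_at(den_nm)
    if den <= 0:
        raise ValueError(
            "non-positive reference intensity after blank correction "
            f"(I({den_nm:g} nm) = {den:g})"
        )
    return num / den


def aggregate_rex(
    values: Sequence[float],
    condition: tuple[LipidSystem, Compound],
) -> RexResult:
    """Mean +/- sample SD (n-1 denominator) of replicate R_ex values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("no replicate ratios supplied")
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("replicate ratios must be finite and positive")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return RexResult(mean_rex=mean, sd_rex=sd, n=int(arr.size), condition=condition)


def psi_from_rex(rex: float, cal: CalibrationLinear | None = None) -> float:
    """Absolute dipole potential in mV from one R_ex value."""
    cal = cal or CalibrationLinear()
    return (rex + cal.intercept_b) / cal.slope_m_per_mV


def rescale_slope(
    anchors: Sequence[tuple[float, float]] | None = None,
    default: RescaledSlope | None = None,
) -> RescaledSlope:
    """Proportionality constant k, either the default or fitted from anchors.

    Anchors are (measured R_ex, reference psi_d in mV) pairs from systems
    with literature dipole potentials; k is the ordinary least-squares
    slope of psi against R_ex.  With exactly two anchors this is the
    two-point slope; a regression SE is attached only for >= 3 anchors.
    With no anchors the default constant (365 +/- 102) is returned.
    """
    if anchors is None or len(anchors) == 0:
        return default or RescaledSlope()
    if len(anchors) < 2:
        raise ValueError("need >= 2 anchors to fit a slope")
    rex = np.asarray([a[0] for a in anchors], dtype=float)
    psi = np.asarray([a[1] for a in anchors], dtype=float)
    if np.ptp(rex) == 0:
        raise ValueError("anchor R_ex values are all identical")
    # OLS slope with intercept; the intercept is a nuisance here
    X = np.column_stack([np.ones_like(rex), rex])
    coef, res, _, _ = np.linalg.lstsq(X, psi, rcond=None)
    k = float(coef[1])
    if k <= 0:
        raise ValueError(f"fitted slope is non-positive ({k:g})")
    k_sd = 0.0
    if len(anchors) >= 3:
        resid = psi - X @ coef
        dof = len(anchors) - 2
        s2 = float(resid @ resid) / dof if dof > 0 else 0.0
        sxx = float(((rex - rex.mean()) ** 2).sum())
        k_sd = math.sqrt(s2 / sxx) if sxx > 0 else 0.0
    return RescaledSlope(k_mV_per_ratio=k, k_sd=k_sd, provenance="fitted from anchors")


def delta_psi(
    sample: RexResult,
    control: RexResult,
    slope: RescaledSlope | None = None,
) -> DipoleShift:
    """Dipole-potential change of a compound condition vs. its control.

    delta_R_ex = mean(sample) - mean(control); delta_psi = k * delta_R_ex.
    The uncertainty adds the replicate term and the slope term in
    quadrature, so the slope term k_sd*|delta_R| is a floor on sd_mV.
    """
    slope = slope or RescaledSlope()
    if sample.condition[0] is not control.condition[0]:
        raise ValueError(
            "sample and control come from different lipid systems: "
            f"{sample.condition[0].name} vs {control.condition[0].name}"
        )
    if control.condition[1] is not Compound.CONTROL:
        raise ValueError("control RexResult must have compound = CONTROL")
    d_rex = sample.mean_rex - control.mean_rex
    sigma_dr = math.hypot(sample.sd_rex, control.sd_rex)
    k, k_sd = slope.k_mV_per_ratio, slope.k_sd
    sd = math.hypot(k * sigma_dr, k_sd * d_rex)
    return DipoleShift(
        delta_psi_mV=k * d_rex,
        sd_mV=sd,
        delta_rex=d_rex,
        condition=sample.condition,
    )


def dipole_table(
    results: Iterable[RexResult],
    slope: RescaledSlope | None = None,
    round_mV: bool = True,
):
    """Compound x lipid-system table of delta_psi_d +/- sd in mV.

    One control and at least one compound result per lipid system are
    required; output rows follow the canonical compound order and columns
    the canonical lipid-system order, entries rounded to integer mV.
    """
    import pandas as pd

    slope = slope or RescaledSlope()
    results = list(results)
    by_system: dict[LipidSystem, dict[Compound, RexResult]] = {}
    for r in results:
        by_system.setdefault(r.condition[0], {})[r.condition[1]] = r
    shifts: dict[tuple[str, str], DipoleShift] = {}
    compounds_seen: list[Compound] = []
    for system, per_compound in by_system.items():
        if Compound.CONTROL not in per_compound:
            raise ValueError(f"missing control for lipid system {system.name}")
        control = per_compound[Compound.CONTROL]
        for compound, res in per_compound.items():
            if compound is Compound.CONTROL:
                continue
            shifts[(system.name, compound.name)] = delta_psi(res, control, slope)
            if compound not in compounds_seen:
                compounds_seen.append(compound)
    compounds = [c for c in Compound if c in compounds_seen]
    systems = [s for s in LipidSystem if s in by_system]
    rows = {}
    for c in compounds:
        row = {}
        for s in systems:
            shift = shifts.get((s.name, c.name))
            if shift is None:
                row[s.name] = ""
                continue
            if round_mV:
                row[s.name] = f"{shift.delta_psi_mV:.0f} ± {shift.sd_mV:.0f}"
            else:
                row[s.name] = f"{shift.delta_psi_mV:g} ± {shift.sd_mV:g}"
        rows[c.name] = row
    table = pd.DataFrame.from_dict(rows, orient="index", columns=[s.name for s in systems])
    table.index.name = "compound"
    return table
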