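"""Steady-state fluorescence anisotropy of DPH-PC (membrane order readout).

The anisotropy of the membrane-embedded diphenylhexatriene chromophore
reports acyl-chain orientational order.  With a vertically polarized
excitation beam and emission analyzed parallel/perpendicular,

    <r> = (I_VV - G I_VH) / (I_VV + 2 G I_VH),   G = I_HV / I_HH,

where G corrects for the polarization bias of the detection channel.
Aggregation follows the acquisition design: each sample is read seven
times (four-component quadruple per repeat, blank-subtracted, G estimated
per repeat), repeats are averaged into a sample-level <r>, and independent
samples (triplicates) give the condition mean +/- SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import Compound, LipidSystem, PolarizedReadingSet

__all__ = [
    "AnisotropyResult",
    "g_factor",
    "steady_state_anisotropy",
    "sample_anisotropy",
    "aggregate_anisotropy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnisotropyResult:
    """Condition-level steady-state anisotropy (mean over triplicates)."""

    mean_r: float
    sd_r: float
    G_mean: float
    n_samples: int
    condition: tuple[LipidSystem, Compound]

    def __post_init__(self):
        if not (-0.5 <= self.mean_r <= 1.0):
            raise ValueError(f"mean_r outside formula range [-0.5, 1]: {self.mean_r}")
        if self.sd_r < 0:
            raise ValueError("sd_r must be non-negative")
        if self.G_mean <= 0:
            raise ValueError("G_mean must be positive")


def g_factor(I_HV: float, I_HH: float) -> float:
    """Detector polarization-sensitivity correction G = I_HV / I_HH."""
    if I_HH <= 0:
        raise ValueError(f"I_HH must be positive, got {I_HH}")
    g = I_HV / I_HH
    if g <= 0:
        raise ValueError(f"G factor must be positive, got {g}")
    return g


def steady_state_anisotropy(I_VV: float, I_VH: float, G: float) -> float:
    """<r> = (I_VV - G I_VH) / (I_VV + 2 G I_VH)."""
    if G <= 0:
        raise ValueError("G must be positive")
    den = I_VV + 2.0 * G * I_VH
    if den == 0:
        raise ValueError("zero denominator in anisotropy formula")
    return (I_VV - G * I_VH) / den


def sample_anisotropy(
    pset: PolarizedReadingSet,
    blank: PolarizedReadingSet | None = None,
) -> tuple[float, float]:
    """Sample-level (<r>, <G>) averaged over the repeated readings.

    Each repeat is blank-subtracted component-wise, gets its own G from
    its HV/HH pair, and yields one anisotropy; repeats with any corrected
    intensity <= 0 are excluded (clipping would bias r upward).
    """
    blank = blank if blank is not None else pset.blank
    if blank is not None and blank.n_repeats != pset.n_repeats:
        raise ValueError(
            "blank repeat count differs from sample "
            f"({blank.n_repeats} vs {pset.n_repeats})"
        )
    rs, gs = [], []
    for k in range(pset.n_repeats):
        comp = {
            n: float(getattr(pset, n)[k]) - (float(getattr(blank, n)[k]) if blank is not None else 0.0)
            for n in ("I_VV", "I_VH", "I_HV", "I_HH")
        }
        if any(v <= 0 for v in comp.values()):
            logger.warning(
                "sample %s repeat %d: non-positive corrected intensity, excluded",
                pset.meta.sample_id,
                k + 1,
            )
            continue
        G = g_factor(comp["I_HV"], comp["I_HH"])
        rs.append(steady_state_anisotropy(comp["I_VV"], comp["I_VH"], G))
        gs.append(G)
    if not rs:
        raise ValueError(
            f"sample {pset.meta.sample_id}: all repeats excluded "
            "(non-positive corrected intensities)"
        )
    return float(np.mean(rs)), float(np.mean(gs))


def aggregate_anisotropy(
    sets: Sequence[PolarizedReadingSet] | PolarizedReadingSet,
    blanks: Sequence[PolarizedReadingSet | None] | PolarizedReadingSet | None = None,
) -> AnisotropyResult:
    """Condition-level mean +/- SD of <r> over independent samples.

    Accepts a single reading set (n_samples = 1, SD 0) or the triplicate
    list; per-sample blanks may ride on the sets themselves or be passed
    alongside.
    """
    if isinstance(sets, PolarizedReadingSet):
        sets = [sets]
        if isinstance(blanks, PolarizedReadingSet) or blanks is None:
            blanks = [blanks]
    if blanks is None:
        blanks = [None] * len(sets)
    if len(blanks) != len(sets):
        raise ValueError("blanks list length must match sets")
    if not sets:
        raise ValueError("no reading sets supplied")
    condition = sets[0].meta.condition
    for s in sets:
        if s.meta.condition != condition:
            raise ValueError("all reading sets must share one condition")
    r_vals, g_vals = [], []
    for s, b in zip(sets, blanks):
        r, g = sample_anisotropy(s, b)
        r_vals.append(r)
        g_vals.append(g)
    arr = np.asarray(r_vals)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return AnisotropyResult(
        mean_r=float(arr.mean()),
        sd_r=sd,
        G_mean=float(np.mean(g_vals)),
        n_samples=int(arr.size),
        condition=condition,
    )
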