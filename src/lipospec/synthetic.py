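"""Forward simulation of the three-arm liposome spectroscopy study.

Emulates the acquisition design with known ground truth so every analysis
stage can be verified by parameter recovery:

* di-8-ANEPPS excitation spectra (400-625 nm, 1-nm grid) built from two
  Gaussian bands whose blank-subtracted 420/520 intensity ratio equals the
  requested R_ex exactly before noise; multiplicative log-normal noise;
  blank traces capped at 0.7% of the labelled peak;
* DPH-PC polarized intensity quadruples (7 repeats) consistent with a
  requested anisotropy and G factor, log-normal reading noise;
* TCSPC decay histograms: multi-exponential law convolved with a Gaussian
  IRF (default FWHM 0.05 ns), channel width 0.055517 ns, expected peak in
  the 10,000-20,000 count band, channel-wise Poisson statistics.

``generate_study`` lays a complete triplicate study on disk (spectra +
blanks, polarized sets + blanks, decays, manifest) with a ground-truth
table keyed by sample_id.  All randomness flows from the single seed
passed in; identical (design, seed) pairs give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_formats import (
    Compound,
    DecayHistogram,
    LipidSystem,
    Manifest,
    ManifestEntry,
    PolarizedReadingSet,
    Probe,
    RecordKind,
    SampleMeta,
    Spectrum,
    write_decay,
    write_manifest,
    write_polarized,
    write_spectrum,
)

__all__ = [
    "SynthTruth",
    "SpectrumShapeConfig",
    "StudyDesign",
    "generate_excitation_pair",
    "generate_polarized_set",
    "generate_decay",
    "generate_study",
    "noise_cv_for_condition_sd",
    "DEFAULT_CONTROL_REX",
    "DEFAULT_DELTA_PSI_MV",
    "DEFAULT_ANISOTROPY",
    "DEFAULT_DELTA_R",
]

BLANK_FRACTION_MAX = 0.007

GRID_START_NM = 400.0
GRID_STOP_NM = 625.0
GRID_STEP_NM = 1.0

DEFAULT_CHANNEL_WIDTH_NS = 0.055517
DEFAULT_IRF_FWHM_NS = 0.05
PEAK_BAND = (10_000, 20_000)


@dataclass(frozen=True)
class SynthTruth:
    """Ground-truth parameters attached to a generated dataset."""

    seed: int
    truth_rex: float | None = None
    truth_delta_psi_mV: float | None = None
    truth_r: float | None = None
    truth_G: float | None = None
    truth_alphas: tuple[float, ...] | None = None
    truth_taus_ns: tuple[float, ...] | None = None
    noise_model: str = "none"

    def __post_init__(self):
        fields = (
            self.truth_rex,
            self.truth_delta_psi_mV,
            self.truth_r,
            self.truth_G,
            self.truth_alphas,
            self.truth_taus_ns,
        )
        if all(f is None for f in fields):
            raise ValueError("SynthTruth needs at least one truth field")
        if self.truth_alphas is not None:
            if abs(sum(self.truth_alphas) - 1.0) > 1e-9:
                raise ValueError("truth_alphas must sum to 1")
        if self.truth_taus_ns is not None:
            t = self.truth_taus_ns
            if any(x <= 0 for x in t) or any(
                t[i + 1] <= t[i] for i in range(len(t) - 1)
            ):
                raise ValueError("truth_taus_ns must be positive and increasing")


@dataclass(frozen=True)
class SpectrumShapeConfig:
    """Nuisance shape of the synthetic two-band excitation spectrum.

    The band model (two Gaussians in wavelength over a flat baseline) is a
    generator convenience: only the 420/520 intensity ratio is physically
    constrained, and it is guaranteed by construction.
    """

    band_centers_nm: tuple[float, float] = (420.0, 520.0)
    band_widths_nm: tuple[float, float] = (35.0, 40.0)
    baseline_frac: float = 0.02
    noise_cv: float = 0.007
    blank_frac: float = 0.005

    def __post_init__(self):
        if any(w <= 0 for w in self.band_widths_nm):
            raise ValueError("band widths must be positive")
        if self.baseline_frac < 0 or self.noise_cv < 0:
            raise ValueError("baseline_frac and noise_cv must be non-negative")
        if not 0 <= self.blank_frac <= BLANK_FRACTION_MAX:
            raise ValueError(
                f"blank_frac must lie in [0, {BLANK_FRACTION_MAX}] "
                f"(blank below 0.7% of labelled signal), got {self.blank_frac}"
            )


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean multiplicative noise factors with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


_DUMMY_META = SampleMeta(
    sample_id="synthetic",
    lipid_system=LipidSystem.POPC,
    compound=Compound.CONTROL,
    replicate=1,
    probe=Probe.DI8ANEPPS,
    compound_conc_uM=0.0,
)


# ---------------------------------------------------------------------------
# excitation spectra

def generate_excitation_pair(
    truth_rex: float,
    shape: SpectrumShapeConfig | None = None,
    meta: SampleMeta | None = None,
    seed: int = 0,
) -> tuple[Spectrum, Spectrum, SynthTruth]:
    """Labelled + blank excitation spectrum pair with exact pre-noise ratio.

    The two Gaussian band amplitudes are solved so the blank-subtracted
    intensity obeys I(420)/I(520) = truth_rex exactly; pointwise log-normal
    noise (CV = shape.noise_cv) is then applied to both traces.
    """
    if truth_rex <= 0:
        raise ValueError(f"truth_rex must be positive, got {truth_rex}")
    shape = shape or SpectrumShapeConfig()
    meta = meta or _DUMMY_META
    rng = np.random.default_rng(seed)

    wl = np.arange(GRID_START_NM, GRID_STOP_NM + GRID_STEP_NM / 2, GRID_STEP_NM)
    c1, c2 = shape.band_centers_nm
    w1, w2 = shape.band_widths_nm
    g1 = np.exp(-0.5 * ((wl - c1) / w1) ** 2)
    g2 = np.exp(-0.5 * ((wl - c2) / w2) ** 2)

    def at(arr: np.ndarray, nm: float) -> float:
        return float(np.interp(nm, wl, arr))

    s0 = 1.0e5  # arbitrary-unit scale of the reference (520 nm) intensity
    base = shape.baseline_frac * s0
    # solve amplitudes: base + A1 g1(420) + A2 g2(420) = R*s0
    #                   base + A1 g1(520) + A2 g2(520) = s0
    M = np.array(
        [
            [at(g1, 420.0), at(g2, 420.0)],
            [at(g1, 520.0), at(g2, 520.0)],
        ]
    )
    rhs = np.array([truth_rex * s0 - base, s0 - base])
    A1, A2 = np.linalg.solve(M, rhs)
    if A1 < 0 or A2 < 0:
        raise ValueError(
            f"band shape cannot realise R_ex={truth_rex} with non-negative "
            "amplitudes; widen the bands or move the ratio"
        )
    signal = base + A1 * g1 + A2 * g2

    blank_shape = np.exp(-0.5 * ((wl - 470.0) / 90.0) ** 2)
    blank_clean = shape.blank_frac * signal.max() * blank_shape / blank_shape.max()
    labelled_clean = signal + blank_clean

    labelled = labelled_clean * _lognormal_factors(rng, shape.noise_cv, wl.shape)
    blank = blank_clean * _lognormal_factors(rng, shape.noise_cv, wl.shape)

    blank_id = meta.blank_id or f"blank-{meta.sample_id}"
    blank_meta = SampleMeta(
        sample_id=blank_id,
        lipid_system=meta.lipid_system,
        compound=Compound.CONTROL,
        replicate=meta.replicate,
        probe=meta.probe,
        compound_conc_uM=0.0,
    )
    truth = SynthTruth(
        seed=seed,
        truth_rex=truth_rex,
        noise_model=f"lognormal(cv={shape.noise_cv})",
    )
    return (
        Spectrum(wl, labelled, replace(meta, blank_id=blank_id)),
        Spectrum(wl, blank, blank_meta, is_blank=True),
        truth,
    )


# ---------------------------------------------------------------------------
# polarized quadruples

def generate_polarized_set(
    truth_r: float,
    truth_G: float,
    scale: float = 1.0e5,
    n_repeats: int = 7,
    noise_cv: float = 0.0,
    seed: int = 0,
    meta: SampleMeta | None = None,
) -> tuple[PolarizedReadingSet, SynthTruth]:
    """Polarized intensity quadruple repeats consistent with (r, G).

    Noiseless components: I_VV = s(1+2r), I_VH = s(1-r)/G, I_HV = G*s,
    I_HH = s, so the per-repeat G estimate and the anisotropy formula
    recover truth_G and truth_r exactly; each reading then gets an
    independent log-normal factor with CV = noise_cv.
    """
    if not -0.5 < truth_r < 1.0:
        raise ValueError(f"truth_r must lie in (-0.5, 1), got {truth_r}")
    if truth_G <= 0:
        raise ValueError("truth_G must be positive")
    if scale <= 0:
        raise ValueError("scale must be positive")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    meta = meta or replace(_DUMMY_META, probe=Probe.DPHPC)
    rng = np.random.default_rng(seed)
    base = {
        "I_VV": scale * (1.0 + 2.0 * truth_r),
        "I_VH": scale * (1.0 - truth_r) / truth_G,
        "I_HV": truth_G * scale,
        "I_HH": scale,
    }
    arrays = {
        k: v * _lognormal_factors(rng, noise_cv, n_repeats)
        for k, v in base.items()
    }
    truth = SynthTruth(
        seed=seed,
        truth_r=truth_r,
        truth_G=truth_G,
        noise_model=f"lognormal(cv={noise_cv})",
    )
    return PolarizedReadingSet(meta=meta, **arrays), truth


def noise_cv_for_condition_sd(
    target_sd: float,
    truth_r: float,
    n_repeats: int = 7,
) -> float:
    """Per-reading CV that yields a given condition-level anisotropy SD.

    Delta-method propagation of independent log-intensity noise through
    the anisotropy formula: each of the four readings contributes
    sensitivity K = (1+2r)(1-r)/3, so SD(r per repeat) = 2*K*cv and the
    7-repeat sample mean has SD 2*K*cv/sqrt(n_repeats), which is also the
    SD across independent samples.
    """
    if target_sd < 0:
        raise ValueError("target_sd must be non-negative")
    K = (1.0 + 2.0 * truth_r) * (1.0 - truth_r) / 3.0
    return target_sd * math.sqrt(n_repeats) / (2.0 * K)


# ---------------------------------------------------------------------------
# TCSPC decays

def generate_decay(
    truth_alphas: Sequence[float],
    truth_taus_ns: Sequence[float],
    irf_fwhm_ns: float = DEFAULT_IRF_FWHM_NS,
    n_channels: int = 1024,
    channel_width_ns: float = DEFAULT_CHANNEL_WIDTH_NS,
    target_peak_counts: int = 15_000,
    seed: int = 0,
    meta: SampleMeta | None = None,
    background_per_channel: float = 0.0,
    poisson: bool = True,
    enforce_peak_band: bool = True,
) -> tuple[DecayHistogram, SynthTruth]:
    """Simulated TCSPC histogram: exponential sum (*) Gaussian IRF + Poisson.

    The IRF histogram (Gaussian of the stated FWHM, integrated over
    channels) is emitted alongside; the expected decay is the convolution
    of the exponential sum with that emitted histogram, scaled so its peak
    equals ``target_peak_counts``, and observed counts are channel-wise
    Poisson draws (or the rounded expectation when ``poisson=False``).
    """
    from .lifetime import DecayModel, convolve_model  # local: avoid cycle

    alphas = np.asarray(truth_alphas, dtype=float)
    taus = np.asarray(truth_taus_ns, dtype=float)
    if abs(alphas.sum() - 1.0) > 1e-9 or np.any(alphas < 0):
        raise ValueError("truth_alphas must be a simplex vector")
    if np.any(taus <= 0):
        raise ValueError("truth_taus_ns must be positive")
    if np.any(np.diff(taus) <= 0):
        raise ValueError("truth_taus_ns must be strictly increasing")
    if irf_fwhm_ns <= 0:
        raise ValueError("irf_fwhm_ns must be positive")
    if channel_width_ns <= 0:
        raise ValueError("channel_width_ns must be positive")
    record_ns = n_channels * channel_width_ns
    if record_ns < 5.0 * taus.max():
        raise ValueError(
            f"channel grid ({record_ns:.1f} ns) too short to contain "
            f"5*max(tau) = {5 * taus.max():.1f} ns"
        )
    if enforce_peak_band and not PEAK_BAND[0] <= target_peak_counts <= PEAK_BAND[1]:
        raise ValueError(
            f"target_peak_counts {target_peak_counts} outside the acquisition "
            f"band {PEAK_BAND}; pass enforce_peak_band=False to override"
        )
    meta = meta or replace(_DUMMY_META, probe=Probe.DPHPC)
    rng = np.random.default_rng(seed)

    sigma = irf_fwhm_ns / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    t0 = max(30 * channel_width_ns, 6.0 * sigma)  # pre-rise room for background
    edges = np.arange(n_channels + 1) * channel_width_ns
    cdf = norm.cdf(edges, loc=t0, scale=sigma)
    irf_frac = np.diff(cdf)
    irf_counts = np.round(irf_frac / max(irf_frac.max(), 1e-300) * target_peak_counts)
    irf_counts = irf_counts.astype(np.int64)

    model = DecayModel(alphas=tuple(alphas), taus_ns=tuple(taus))
    curve = convolve_model(model, irf_counts, channel_width_ns, n_channels)
    scale = (target_peak_counts - background_per_channel) / curve.max()
    expected = scale * curve + background_per_channel
    if poisson:
        counts = rng.poisson(expected)
    else:
        counts = np.round(expected).astype(np.int64)
    truth = SynthTruth(
        seed=seed,
        truth_alphas=tuple(alphas),
        truth_taus_ns=tuple(taus),
        noise_model="poisson" if poisson else "none",
    )
    hist = DecayHistogram(
        counts=counts,
        channel_width_ns=channel_width_ns,
        irf_counts=irf_counts,
        meta=meta,
    )
    return hist, truth


# ---------------------------------------------------------------------------
# full study

DEFAULT_CONTROL_REX: dict[LipidSystem, float] = {
    LipidSystem.POPC: 2.03,
    LipidSystem.POPC_CHOL: 3.05,  # 1.5-fold above the POPC control
    LipidSystem.POPC_CHOL_PSM: 2.20,
}

#: Default ground-truth dipole-potential shifts in mV per (compound, system).
#: Aglycones and the O-glucoside carry the measured shifts; the three
#: C-glucosides are true nulls (the generator encodes "no effect" so that
#: statistical non-detection is a meaningful recovery outcome).
DEFAULT_DELTA_PSI_MV: dict[Compound, dict[LipidSystem, float]] = {
    Compound.PHLORETIN: {
        LipidSystem.POPC: -103.0,
        LipidSystem.POPC_CHOL: -327.0,
        LipidSystem.POPC_CHOL_PSM: -218.0,
    },
    Compound.NOTHOFAGIN: dict.fromkeys(LipidSystem, 0.0),
    Compound.PHLORIZIN: {
        LipidSystem.POPC: -72.0,
        LipidSystem.POPC_CHOL: -173.0,
        LipidSystem.POPC_CHOL_PSM: -126.0,
    },
    Compound.GENISTEIN: {
        LipidSystem.POPC: -61.0,
        LipidSystem.POPC_CHOL: -127.0,
        LipidSystem.POPC_CHOL_PSM: -62.0,
    },
    Compound.G8: dict.fromkeys(LipidSystem, 0.0),
    Compound.RESVERATROL: {
        LipidSystem.POPC: -32.0,
        LipidSystem.POPC_CHOL: -76.0,
        LipidSystem.POPC_CHOL_PSM: -80.0,
    },
    Compound.GLCRESVERATROL: dict.fromkeys(LipidSystem, 0.0),
}

DEFAULT_ANISOTROPY: dict[LipidSystem, float] = {
    LipidSystem.POPC: 0.165,
    LipidSystem.POPC_CHOL: 0.247,
    LipidSystem.POPC_CHOL_PSM: 0.235,
}

DEFAULT_ANISOTROPY_SD: dict[LipidSystem, float] = {
    LipidSystem.POPC: 0.002,
    LipidSystem.POPC_CHOL: 0.007,
    LipidSystem.POPC_CHOL_PSM: 0.005,
}

#: Small fluidization by the stilbenes and C-glucosides in the
#: liquid-disordered system only.
DEFAULT_DELTA_R: dict[Compound, dict[LipidSystem, float]] = {
    Compound.RESVERATROL: {LipidSystem.POPC: -0.008},
    Compound.GLCRESVERATROL: {LipidSystem.POPC: -0.008},
    Compound.G8: {LipidSystem.POPC: -0.006},
    Compound.NOTHOFAGIN: {LipidSystem.POPC: -0.003},
}

DEFAULT_LIFETIME = {"alphas": (0.5, 0.5), "taus_ns": (3.0, 7.0)}
#: Genistein shortens the probe's lifetime (polarity effect).
GENISTEIN_LIFETIME = {"alphas": (0.5, 0.5), "taus_ns": (2.7, 6.3)}


@dataclass(frozen=True)
class StudyDesign:
    """Complete ground-truth specification of a synthetic study."""

    lipid_systems: tuple[LipidSystem, ...] = tuple(LipidSystem)
    compounds: tuple[Compound, ...] = tuple(Compound)
    n_replicates: int = 3
    control_rex: Mapping[LipidSystem, float] = field(
        default_factory=lambda: dict(DEFAULT_CONTROL_REX)
    )
    delta_psi_mV: Mapping[Compound, Mapping[LipidSystem, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_DELTA_PSI_MV.items()}
    )
    k_mV_per_ratio: float = 365.0
    anisotropy: Mapping[LipidSystem, float] = field(
        default_factory=lambda: dict(DEFAULT_ANISOTROPY)
    )
    anisotropy_sd: Mapping[LipidSystem, float] = field(
        default_factory=lambda: dict(DEFAULT_ANISOTROPY_SD)
    )
    delta_r: Mapping[Compound, Mapping[LipidSystem, float]] = field(
        default_factory=lambda: {c: dict(v) for c, v in DEFAULT_DELTA_R.items()}
    )
    G_factor: float = 1.2
    shape: SpectrumShapeConfig = field(default_factory=SpectrumShapeConfig)
    polarized_noise_cv: float | None = None  # None: derived from anisotropy_sd
    n_decay_channels: int = 1024
    decay_peak_counts: int = 15_000
    irf_fwhm_ns: float = DEFAULT_IRF_FWHM_NS
    include_decays: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyDesign":
        """Build a design from a YAML config.

        Recognized keys (all optional): lipid_systems, compounds,
        n_replicates, control_rex, delta_psi_mV, k_mV_per_ratio,
        anisotropy, anisotropy_sd, delta_r, G_factor, noise_cv (spectrum
        reading noise), polarized_noise_cv, decay_peak_counts,
        include_decays.  Enum tokens are case-insensitive.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        if "lipid_systems" in raw:
            kwargs["lipid_systems"] = tuple(
                LipidSystem[s.upper()] for s in raw["lipid_systems"]
            )
        if "compounds" in raw:
            kwargs["compounds"] = tuple(Compound[c.upper()] for c in raw["compounds"])
        if "control_rex" in raw:
            kwargs["control_rex"] = {
                LipidSystem[s.upper()]: float(v) for s, v in raw["control_rex"].items()
            }
        if "delta_psi_mV" in raw:
            kwargs["delta_psi_mV"] = {
                Compound[c.upper()]: {
                    LipidSystem[s.upper()]: float(v) for s, v in per.items()
                }
                for c, per in raw["delta_psi_mV"].items()
            }
        if "anisotropy" in raw:
            kwargs["anisotropy"] = {
                LipidSystem[s.upper()]: float(v) for s, v in raw["anisotropy"].items()
            }
        if "anisotropy_sd" in raw:
            kwargs["anisotropy_sd"] = {
                LipidSystem[s.upper()]: float(v)
                for s, v in raw["anisotropy_sd"].items()
            }
        if "delta_r" in raw:
            kwargs["delta_r"] = {
                Compound[c.upper()]: {
                    LipidSystem[s.upper()]: float(v) for s, v in per.items()
                }
                for c, per in raw["delta_r"].items()
            }
        if "noise_cv" in raw:
            kwargs["shape"] = SpectrumShapeConfig(noise_cv=float(raw["noise_cv"]))
        for key in (
            "n_replicates",
            "k_mV_per_ratio",
            "G_factor",
            "polarized_noise_cv",
            "n_decay_channels",
            "decay_peak_counts",
            "irf_fwhm_ns",
            "include_decays",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def truth_rex(self, system: LipidSystem, compound: Compound) -> float:
        r0 = self.control_rex[system]
        if compound is Compound.CONTROL:
            return r0
        if compound not in self.delta_psi_mV or system not in self.delta_psi_mV[compound]:
            raise ValueError(f"no dipole truth for {compound.name}/{system.name}")
        return r0 + self.delta_psi_mV[compound][system] / self.k_mV_per_ratio

    def truth_r(self, system: LipidSystem, compound: Compound) -> float:
        r0 = self.anisotropy[system]
        return r0 + self.delta_r.get(compound, {}).get(system, 0.0)

    def truth_lifetime(self, system: LipidSystem, compound: Compound) -> dict:
        return GENISTEIN_LIFETIME if compound is Compound.GENISTEIN else DEFAULT_LIFETIME


def generate_study(
    design: StudyDesign | None = None,
    seed: int = 0,
    out_dir: str | Path = "synthetic_study",
) -> tuple[Manifest, pd.DataFrame]:
    """Write a full synthetic study to disk and return manifest + truth table.

    The layout mirrors the wet study: per lipid system and compound,
    triplicate independent samples in both probe arms (each spectrum and
    polarized set with its own blank) plus one TCSPC decay per replicate.
    """
    design = design or StudyDesign()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries: list[ManifestEntry] = []
    truth_rows: list[dict] = []
    counter = 0

    def next_seed() -> int:
        nonlocal counter
        counter += 1
        return int(np.random.SeedSequence((seed, counter)).generate_state(1)[0] % (2**31))

    for system in design.lipid_systems:
        for compound in design.compounds:
            for rep in range(1, design.n_replicates + 1):
                conc = 0.0 if compound is Compound.CONTROL else 50.0
                # --- di-8-ANEPPS spectral arm ---
                sid = f"anepps-{system.name}-{compound.name}-r{rep}".lower()
                meta = SampleMeta(
                    sample_id=sid,
                    lipid_system=system,
                    compound=compound,
                    replicate=rep,
                    probe=Probe.DI8ANEPPS,
                    compound_conc_uM=conc,
                )
                s = next_seed()
                rex = design.truth_rex(system, compound)
                lab, blank, truth = generate_excitation_pair(
                    rex, design.shape, meta, seed=s
                )
                lab_path = out_dir / f"{sid}.csv"
                blank_path = out_dir / f"{blank.meta.sample_id}.csv"
                write_spectrum(lab, lab_path)
                write_spectrum(blank, blank_path)
                entries.append(ManifestEntry(lab_path, RecordKind.SPECTRUM, lab.meta))
                entries.append(
                    ManifestEntry(blank_path, RecordKind.SPECTRUM, blank.meta)
                )
                truth_rows.append(
                    {
                        "sample_id": sid,
                        "lipid_system": system.name,
                        "compound": compound.name,
                        "replicate": rep,
                        "quantity": "rex",
                        "truth": rex,
                        "seed": s,
                    }
                )

                # --- DPH-PC polarized arm ---
                sid_p = f"dph-{system.name}-{compound.name}-r{rep}".lower()
                blank_p_id = f"blank-{sid_p}"
                meta_p = SampleMeta(
                    sample_id=sid_p,
                    lipid_system=system,
                    compound=compound,
                    replicate=rep,
                    probe=Probe.DPHPC,
                    compound_conc_uM=conc,
                    blank_id=blank_p_id,
                )
                r_true = design.truth_r(system, compound)
                cv = design.polarized_noise_cv
                if cv is None:
                    cv = noise_cv_for_condition_sd(
                        design.anisotropy_sd[system], r_true
                    )
                s_p = next_seed()
                pset, _ = generate_polarized_set(
                    r_true,
                    design.G_factor,
                    n_repeats=7,
                    noise_cv=cv,
                    seed=s_p,
                    meta=meta_p,
                )
                # blank: a 0.5% proportional pickup with its own noise
                s_b = next_seed()
                rngb = np.random.default_rng(s_b)
                blank_meta_p = SampleMeta(
                    sample_id=blank_p_id,
                    lipid_system=system,
                    compound=Compound.CONTROL,
                    replicate=rep,
                    probe=Probe.DPHPC,
                    compound_conc_uM=0.0,
                )
                bfrac = 0.005
                blank_p = PolarizedReadingSet(
                    I_VV=bfrac * pset.I_VV * _lognormal_factors(rngb, cv, 7),
                    I_VH=bfrac * pset.I_VH * _lognormal_factors(rngb, cv, 7),
                    I_HV=bfrac * pset.I_HV * _lognormal_factors(rngb, cv, 7),
                    I_HH=bfrac * pset.I_HH * _lognormal_factors(rngb, cv, 7),
                    meta=blank_meta_p,
                )
                p_path = out_dir / f"{sid_p}.csv"
                bp_path = out_dir / f"{blank_p_id}.csv"
                write_polarized(pset, p_path)
                write_polarized(blank_p, bp_path)
                entries.append(ManifestEntry(p_path, RecordKind.POLARIZED, meta_p))
                entries.append(
                    ManifestEntry(bp_path, RecordKind.POLARIZED, blank_meta_p)
                )
                truth_rows.append(
                    {
                        "sample_id": sid_p,
                        "lipid_system": system.name,
                        "compound": compound.name,
                        "replicate": rep,
                        "quantity": "anisotropy",
                        "truth": r_true,
                        "seed": s_p,
                    }
                )

                # --- TCSPC decay arm ---
                if design.include_decays:
                    sid_d = f"tcspc-{system.name}-{compound.name}-r{rep}".lower()
                    meta_d = SampleMeta(
                        sample_id=sid_d,
                        lipid_system=system,
                        compound=compound,
                        replicate=rep,
                        probe=Probe.DPHPC,
                        compound_conc_uM=conc,
                    )
                    lt = design.truth_lifetime(system, compound)
                    s_d = next_seed()
                    hist, _ = generate_decay(
                        lt["alphas"],
                        lt["taus_ns"],
                        irf_fwhm_ns=design.irf_fwhm_ns,
                        n_channels=design.n_decay_channels,
                        target_peak_counts=design.decay_peak_counts,
                        seed=s_d,
                        meta=meta_d,
                    )
                    d_path = out_dir / f"{sid_d}.csv"
                    write_decay(hist, d_path)
                    entries.append(ManifestEntry(d_path, RecordKind.DECAY, meta_d))
                    from .lifetime import DecayModel, mean_lifetime

                    truth_rows.append(
                        {
                            "sample_id": sid_d,
                            "lipid_system": system.name,
                            "compound": compound.name,
                            "replicate": rep,
                            "quantity": "mean_tau_ns",
                            "truth": mean_lifetime(
                                DecayModel(alphas=lt["alphas"], taus_ns=lt["taus_ns"])
                            ),
                            "seed": s_d,
                        }
                    )

    entries.sort(key=lambda e: e.meta.sample_id)
    manifest = Manifest(entries=entries, root=out_dir)
    write_manifest(manifest, out_dir / "manifest.csv")
    truth = pd.DataFrame(truth_rows).sort_values("sample_id").reset_index(drop=True)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return manifest, truth
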