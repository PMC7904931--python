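"""File dialects and validated domain records for the liposome screen.

All on-disk formats are plain UTF-8 delimited text: a ``#``-prefixed
``key: value`` metadata header block followed by a column-labelled CSV body.
Three record kinds exist: excitation spectra (di-8-ANEPPS arm), polarized
intensity quadruples (DPH-PC steady-state arm) and TCSPC decay histograms
with a companion instrument-response file.  A manifest CSV binds files to
experimental conditions and resolves blank linkage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "LipidSystem",
    "Compound",
    "Probe",
    "RecordKind",
    "SampleMeta",
    "Spectrum",
    "PolarizedReadingSet",
    "DecayHistogram",
    "ManifestEntry",
    "Manifest",
    "read_spectrum",
    "write_spectrum",
    "read_polarized",
    "write_polarized",
    "read_decay",
    "write_decay",
    "load_manifest",
    "write_manifest",
    "write_results_table",
    "read_results_table",
]

RATIO_NUM_NM = 420.0
RATIO_DEN_NM = 520.0


class FormatError(ValueError):
    """A file or record violates the project's structural rules."""


class LipidSystem(enum.Enum):
    """Vesicle composition: liquid-disordered, liquid-ordered, raft-mimetic."""

    POPC = "POPC"
    POPC_CHOL = "POPC_CHOL"
    POPC_CHOL_PSM = "POPC_CHOL_PSM"


class Compound(enum.Enum):
    CONTROL = "CONTROL"
    PHLORETIN = "PHLORETIN"
    NOTHOFAGIN = "NOTHOFAGIN"
    PHLORIZIN = "PHLORIZIN"
    GENISTEIN = "GENISTEIN"
    G8 = "G8"
    RESVERATROL = "RESVERATROL"
    GLCRESVERATROL = "GLCRESVERATROL"


#: Aglycone corresponding to each glycoside (for vs.-aglycone comparisons).
AGLYCONE_OF = {
    Compound.NOTHOFAGIN: Compound.PHLORETIN,
    Compound.PHLORIZIN: Compound.PHLORETIN,
    Compound.G8: Compound.GENISTEIN,
    Compound.GLCRESVERATROL: Compound.RESVERATROL,
}

#: The three carbon-linked glucosides (hydrolysis-resistant derivatives).
C_GLUCOSIDES = (Compound.NOTHOFAGIN, Compound.G8, Compound.GLCRESVERATROL)


class Probe(enum.Enum):
    DI8ANEPPS = "DI8ANEPPS"
    DPHPC = "DPHPC"


class RecordKind(enum.Enum):
    SPECTRUM = "SPECTRUM"
    POLARIZED = "POLARIZED"
    DECAY = "DECAY"


def _parse_enum(cls, token: str, fieldname: str):
    try:
        return cls[str(token).strip().upper()]
    except KeyError:
        valid = ", ".join(m.name for m in cls)
        raise FormatError(
            f"unknown {fieldname} token {token!r} (expected one of: {valid})"
        ) from None


@dataclass(frozen=True)
class SampleMeta:
    """Condition labels attached to every measured record."""

    sample_id: str
    lipid_system: LipidSystem
    compound: Compound
    replicate: int
    probe: Probe
    compound_conc_uM: float = 50.0
    blank_id: str | None = None

    def __post_init__(self):
        if self.replicate < 1:
            raise FormatError(f"replicate must be >= 1, got {self.replicate}")
        if self.compound_conc_uM < 0:
            raise FormatError("compound_conc_uM must be non-negative")
        if self.compound is Compound.CONTROL and self.compound_conc_uM != 0:
            raise FormatError(
                "CONTROL entries must have compound_conc_uM = 0, got "
                f"{self.compound_conc_uM}"
            )

    @property
    def condition(self) -> tuple[LipidSystem, Compound]:
        return (self.lipid_system, self.compound)


@dataclass
class Spectrum:
    """A wavelength-indexed excitation intensity trace.

    The grid is strictly ascending in nm; a spectrum used for 420/520
    ratiometry must cover both wavelengths.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    meta: SampleMeta
    is_blank: bool = False

    def __post_init__(self):
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.intensity.ndim != 1:
            raise FormatError("wavelength_nm and intensity must be 1-D")
        if len(self.wavelength_nm) != len(self.intensity):
            raise FormatError(
                "wavelength_nm and intensity lengths differ: "
                f"{len(self.wavelength_nm)} vs {len(self.intensity)}"
            )
        dw = np.diff(self.wavelength_nm)
        if np.any(dw <= 0):
            i = int(np.argmax(dw <= 0))
            raise FormatError(
                "wavelength_nm grid not strictly ascending at index "
                f"{i + 1} ({self.wavelength_nm[i]} -> {self.wavelength_nm[i + 1]})"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise FormatError("intensity contains non-finite values")

    def covers_ratio_range(self) -> bool:
        return (
            self.wavelength_nm[0] <= RATIO_NUM_NM
            and self.wavelength_nm[-1] >= RATIO_DEN_NM
        )

    def intensity_at(self, nm: float) -> float:
        """Intensity at a wavelength, linearly interpolated between grid points."""
        if not (self.wavelength_nm[0] <= nm <= self.wavelength_nm[-1]):
            raise FormatError(
                f"wavelength {nm} nm outside recorded range "
                f"[{self.wavelength_nm[0]}, {self.wavelength_nm[-1]}]"
            )
        return float(np.interp(nm, self.wavelength_nm, self.intensity))


@dataclass
class PolarizedReadingSet:
    """The four polarized emission components, repeated n_repeats times.

    I_XY is the intensity with excitation polarizer X and emission
    polarizer Y (V vertical, H horizontal).
    """

    I_VV: np.ndarray
    I_VH: np.ndarray
    I_HV: np.ndarray
    I_HH: np.ndarray
    meta: SampleMeta
    blank: "PolarizedReadingSet | None" = None

    def __post_init__(self):
        for name in ("I_VV", "I_VH", "I_HV", "I_HH"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        lengths = {len(getattr(self, n)) for n in ("I_VV", "I_VH", "I_HV", "I_HH")}
        if len(lengths) != 1:
            raise FormatError("the four intensity arrays must have equal length")
        if self.n_repeats < 1:
            raise FormatError("n_repeats must be >= 1")
        for name in ("I_VV", "I_VH", "I_HV", "I_HH"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"{name} contains non-finite values")
            if np.any(arr < 0):
                raise FormatError(f"{name} contains negative intensities")

    @property
    def n_repeats(self) -> int:
        return len(self.I_VV)


@dataclass
class DecayHistogram:
    """TCSPC photon-arrival histogram plus its instrument response."""

    counts: np.ndarray
    channel_width_ns: float
    irf_counts: np.ndarray
    meta: SampleMeta

    def __post_init__(self):
        counts = np.asarray(self.counts)
        irf = np.asarray(self.irf_counts)
        for name, arr in (("counts", counts), ("irf_counts", irf)):
            if not np.all(np.isfinite(np.asarray(arr, dtype=float))):
                raise FormatError(f"{name} contains non-finite values")
            as_int = np.asarray(arr, dtype=float)
            if np.any(as_int != np.round(as_int)):
                raise FormatError(f"{name} must be integer-valued")
            if np.any(as_int < 0):
                raise FormatError(f"{name} contains negative counts")
        self.counts = counts.astype(np.int64)
        self.irf_counts = irf.astype(np.int64)
        if self.channel_width_ns <= 0:
            raise FormatError("channel_width_ns must be positive")
        if self.irf_counts.sum() <= 0:
            raise FormatError("irf_counts not normalizable (sum <= 0)")

    @property
    def peak_counts(self) -> int:
        return int(self.counts.max())

    @property
    def n_channels(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class ManifestEntry:
    path: Path
    kind: RecordKind
    meta: SampleMeta


@dataclass
class Manifest:
    """The study layout: one row per file, with resolved blank linkage."""

    entries: list[ManifestEntry] = field(default_factory=list)
    root: Path = Path(".")

    def __post_init__(self):
        ids = [e.meta.sample_id for e in self.entries]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise FormatError(f"duplicate sample_id(s): {sorted(dupes)}")
        by_id = {e.meta.sample_id: e for e in self.entries}
        for e in self.entries:
            bid = e.meta.blank_id
            if bid is None:
                continue
            if bid not in by_id:
                raise FormatError(
                    f"sample {e.meta.sample_id!r}: blank_id {bid!r} "
                    "does not match any manifest row"
                )
            blank = by_id[bid].meta
            if (
                blank.lipid_system is not e.meta.lipid_system
                or blank.replicate != e.meta.replicate
            ):
                raise FormatError(
                    f"sample {e.meta.sample_id!r}: blank {bid!r} is from a "
                    "different lipid system or replicate"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def by_id(self, sample_id: str) -> ManifestEntry:
        for e in self.entries:
            if e.meta.sample_id == sample_id:
                return e
        raise KeyError(sample_id)

    @property
    def blank_ids(self) -> set[str]:
        """sample_ids referenced as blanks by other manifest rows."""
        return {e.meta.blank_id for e in self.entries if e.meta.blank_id is not None}

    def select(
        self,
        kind: RecordKind | None = None,
        probe: Probe | None = None,
        lipid_system: LipidSystem | None = None,
        compound: Compound | None = None,
        blanks: bool | None = None,
    ) -> list[ManifestEntry]:
        blank_ids = self.blank_ids
        out = []
        for e in self.entries:
            if kind is not None and e.kind is not kind:
                continue
            if probe is not None and e.meta.probe is not probe:
                continue
            if lipid_system is not None and e.meta.lipid_system is not lipid_system:
                continue
            if compound is not None and e.meta.compound is not compound:
                continue
            if blanks is not None and (e.meta.sample_id in blank_ids) is not blanks:
                continue
            out.append(e)
        return out

    def summary(self) -> pd.DataFrame:
        """Conditions x replicates table of sample counts (study-design log)."""
        rows = [
            {
                "lipid_system": e.meta.lipid_system.name,
                "compound": e.meta.compound.name,
                "probe": e.meta.probe.name,
                "kind": e.kind.name,
            }
            for e in self.entries
        ]
        df = pd.DataFrame(rows)
        if df.empty:
            return df
        return (
            df.groupby(["probe", "kind", "lipid_system", "compound"])
            .size()
            .rename("n")
            .reset_index()
        )


# ---------------------------------------------------------------------------
# header block helpers

_META_KEYS = (
    "sample_id",
    "lipid_system",
    "compound",
    "replicate",
    "probe",
    "compound_conc_uM",
    "blank_id",
)


def _meta_header_lines(meta: SampleMeta, extra: dict | None = None) -> list[str]:
    pairs: list[tuple[str, str]] = [
        ("sample_id", meta.sample_id),
        ("lipid_system", meta.lipid_system.name),
        ("compound", meta.compound.name),
        ("replicate", str(meta.replicate)),
        ("probe", meta.probe.name),
        ("compound_conc_uM", repr(meta.compound_conc_uM)),
    ]
    if meta.blank_id is not None:
        pairs.append(("blank_id", meta.blank_id))
    for k, v in (extra or {}).items():
        pairs.append((k, str(v)))
    return [f"# {k}: {v}" for k, v in pairs]


def _read_header_and_body(path: Path) -> tuple[dict[str, str], pd.DataFrame]:
    path = Path(path)
    header: dict[str, str] = {}
    body_start = 0
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line[1:].strip()
            if ":" in stripped:
                k, v = stripped.split(":", 1)
                header[k.strip()] = v.strip()
        elif line.strip():
            body_start = i
            break
    else:
        raise FormatError(f"{path}: no data body found")
    from io import StringIO

    try:
        body = pd.read_csv(
            StringIO("".join(lines[body_start:])), float_precision="round_trip"
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise FormatError(f"{path}: cannot parse CSV body ({exc})") from exc
    return header, body


def _meta_from_header(header: dict[str, str], path: Path) -> SampleMeta:
    missing = [k for k in ("sample_id", "lipid_system", "compound", "replicate", "probe") if k not in header]
    if missing:
        raise FormatError(f"{path}: header missing keys {missing}")
    return SampleMeta(
        sample_id=header["sample_id"],
        lipid_system=_parse_enum(LipidSystem, header["lipid_system"], "lipid_system"),
        compound=_parse_enum(Compound, header["compound"], "compound"),
        replicate=int(header["replicate"]),
        probe=_parse_enum(Probe, header["probe"], "probe"),
        compound_conc_uM=float(header.get("compound_conc_uM", 50.0)),
        blank_id=header.get("blank_id") or None,
    )


# ---------------------------------------------------------------------------
# spectrum files

def read_spectrum(path: str | Path, require_ratio_range: bool = True) -> Spectrum:
    """Read a two-column excitation spectrum CSV with metadata header.

    The recorded grid must be strictly ascending and, by default, cover the
    420-520 nm window used for ratiometry.
    """
    path = Path(path)
    header, body = _read_header_and_body(path)
    for col in ("wavelength_nm", "intensity"):
        if col not in body.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    try:
        wl = body["wavelength_nm"].astype(float).to_numpy()
        inten = body["intensity"].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric body row ({exc})") from exc
    meta = _meta_from_header(header, path)
    is_blank = header.get("is_blank", "false").lower() in ("true", "1", "yes")
    try:
        spec = Spectrum(wl, inten, meta, is_blank=is_blank)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if require_ratio_range and not spec.covers_ratio_range():
        raise FormatError(
            f"{path}: range [{wl[0]}, {wl[-1]}] nm does not cover ratio "
            f"wavelengths [{RATIO_NUM_NM:g}, {RATIO_DEN_NM:g}] nm"
        )
    return spec


def write_spectrum(spec: Spectrum, path: str | Path) -> Path:
    path = Path(path)
    lines = _meta_header_lines(spec.meta, {"is_blank": str(spec.is_blank).lower()})
    lines.append("wavelength_nm,intensity")
    for w, i in zip(spec.wavelength_nm, spec.intensity):
        lines.append(f"{float(w)!r},{float(i)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# polarized files

def read_polarized(path: str | Path) -> PolarizedReadingSet:
    path = Path(path)
    header, body = _read_header_and_body(path)
    for col in ("repeat", "I_VV", "I_VH", "I_HV", "I_HH"):
        if col not in body.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    meta = _meta_from_header(header, path)
    try:
        return PolarizedReadingSet(
            I_VV=body["I_VV"].astype(float).to_numpy(),
            I_VH=body["I_VH"].astype(float).to_numpy(),
            I_HV=body["I_HV"].astype(float).to_numpy(),
            I_HH=body["I_HH"].astype(float).to_numpy(),
            meta=meta,
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_polarized(pset: PolarizedReadingSet, path: str | Path) -> Path:
    path = Path(path)
    lines = _meta_header_lines(pset.meta)
    lines.append("repeat,I_VV,I_VH,I_HV,I_HH")
    for k in range(pset.n_repeats):
        lines.append(
            f"{k + 1},{float(pset.I_VV[k])!r},{float(pset.I_VH[k])!r},"
            f"{float(pset.I_HV[k])!r},{float(pset.I_HH[k])!r}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# decay files

def _irf_path_for(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".irf.csv") if path.suffix == ".csv" else Path(str(path) + ".irf.csv")


def read_decay(path: str | Path, irf_path: str | Path | None = None) -> DecayHistogram:
    """Read a TCSPC decay CSV and its companion ``<name>.irf.csv``."""
    path = Path(path)
    header, body = _read_header_and_body(path)
    for col in ("channel", "counts"):
        if col not in body.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if irf_path is None:
        irf_path = _irf_path_for(path)
    irf_path = Path(irf_path)
    if not irf_path.exists():
        raise FormatError(f"{path}: no IRF file found at {irf_path}")
    _, irf_body = _read_header_and_body(irf_path)
    if "counts" not in irf_body.columns:
        raise FormatError(f"{irf_path}: missing column 'counts'")
    meta = _meta_from_header(header, path)
    if "channel_width_ns" not in header:
        raise FormatError(f"{path}: header missing channel_width_ns")
    try:
        return DecayHistogram(
            counts=body["counts"].to_numpy(),
            channel_width_ns=float(header["channel_width_ns"]),
            irf_counts=irf_body["counts"].to_numpy(),
            meta=meta,
        )
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_decay(h: DecayHistogram, path: str | Path) -> Path:
    path = Path(path)
    lines = _meta_header_lines(h.meta, {"channel_width_ns": repr(h.channel_width_ns)})
    lines.append("channel,counts")
    for k, c in enumerate(h.counts):
        lines.append(f"{k},{int(c)}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    irf_path = _irf_path_for(path)
    irf_lines = [f"# channel_width_ns: {h.channel_width_ns!r}", "channel,counts"]
    for k, c in enumerate(h.irf_counts):
        irf_lines.append(f"{k},{int(c)}")
    irf_path.write_text("\n".join(irf_lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# manifest

_MANIFEST_COLUMNS = (
    "sample_id",
    "kind",
    "lipid_system",
    "compound",
    "replicate",
    "probe",
    "compound_conc_uM",
    "blank_id",
    "file",
)


def load_manifest(path: str | Path, check_files: bool = True) -> Manifest:
    """Load and validate a study manifest CSV.

    Row order is irrelevant: the resolved study structure depends only on
    row content.  Blank linkage must resolve within the manifest.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str, "blank_id": str})
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns and c != "compound_conc_uM"]
    if missing:
        raise FormatError(f"{path}: manifest missing columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: no entries")
    root = path.parent
    entries = []
    for _, row in df.iterrows():
        blank_id = row.get("blank_id")
        if pd.isna(blank_id) or blank_id == "":
            blank_id = None
        conc = row.get("compound_conc_uM", 50.0)
        if pd.isna(conc):
            conc = 50.0
        meta = SampleMeta(
            sample_id=str(row["sample_id"]),
            lipid_system=_parse_enum(LipidSystem, row["lipid_system"], "lipid_system"),
            compound=_parse_enum(Compound, row["compound"], "compound"),
            replicate=int(row["replicate"]),
            probe=_parse_enum(Probe, row["probe"], "probe"),
            compound_conc_uM=float(conc),
            blank_id=blank_id,
        )
        fpath = root / str(row["file"])
        if check_files and not fpath.exists():
            raise FormatError(f"{path}: referenced file does not exist: {fpath}")
        entries.append(
            ManifestEntry(path=fpath, kind=_parse_enum(RecordKind, row["kind"], "kind"), meta=meta)
        )
    # deterministic structure regardless of on-disk row order
    entries.sort(key=lambda e: e.meta.sample_id)
    return Manifest(entries=entries, root=root)


def write_manifest(manifest: Manifest, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for e in manifest.entries:
        rows.append(
            {
                "sample_id": e.meta.sample_id,
                "kind": e.kind.name,
                "lipid_system": e.meta.lipid_system.name,
                "compound": e.meta.compound.name,
                "replicate": e.meta.replicate,
                "probe": e.meta.probe.name,
                "compound_conc_uM": e.meta.compound_conc_uM,
                "blank_id": e.meta.blank_id or "",
                "file": str(Path(e.path).relative_to(manifest.root)),
            }
        )
    pd.DataFrame(rows, columns=_MANIFEST_COLUMNS).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# results tables

_COMPOUND_ORDER = [c.name for c in Compound]
_SYSTEM_ORDER = [s.name for s in LipidSystem]


def write_results_table(rows: Iterable[dict], path: str | Path) -> Path:
    """Write condition-level results as a TSV with deterministic ordering.

    Rows are dicts with at least ``lipid_system`` and ``compound`` labels
    plus estimate/uncertainty/n columns.  Ordering is lipid system first,
    then compound in the canonical enum order.
    """
    path = Path(path)
    rows = list(rows)
    if not rows:
        cols = ["lipid_system", "compound", "estimate", "sd", "n"]
        pd.DataFrame(columns=cols).to_csv(path, sep="\t", index=False)
        return path
    df = pd.DataFrame(rows)
    for col in ("lipid_system", "compound"):
        if col not in df.columns:
            raise FormatError(f"results rows missing {col!r} label")
        df[col] = df[col].map(lambda v: v.name if isinstance(v, enum.Enum) else str(v))
    df["_sys"] = df["lipid_system"].map(_SYSTEM_ORDER.index)
    df["_cmp"] = df["compound"].map(_COMPOUND_ORDER.index)
    df = df.sort_values(["_sys", "_cmp"]).drop(columns=["_sys", "_cmp"])
    lead = ["lipid_system", "compound"]
    df = df[lead + [c for c in df.columns if c not in lead]]
    df.to_csv(path, sep="\t", index=False)
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")
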