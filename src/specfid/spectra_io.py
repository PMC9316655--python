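"""Readers and writers for MS/MS spectral-library text formats.

Spectral libraries ship as MSP (the NIST text dialect) or MGF peak-list
files.  Both are line-oriented: a metadata header followed by ``m/z
intensity`` pairs.  Parsing normalizes the sixteen metadata fields found in
public libraries (InChIKey, SMILES, spectrum ID, source, ionization mode,
adduct, precursor mass, exact mass, instrument type, instrument, collision
energy, mass accuracy, library, external IDs, plus the peak list itself)
into :class:`SpectrumRecord`, matching header keys case-insensitively
through a synonym table because the big repositories use different
dialects for the same field.

Malformed entries (e.g. a ``Num Peaks`` count that disagrees with the peak
lines that follow) are skipped and reported as :class:`ParseIssue` objects
carrying the line number; parsing always continues with the next entry.
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple


class Peak(NamedTuple):
    """A single fragment peak: m/z in thomson, intensity in arbitrary units."""

    mz: float
    intensity: float


@dataclass
class SpectrumRecord:
    """One MS/MS spectrum with normalized library metadata.

    ``peaks`` are kept sorted ascending by m/z.  Optional fields are
    ``None`` when the source entry does not carry them.  Header keys that
    do not map onto a modeled field are preserved verbatim in ``extras``.
    """

    peaks: list[Peak] = field(default_factory=list)
    inchikey: str | None = None
    smiles: str | None = None
    spectrum_id: str | None = None
    source: str | None = None
    ionization_mode: str | None = None  # "positive" | "negative"
    adduct: str | None = None
    precursor_mz: float | None = None
    exact_mass: float | None = None
    instrument_type: str | None = None
    instrument: str | None = None
    collision_energy_raw: str | None = None
    collision_energy_ev: float | None = None
    mass_accuracy: float | None = None
    library: str | None = None
    external_ids: str | None = None
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)
        if self.ionization_mode is not None and self.ionization_mode not in (
            "positive",
            "negative",
        ):
            raise ValueError(f"ionization_mode must be positive/negative, got {self.ionization_mode!r}")
        if self.collision_energy_ev is not None and self.collision_energy_ev < 0:
            raise ValueError("collision_energy_ev must be >= 0")

    @property
    def base_peak_intensity(self) -> float:
        return max((p.intensity for p in self.peaks), default=0.0)


@dataclass(frozen=True)
class ParseIssue:
    """A recoverable per-entry parse failure."""

    line: int
    message: str


# canonical field -> header-key synonyms (lower-cased, stripped)
_SYNONYMS: dict[str, tuple[str, ...]] = {
    "spectrum_id": ("name", "title", "spectrum id", "spectrumid", "spectrum_id", "db#", "id"),
    "inchikey": ("inchikey", "inchi key", "inchikey_id"),
    "smiles": ("smiles", "canonical smiles", "canonicalsmiles"),
    "source": ("source", "data source", "submituser"),
    "ionization_mode": ("ion mode", "ion_mode", "ionmode", "ionization mode", "ionization_mode", "mode", "polarity"),
    "adduct": ("precursor_type", "precursortype", "precursor type", "adduct", "ion"),
    "precursor_mz": ("precursormz", "precursor_mz", "precursor m/z", "precursor mz", "pepmass", "precursor mass"),
    "exact_mass": ("exactmass", "exact_mass", "exact mass", "monoisotopic mass", "mw"),
    "instrument_type": ("instrument_type", "instrument type", "instrumenttype"),
    "instrument": ("instrument",),
    "collision_energy": ("collision_energy", "collision energy", "collisionenergy", "ce"),
    "mass_accuracy": ("mass_accuracy", "mass accuracy", "ms mass accuracy"),
    "library": ("library", "library name"),
    "external_ids": ("external_ids", "external ids", "externalids", "comments", "comment"),
}

_KEY_TO_FIELD = {syn: fld for fld, syns in _SYNONYMS.items() for syn in syns}

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def is_valid_inchikey(key: str) -> bool:
    """Format-only InChIKey check: 27 chars, two hyphens. No checksum."""
    return bool(_INCHIKEY_RE.match(key))


def first_block(inchikey: str) -> str:
    """The 14-character skeleton block of an InChIKey."""
    return inchikey.split("-")[0]


def _normalize_mode(value: str) -> str | None:
    v = value.strip().lower()
    if v in ("p", "+", "pos", "positive", "1+", "+1"):
        return "positive"
    if v in ("n", "-", "neg", "negative", "1-", "-1"):
        return "negative"
    return None


_RANGE_RE = re.compile(r"(-?\d+(?:\.\d+)?)\s*[-–]\s*(\d+(?:\.\d+)?)")
_NUM_RE = re.compile(r"\d+(?:\.\d+)?")


def parse_collision_energy(raw: str | None) -> float | None:
    """Extract a collision energy in eV from a vendor string.

    Libraries carry hundreds of collision-energy formats ("35", "35 eV",
    "CE: 10V", "20-40", "HCD (NCE 30%)").  Only values with unambiguous
    eV semantics are converted: numeric ranges collapse to their mean, and
    normalized collision energies expressed as percentages (NCE) return
    ``None`` because converting them to eV needs instrument calibration.
    Never raises; anything unparseable maps to ``None``.
    """
    if raw is None:
        return None
    text = str(raw).strip()
    if not text:
        return None
    low = text.lower()
    if "%" in low or "nce" in low:
        return None
    m = _RANGE_RE.search(text)
    if m:
        a, b = float(m.group(1)), float(m.group(2))
        if a >= 0:
            return (a + b) / 2.0
    m = _NUM_RE.search(text)
    if m:
        value = float(m.group(0))
        return value if math.isfinite(value) else None
    return None


def _apply_metadata(record: SpectrumRecord, key: str, value: str) -> None:
    fld = _KEY_TO_FIELD.get(key.strip().lower())
    value = value.strip()
    if fld is None:
        record.extras[key.strip()] = value
        return
    if fld == "ionization_mode":
        mode = _normalize_mode(value)
        if mode is not None:
            record.ionization_mode = mode
        else:
            record.extras[key.strip()] = value
    elif fld in ("precursor_mz", "exact_mass", "mass_accuracy"):
        try:
            # MGF PEPMASS may carry "mz intensity"
            setattr(record, fld, float(value.split()[0]))
        except (ValueError, IndexError):
            record.extras[key.strip()] = value
    elif fld == "collision_energy":
        record.collision_energy_raw = value
        record.collision_energy_ev = parse_collision_energy(value)
    else:
        setattr(record, fld, value)


_PEAK_LINE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)[\s,;:]+(\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)")


def _parse_peak_line(line: str) -> Peak | None:
    m = _PEAK_LINE_RE.match(line)
    if m is None:
        return None
    return Peak(float(m.group(1)), float(m.group(2)))


def scan_msp(text: str) -> tuple[list[SpectrumRecord], list[ParseIssue]]:
    """Parse MSP text, returning records and recoverable per-entry issues."""
    records: list[SpectrumRecord] = []
    issues: list[ParseIssue] = []
    lines = text.splitlines()
    i, n = 0, len(lines)
    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        entry_start = i
        record = SpectrumRecord()
        declared: int | None = None
        peaks: list[Peak] = []
        error: str | None = None
        in_peaks = False
        while i < n and lines[i].strip():
            line = lines[i]
            if not in_peaks and ":" in line:
                key, _, value = line.partition(":")
                if key.strip().lower() in ("num peaks", "numpeaks", "num_peaks"):
                    try:
                        declared = int(value.strip())
                    except ValueError:
                        error = f"unreadable peak count {value.strip()!r}"
                    in_peaks = True
                else:
                    _apply_metadata(record, key, value)
            else:
                in_peaks = True
                peak = _parse_peak_line(line)
                if peak is None:
                    error = error or f"unreadable peak line {line.strip()!r}"
                else:
                    peaks.append(peak)
            i += 1
        if error is None and declared is not None and declared != len(peaks):
            error = f"Num Peaks declares {declared} but {len(peaks)} peak lines found"
        if error is not None:
            issues.append(ParseIssue(line=entry_start + 1, message=error))
            continue
        record.peaks = sorted(peaks)
        records.append(record)
    return records, issues


def parse_msp(text: str) -> list[SpectrumRecord]:
    """Parse MSP text; malformed entries are silently skipped (see scan_msp)."""
    return scan_msp(text)[0]


def scan_mgf(text: str) -> tuple[list[SpectrumRecord], list[ParseIssue]]:
    """Parse MGF text (BEGIN IONS / END IONS blocks)."""
    records: list[SpectrumRecord] = []
    issues: list[ParseIssue] = []
    lines = text.splitlines()
    i, n = 0, len(lines)
    while i < n:
        if lines[i].strip().upper() != "BEGIN IONS":
            i += 1
            continue
        block_start = i
        i += 1
        record = SpectrumRecord()
        peaks: list[Peak] = []
        charge_sign: str | None = None
        error: str | None = None
        closed = False
        while i < n:
            line = lines[i].strip()
            if line.upper() == "END IONS":
                closed = True
                i += 1
                break
            if "=" in line:
                key, _, value = line.partition("=")
                if key.strip().upper() == "CHARGE":
                    v = value.strip()
                    charge_sign = "negative" if v.endswith("-") else "positive"
                    record.extras["CHARGE"] = v
                else:
                    _apply_metadata(record, key, value)
            elif line:
                peak = _parse_peak_line(line)
                if peak is None:
                    error = error or f"unreadable peak line {line!r}"
                else:
                    peaks.append(peak)
            i += 1
        if not closed:
            error = "missing END IONS"
        if error is not None:
            issues.append(ParseIssue(line=block_start + 1, message=error))
            continue
        if record.ionization_mode is None and charge_sign is not None:
            record.ionization_mode = charge_sign
        record.peaks = sorted(peaks)
        records.append(record)
    return records, issues


def parse_mgf(text: str) -> list[SpectrumRecord]:
    return scan_mgf(text)[0]


_MSP_FIELD_ORDER: tuple[tuple[str, str], ...] = (
    ("spectrum_id", "Name"),
    ("inchikey", "InChIKey"),
    ("smiles", "SMILES"),
    ("source", "Source"),
    ("ionization_mode", "Ion_mode"),
    ("adduct", "Precursor_type"),
    ("precursor_mz", "PrecursorMZ"),
    ("exact_mass", "ExactMass"),
    ("instrument_type", "Instrument_type"),
    ("instrument", "Instrument"),
    ("collision_energy_raw", "Collision_energy"),
    ("mass_accuracy", "Mass_accuracy"),
    ("library", "Library"),
    ("external_ids", "External_IDs"),
)


def write_msp(records: list[SpectrumRecord]) -> str:
    """Serialize records to MSP text; ``parse_msp`` round-trips all modeled fields."""
    blocks: list[str] = []
    for rec in records:
        lines: list[str] = []
        for fld, header in _MSP_FIELD_ORDER:
            value = getattr(rec, fld)
            if value is None:
                continue
            if fld == "ionization_mode":
                value = "P" if value == "positive" else "N"
            lines.append(f"{header}: {value}")
        for key, value in rec.extras.items():
            lines.append(f"{key}: {value}")
        lines.append(f"Num Peaks: {len(rec.peaks)}")
        for p in rec.peaks:
            lines.append(f"{p.mz:.10g} {p.intensity:.10g}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def _read_text(path: str | Path) -> str:
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            return fh.read()
    return path.read_text(encoding="utf-8")


def read_msp(path: str | Path) -> list[SpectrumRecord]:
    """Read an MSP file (plain or gzip-compressed)."""
    return parse_msp(_read_text(path))


def read_mgf(path: str | Path) -> list[SpectrumRecord]:
    """Read an MGF file (plain or gzip-compressed)."""
    return parse_mgf(_read_text(path))


def write_msp_file(records: list[SpectrumRecord], path: str | Path) -> None:
    Path(path).write_text(write_msp(records), encoding="utf-8")
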