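"""Spectral preprocessing: scaling, filtering, selecting, merging, binning.

The transformation chain turns raw library spectra into fixed-length
intensity vectors suitable as model input:

1. *select* — keep spectra from the allowed instrument types
   (Orbitrap, QqQ, Q-TOF, ion trap) so training data stay homogeneous;
2. *scale* — max-normalize peak intensities into [0, 100];
3. *filter* — drop peaks above the precursor m/z, reject spectra with
   fewer than five peaks above 2% relative intensity, and reject
   compounds whose neutral mass falls outside [100, 1010] Da;
4. *merge* (training only) — pool all spectra of one compound, keyed by
   full InChIKey, accumulating coincident peaks;
5. *bin* — accumulate intensities over unit-width integer m/z bins,
   yielding a 1174-long vector by default.

Scaling is max-normalization (implicit minimum 0) rather than literal
(x-min)/(max-min): the literal form would zero the weakest real peak and
interact destructively with the 2% relative-intensity filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import floor

import numpy as np

from .spectra_io import Peak, SpectrumRecord

#: neutral-mass shift (Da) and charge sign per adduct, singly charged
ADDUCT_SHIFTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (1.007276, +1),
    "[M+Na]+": (22.989218, +1),
    "[M+NH4]+": (18.033823, +1),
    "[M-H]-": (-1.007276, -1),
    "[M+Cl]-": (34.969402, -1),
}

_INSTRUMENT_ALIASES = {
    "orbitrap": "Orbitrap",
    "q-tof": "Q-TOF",
    "qtof": "Q-TOF",
    "q tof": "Q-TOF",
    "qqq": "QqQ",
    "it": "IT",
    "ion trap": "IT",
    "iontrap": "IT",
    "itft": "IT",
}


def normalize_instrument_type(value: str | None) -> str | None:
    if value is None:
        return None
    return _INSTRUMENT_ALIASES.get(value.strip().lower(), value.strip())


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable thresholds of the filtering chain (defaults follow the
    standard library-curation settings: >=5 peaks above 2% of the base
    peak, neutral mass in [100, 1010] Da, intensities scaled to 100)."""

    min_peaks: int = 5
    min_rel_intensity: float = 2.0  # percent of base peak
    mass_min: float = 100.0
    mass_max: float = 1010.0
    scale_max: float = 100.0
    allowed_instrument_types: frozenset[str] = frozenset({"Orbitrap", "QqQ", "Q-TOF", "IT"})
    allow_unknown_instrument: bool = True

    def __post_init__(self) -> None:
        if self.min_peaks < 1:
            raise ValueError("min_peaks must be >= 1")
        if not (0 <= self.min_rel_intensity < 100):
            raise ValueError("min_rel_intensity must be in [0, 100)")
        if self.mass_min >= self.mass_max:
            raise ValueError("mass_min must be < mass_max")


@dataclass(frozen=True)
class BinningSpec:
    """Consecutive unit-width integer m/z bins [b, b+1)."""

    bin_start: int = 1
    bin_count: int = 1174
    bin_width: int = 1  # fixed

    def __post_init__(self) -> None:
        if self.bin_count < 1:
            raise ValueError("bin_count must be >= 1")
        if self.bin_width != 1:
            raise ValueError("bin_width is fixed at 1")


@dataclass
class BinnedSpectrum:
    """Fixed-length accumulated-intensity vector, optionally extended by
    the three instrument-context bits (energy, resolution, mode)."""

    values: np.ndarray
    compound_key: str | None = None  # InChIKey first block
    spectrum_id: str | None = None
    context: "object | None" = None  # models.InstrumentContext once attached
    n_dropped_peaks: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("binned values must be non-negative")


class DegenerateSpectrumError(ValueError):
    """All-zero intensities cannot be scaled."""


@dataclass(frozen=True)
class Rejection:
    """A spectrum rejected by the filter chain, with a machine-readable reason."""

    reason: str
    spectrum_id: str | None = None


def scale_intensities(peaks: list[Peak], scale_max: float = 100.0) -> list[Peak]:
    """Max-normalize intensities so the base peak equals ``scale_max``."""
    if not peaks:
        raise DegenerateSpectrumError("empty peak list")
    top = max(p.intensity for p in peaks)
    if top <= 0:
        raise DegenerateSpectrumError("all intensities are zero")
    return [Peak(p.mz, p.intensity / top * scale_max) for p in peaks]


def neutral_mass(record: SpectrumRecord) -> float | None:
    """Neutral monoisotopic mass implied by precursor m/z and adduct.

    Falls back to the record's exact mass when the adduct is unknown.
    """
    if record.precursor_mz is not None and record.adduct in ADDUCT_SHIFTS:
        shift, _ = ADDUCT_SHIFTS[record.adduct]
        return record.precursor_mz - shift
    return record.exact_mass


def filter_spectrum(record: SpectrumRecord, cfg: PreprocessConfig = PreprocessConfig()) -> SpectrumRecord | Rejection:
    """Apply the filter chain to one spectrum.

    Returns a new record carrying scaled, filtered peaks, or a
    :class:`Rejection` naming the first rule violated:

    - ``missing-precursor``: the super-precursor rule cannot be applied;
    - ``instrument-type``: not in the allowed set;
    - ``few-peaks``: fewer than ``min_peaks`` peaks above
      ``min_rel_intensity`` percent of the base peak (measured after
      super-precursor peaks are removed);
    - ``mass-range``: neutral mass outside [mass_min, mass_max];
    - ``degenerate``: no peaks with positive intensity remain.
    """
    sid = record.spectrum_id
    itype = normalize_instrument_type(record.instrument_type)
    if itype is None:
        if not cfg.allow_unknown_instrument:
            return Rejection("instrument-type", sid)
    elif itype not in cfg.allowed_instrument_types:
        return Rejection("instrument-type", sid)
    if record.precursor_mz is None:
        return Rejection("missing-precursor", sid)
    kept = [p for p in record.peaks if p.mz <= record.precursor_mz]
    if not kept or max(p.intensity for p in kept) <= 0:
        return Rejection("degenerate", sid)
    scaled = scale_intensities(kept, cfg.scale_max)
    threshold = cfg.min_rel_intensity / 100.0 * cfg.scale_max
    if sum(1 for p in scaled if p.intensity > threshold) < cfg.min_peaks:
        return Rejection("few-peaks", sid)
    mass = neutral_mass(record)
    if mass is None or not (cfg.mass_min <= mass <= cfg.mass_max):
        return Rejection("mass-range", sid)
    return replace(record, peaks=scaled)


def merge_spectra(records: list[SpectrumRecord], scale_max: float = 100.0) -> list[SpectrumRecord]:
    """Merge spectra of the same compound (full-InChIKey equality).

    Member peak lists (already scaled) are pooled; peaks landing in the
    same integer m/z bin accumulate, the representative m/z being their
    intensity-weighted mean, and the merged list is re-scaled to
    ``scale_max``.  The merged precursor m/z is taken from the most
    frequent adduct group.  Records without an InChIKey pass through
    unmerged, flagged in ``extras``.
    """
    groups: dict[str, list[SpectrumRecord]] = {}
    passthrough: list[SpectrumRecord] = []
    for rec in records:
        if rec.inchikey:
            groups.setdefault(rec.inchikey, []).append(rec)
        else:
            flagged = replace(rec, extras={**rec.extras, "unmerged": "no-inchikey"})
            passthrough.append(flagged)
    merged: list[SpectrumRecord] = []
    for key, members in groups.items():
        if len(members) == 1:
            merged.append(members[0])
            continue
        acc: dict[int, list[float]] = {}  # bin -> [sum_intensity, sum_w_mz]
        for rec in members:
            for p in rec.peaks:
                b = floor(p.mz)
                cell = acc.setdefault(b, [0.0, 0.0])
                cell[0] += p.intensity
                cell[1] += p.intensity * p.mz
        pooled = [Peak(wm / s, s) for s, wm in acc.values() if s > 0]
        pooled = scale_intensities(pooled, scale_max)
        adduct_groups: dict[str | None, list[SpectrumRecord]] = {}
        for rec in members:
            adduct_groups.setdefault(rec.adduct, []).append(rec)
        top_adduct, top_members = max(adduct_groups.items(), key=lambda kv: (len(kv[1]), str(kv[0])))
        precursors = [r.precursor_mz for r in top_members if r.precursor_mz is not None]
        head = members[0]
        merged.append(
            replace(
                head,
                peaks=pooled,
                adduct=top_adduct,
                precursor_mz=float(np.mean(precursors)) if precursors else head.precursor_mz,
                extras={**head.extras, "merged_from": ";".join(str(r.spectrum_id) for r in members)},
            )
        )
    return merged + passthrough


def bin_spectrum(peaks: list[Peak], spec: BinningSpec = BinningSpec()) -> BinnedSpectrum:
    """Accumulate peak intensities over unit integer m/z bins.

    ``values[i]`` sums the intensities of peaks with ``floor(mz) ==
    bin_start + i``; peaks outside the bin range are dropped and counted.
    Total in-range intensity is conserved.
    """
    values = np.zeros(spec.bin_count, dtype=float)
    dropped = 0
    for p in peaks:
        idx = floor(p.mz) - spec.bin_start
        if 0 <= idx < spec.bin_count:
            values[idx] += p.intensity
        else:
            dropped += 1
    return BinnedSpectrum(values=values, n_dropped_peaks=dropped)


def drop_zero_bins(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove columns that are identically zero across all rows.

    Used only for the flat baseline models (LR/SLP/SVM/MLP), whose inputs
    need not be spatially consecutive; the convolutional model always
    consumes the full bin vector.  Returns the reduced matrix and the
    kept-column indices for projecting new spectra onto the same space.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] == 0:
        raise ValueError("matrix must be 2-D and nonempty")
    kept = np.flatnonzero(np.any(matrix != 0, axis=0))
    if kept.size == 0:
        warnings.warn("all bins are zero across all spectra", stacklevel=2)
    return matrix[:, kept], kept


def attach_context(binned: BinnedSpectrum, ctx, bin_count: int) -> BinnedSpectrum:
    """Append the three binary context entries (energy, resolution, mode).

    Guards against double application by checking the input length against
    ``bin_count``.
    """
    if binned.values.shape[0] != bin_count:
        raise ValueError(
            f"expected a plain {bin_count}-bin vector, got length {binned.values.shape[0]} (context already attached?)"
        )
    bits = ctx.as_bits()
    return BinnedSpectrum(
        values=np.concatenate([binned.values, np.asarray(bits, dtype=float)]),
        compound_key=binned.compound_key,
        spectrum_id=binned.spectrum_id,
        context=ctx,
        n_dropped_peaks=binned.n_dropped_peaks,
    )


@dataclass
class ProcessedCorpus:
    """Dense model-input matrix plus sidecar metadata, one row per spectrum."""

    matrix: np.ndarray
    spectrum_ids: list[str | None]
    inchikeys: list[str | None]
    records: list[SpectrumRecord] = field(default_factory=list)
    rejections: list[Rejection] = field(default_factory=list)


def preprocess_corpus(
    records: list[SpectrumRecord],
    cfg: PreprocessConfig = PreprocessConfig(),
    binning: BinningSpec = BinningSpec(),
    merge: bool = True,
) -> ProcessedCorpus:
    """Run the full chain select -> scale -> filter -> [merge] -> bin.

    Merging is skipped when preparing evaluation queries, so the model is
    judged on individual spectra.
    """
    surviving: list[SpectrumRecord] = []
    rejections: list[Rejection] = []
    for rec in records:
        out = filter_spectrum(rec, cfg)
        if isinstance(out, Rejection):
            rejections.append(out)
        else:
            surviving.append(out)
    if merge:
        surviving = merge_spectra(surviving, cfg.scale_max)
    rows = [bin_spectrum(rec.peaks, binning).values for rec in surviving]
    matrix = np.vstack(rows) if rows else np.zeros((0, binning.bin_count))
    return ProcessedCorpus(
        matrix=matrix,
        spectrum_ids=[r.spectrum_id for r in surviving],
        inchikeys=[r.inchikey for r in surviving],
        records=surviving,
        rejections=rejections,
    )
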