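"""Candidate retrieval and Tanimoto-ranked metabolite annotation.

Given a query spectrum's precursor m/z (and optionally the molecular
formula), candidates are pulled from a local compound table: a compound
matches when, for some adduct compatible with the ionization mode, the
neutral mass implied by the precursor lies within a ppm tolerance
(default 20 ppm) of the compound's monoisotopic mass.  When the formula
is known the list is shortened to candidates with the identical element
composition.  Candidates are then scored by Tanimoto similarity between
the spectrum's predicted fingerprint and each candidate's computed
fingerprint, and returned ranked.

Retrieval runs against a local table (TSV/CSV with columns id, inchikey,
smiles, formula, monoisotopic_mass and optionally a precomputed
fingerprint) rather than a web service, so annotation works offline; the
table can be exported from any compound database.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .fingerprints import Fingerprint, StructureError, compute_fingerprints, tanimoto
from .preprocess import ADDUCT_SHIFTS
from .spectra_io import first_block, is_valid_inchikey


@dataclass
class CompoundRecord:
    """One candidate-database row; the fingerprint is computed lazily from
    SMILES and cached."""

    id: str
    inchikey: str
    smiles: str
    formula: str
    monoisotopic_mass: float
    fingerprint: Fingerprint | None = None

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError("monoisotopic_mass must be positive")
        if not is_valid_inchikey(self.inchikey):
            raise ValueError(f"invalid InChIKey format: {self.inchikey!r}")


@dataclass(frozen=True)
class Adduct:
    name: str
    shift: float  # Da added to the neutral mass
    charge: int  # sign carries the ionization mode

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


DEFAULT_ADDUCTS: tuple[Adduct, ...] = tuple(
    Adduct(name, shift, charge) for name, (shift, charge) in ADDUCT_SHIFTS.items()
)


@dataclass(frozen=True)
class SearchConfig:
    ppm_tolerance: float = 20.0
    adducts: tuple[Adduct, ...] = DEFAULT_ADDUCTS
    mode_filter: bool = True  # restrict adducts to the query's ionization mode

    def __post_init__(self) -> None:
        if self.ppm_tolerance <= 0:
            raise ValueError("ppm_tolerance must be positive")

    def adducts_for_mode(self, mode: str | None) -> tuple[Adduct, ...]:
        if not self.mode_filter or mode is None:
            return self.adducts
        sign = +1 if mode == "positive" else -1
        selected = tuple(a for a in self.adducts if a.charge * sign > 0)
        if not selected:
            raise ValueError(f"no adducts configured for {mode} mode")
        return selected


@dataclass
class CandidateMatch:
    """A compound matched by mass search, possibly via several adducts."""

    compound: CompoundRecord
    adducts: list[str]
    ppm_error: float  # best (smallest) error over matching adducts


@dataclass
class RankedAnnotation:
    """Candidates of one query ordered by descending Tanimoto score."""

    query_id: str | None
    basis: str  # "mass" | "formula"
    entries: list[tuple[CandidateMatch, float]] = field(default_factory=list)
    n_dropped: int = 0  # candidates with uncomputable fingerprints


def retrieve_candidates(
    precursor_mz: float,
    mode: str | None,
    table: list[CompoundRecord],
    cfg: SearchConfig = SearchConfig(),
) -> list[CandidateMatch]:
    """Mass-window candidate search with adduct arithmetic.

    A compound is included iff some mode-compatible adduct implies a
    neutral mass within ``ppm_tolerance`` of its monoisotopic mass.
    Compounds matched via multiple adducts appear once, with all matching
    adducts listed.
    """
    adducts = cfg.adducts_for_mode(mode)
    matches: list[CandidateMatch] = []
    for compound in table:
        hit_adducts: list[str] = []
        best = float("inf")
        for adduct in adducts:
            implied = precursor_mz * abs(adduct.charge) - adduct.shift
            ppm = abs(implied - compound.monoisotopic_mass) / compound.monoisotopic_mass * 1e6
            if ppm <= cfg.ppm_tolerance:
                hit_adducts.append(adduct.name)
                best = min(best, ppm)
        if hit_adducts:
            matches.append(CandidateMatch(compound, hit_adducts, best))
    return matches


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Molecular formula -> element-count map (no parenthesized groups)."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            break
        counts[m.group(1)] = counts.get(m.group(1), 0) + (int(m.group(2)) if m.group(2) else 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"unparseable molecular formula: {formula!r}")
    return counts


def filter_by_formula(candidates: list[CandidateMatch], formula: str) -> list[CandidateMatch]:
    """Keep candidates whose element composition equals the query formula.

    Comparison is element-multiset equality, so atom ordering in the
    formula string is irrelevant.
    """
    target = parse_formula(formula)
    kept = []
    for match in candidates:
        try:
            if parse_formula(match.compound.formula) == target:
                kept.append(match)
        except ValueError:
            continue
    return kept


def _ensure_fingerprints(matches: list[CandidateMatch]) -> tuple[list[CandidateMatch], int]:
    missing = [m for m in matches if m.compound.fingerprint is None]
    usable = [m for m in matches if m.compound.fingerprint is not None]
    if missing:
        try:
            fps = compute_fingerprints([m.compound.smiles for m in missing])
        except StructureError:
            fps = None
        if fps is not None:
            for m, fp in zip(missing, fps):
                m.compound.fingerprint = fp
            usable = matches
        else:  # batch failed: compute one by one, dropping offenders
            for m in missing:
                try:
                    m.compound.fingerprint = compute_fingerprints([m.compound.smiles])[0]
                    usable.append(m)
                except StructureError:
                    warnings.warn(f"dropping candidate {m.compound.id}: unparseable SMILES", stacklevel=2)
    dropped = len(matches) - len(usable)
    return usable, dropped


def rank_candidates(
    predicted: Fingerprint,
    candidates: list[CandidateMatch],
    query_id: str | None = None,
    basis: str = "mass",
) -> RankedAnnotation:
    """Order candidates by Tanimoto score against the predicted fingerprint.

    Ties break deterministically: smaller mass error first, then
    lexicographic InChIKey.  Candidates whose fingerprint cannot be
    computed are dropped (counted in ``n_dropped``).
    """
    usable, dropped = _ensure_fingerprints(list(candidates))
    scored = [(m, tanimoto(predicted, m.compound.fingerprint)) for m in usable]
    scored.sort(key=lambda pair: (-pair[1], pair[0].ppm_error, pair[0].compound.inchikey))
    return RankedAnnotation(query_id=query_id, basis=basis, entries=scored, n_dropped=dropped)


def topk_hit(ranked: RankedAnnotation, true_inchikey: str, k: int, full_key: bool = False) -> bool:
    """Does the true compound appear in the first k entries?

    Matching is at the InChIKey first-block (2-D skeleton) level by
    default, consistent with structure-disjoint evaluation; set
    ``full_key`` for exact 27-character matching.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    want = true_inchikey if full_key else first_block(true_inchikey)
    for match, _ in ranked.entries[:k]:
        got = match.compound.inchikey if full_key else first_block(match.compound.inchikey)
        if got == want:
            return True
    return False


# --------------------------------------------------------------------------
# Compound-table I/O
# --------------------------------------------------------------------------

TABLE_COLUMNS = ("id", "inchikey", "smiles", "formula", "monoisotopic_mass")


def read_compound_table(path: str | Path) -> list[CompoundRecord]:
    """Load a candidate table from TSV/CSV; a ``fingerprint`` column of
    hex-packed bits, when present, pre-populates the cached fingerprints."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t" if path.suffix in (".tsv", ".tab") else ",", dtype=str)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"compound table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples():
        fp = None
        if hasattr(row, "fingerprint") and isinstance(row.fingerprint, str) and row.fingerprint:
            fp = Fingerprint.from_hex(row.fingerprint)
        records.append(
            CompoundRecord(
                id=row.id,
                inchikey=row.inchikey,
                smiles=row.smiles,
                formula=row.formula,
                monoisotopic_mass=float(row.monoisotopic_mass),
                fingerprint=fp,
            )
        )
    return records


def write_compound_table(records: list[CompoundRecord], path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "inchikey": [r.inchikey for r in records],
            "smiles": [r.smiles for r in records],
            "formula": [r.formula for r in records],
            "monoisotopic_mass": [f"{r.monoisotopic_mass:.6f}" for r in records],
            "fingerprint": [r.fingerprint.to_hex() if r.fingerprint else "" for r in records],
        }
    )
    df.to_csv(path, sep="\t" if path.suffix in (".tsv", ".tab") else ",", index=False)


def write_ranked_tsv(ranked: RankedAnnotation, path: str | Path) -> None:
    rows = [
        {
            "rank": i + 1,
            "id": match.compound.id,
            "inchikey": match.compound.inchikey,
            "tanimoto": f"{score:.4f}",
            "adducts": ";".join(match.adducts),
            "ppm_error": f"{match.ppm_error:.2f}",
        }
        for i, (match, score) in enumerate(ranked.entries)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
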