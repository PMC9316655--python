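"""Composite 528-bit molecular fingerprints and similarity metrics.

A compound's fingerprint is the concatenation MACCS (166 structural keys)
‖ FP3 (55 SMARTS functional-group patterns) ‖ FP4 (307 SMARTS patterns),
giving exactly 528 binary items.  MACCS keys come from RDKit, whose
167-slot output carries an unused bit 0 that is dropped; FP3 and FP4 are
computed with the OpenBabel command-line tool, whose hex dump is decoded
into the canonical 55- and 307-bit segments (backend words beyond the
pattern count are truncated).  Segment lengths are enforced regardless of
backend so the composite length is always 528.

Similarity between a predicted and a computed fingerprint uses the
Tanimoto score TP/(TP+FP+FN), which by construction ignores positions
where both vectors are zero — essential here because zeros dominate the
bit vector.  The F1 score (harmonic mean of precision TP/(TP+FP) and
recall TP/(TP+FN)) measures per-bit prediction quality.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")

MACCS_BITS = 166
FP3_BITS = 55
FP4_BITS = 307
TOTAL_BITS = MACCS_BITS + FP3_BITS + FP4_BITS  # 528
#: segment boundaries inside the composite vector
SEGMENTS = {"maccs": (0, 166), "fp3": (166, 221), "fp4": (221, 528)}


class StructureError(ValueError):
    """The structure string could not be parsed by the chemistry backend."""

    def __init__(self, structure: str, message: str = "unparseable structure"):
        super().__init__(f"{message}: {structure!r}")
        self.structure = structure


@dataclass
class Fingerprint:
    """A 528-bit binary vector, either computed from a structure or
    predicted from a spectrum."""

    bits: np.ndarray
    source: str = "computed"  # "computed" | "predicted"

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits)
        if bits.shape != (TOTAL_BITS,):
            raise ValueError(f"fingerprint must have length {TOTAL_BITS}, got {bits.shape}")
        if not np.isin(bits, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        self.bits = bits.astype(np.uint8)

    def segment(self, name: str) -> np.ndarray:
        lo, hi = SEGMENTS[name]
        return self.bits[lo:hi]

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, text: str, source: str = "computed") -> "Fingerprint":
        raw = np.frombuffer(bytes.fromhex(text), dtype=np.uint8)
        bits = np.unpackbits(raw)[:TOTAL_BITS]
        return cls(bits=bits, source=source)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Fingerprint) and bool(np.array_equal(self.bits, other.bits))


class ConfusionCounts(NamedTuple):
    TP: int
    FP: int
    FN: int
    TN: int


def _to_bits(fp: "Fingerprint | np.ndarray") -> np.ndarray:
    bits = fp.bits if isinstance(fp, Fingerprint) else np.asarray(fp)
    return bits.astype(bool)


def confusion(pred: "Fingerprint | np.ndarray", true: "Fingerprint | np.ndarray") -> ConfusionCounts:
    """Positionwise confusion counts between two equal-length bit vectors."""
    p, t = _to_bits(pred), _to_bits(true)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def tanimoto(pred, true) -> float:
    """Tanimoto similarity TP/(TP+FP+FN) in [0, 1].

    Both-zero positions contribute nothing.  Two all-zero vectors are a
    degenerate input and score 0.0 (never raises, so batch ranking cannot
    abort on an empty prediction).
    """
    tp, fp, fn, _ = confusion(pred, true)
    denom = tp + fp + fn
    return tp / denom if denom else 0.0


def f1(pred, true) -> float:
    """F1 = harmonic mean of precision TP/(TP+FP) and recall TP/(TP+FN);
    0.0 on any degenerate denominator."""
    tp, fp, fn, _ = confusion(pred, true)
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def _mol_from_structure(structure: str) -> Chem.Mol:
    if structure.startswith("InChI="):
        mol = Chem.MolFromInchi(structure)
    else:
        mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise StructureError(structure)
    return mol


def _maccs_bits(mol: Chem.Mol) -> np.ndarray:
    fp = MACCSkeys.GenMACCSKeys(mol)  # 167 slots, bit 0 unused
    arr = np.zeros(167, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr[1:]  # drop the unused slot -> 166


def _obabel_bits(smiles_list: list[str], fp_name: str, n_bits: int) -> list[np.ndarray]:
    """Batch-compute an OpenBabel pattern fingerprint for canonical SMILES.

    ``obabel -ofpt -xh`` prints each molecule's bit vector as 32-bit hex
    words, most-significant word first, LSB-first within a word; words are
    truncated to the pattern count ``n_bits``.
    """
    if shutil.which("obabel") is None:
        raise RuntimeError("obabel executable not found on PATH; FP3/FP4 need OpenBabel")
    with tempfile.TemporaryDirectory() as tmp:
        smi = Path(tmp) / "mols.smi"
        smi.write_text("".join(f"{s}\tm{i}\n" for i, s in enumerate(smiles_list)), encoding="utf-8")
        proc = subprocess.run(
            ["obabel", str(smi), "-ofpt", f"-xf{fp_name}", "-xh"],
            capture_output=True,
            text=True,
            check=False,
        )
    by_title: dict[str, np.ndarray] = {}
    title = None
    words: list[int] = []

    def flush() -> None:
        nonlocal words
        if title is not None:
            full = np.zeros(32 * len(words), dtype=np.uint8)
            for w, word in enumerate(reversed(words)):  # reversed: printed MSW first
                for b in range(32):
                    if word >> b & 1:
                        full[32 * w + b] = 1
            by_title[title] = full[:n_bits]
        words = []

    for line in proc.stdout.splitlines():
        line = line.strip()
        if line.startswith(">"):
            flush()
            rest = line[1:].split()
            title = rest[0] if rest else ""
        elif title is not None and all(len(tok) == 8 for tok in line.split()) and line:
            try:
                words.extend(int(tok, 16) for tok in line.split())
            except ValueError:
                pass
    flush()
    out: list[np.ndarray] = []
    for i, s in enumerate(smiles_list):
        bits = by_title.get(f"m{i}")
        if bits is None:
            raise StructureError(s, f"OpenBabel produced no {fp_name} fingerprint")
        if bits.shape[0] < n_bits:  # pad short backend output; policy: zero-fill
            bits = np.concatenate([bits, np.zeros(n_bits - bits.shape[0], dtype=np.uint8)])
        out.append(bits)
    return out


def compute_fingerprints(structures: Iterable[str]) -> list[Fingerprint]:
    """Compute composite fingerprints for a batch of SMILES/InChI strings.

    Structures are canonicalized through RDKit first so both backends see
    identical molecules.  Raises :class:`StructureError` on the first
    unparseable structure.
    """
    structures = list(structures)
    mols = [_mol_from_structure(s) for s in structures]
    canonical = [Chem.MolToSmiles(m) for m in mols]
    maccs = [_maccs_bits(m) for m in mols]
    fp3 = _obabel_bits(canonical, "FP3", FP3_BITS)
    fp4 = _obabel_bits(canonical, "FP4", FP4_BITS)
    return [
        Fingerprint(bits=np.concatenate([m, a, b]), source="computed")
        for m, a, b in zip(maccs, fp3, fp4)
    ]


def compute_fingerprint(structure: str) -> Fingerprint:
    """Composite 528-bit fingerprint (MACCS ‖ FP3 ‖ FP4) for one structure."""
    return compute_fingerprints([structure])[0]


def write_fingerprint_table(path, inchikeys: list[str], fps: list[Fingerprint]) -> None:
    """Persist fingerprints as hex-packed strings in a TSV next to their keys."""
    pd.DataFrame({"inchikey": inchikeys, "fingerprint": [fp.to_hex() for fp in fps]}).to_csv(
        path, sep="\t", index=False
    )


def read_fingerprint_table(path) -> dict[str, Fingerprint]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {row.inchikey: Fingerprint.from_hex(row.fingerprint) for row in df.itertuples()}
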