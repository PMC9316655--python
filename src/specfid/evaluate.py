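"""Structure-disjoint evaluation: splits, k-fold CV, and annotation scoring.

Memorization inflates accuracy when the same compound skeleton occurs on
both sides of a train/test split, so all splitting here operates at the
level of InChIKey first blocks (the 14-character 2-D-skeleton hash): no
block may span train and test.  Annotation performance is summarized by
mean per-spectrum F1 and Tanimoto of the fingerprint prediction plus
top-k ranking accuracy (k in {1, 3, 5, 10}), each reported under two
denominators — all queries, and only the queries whose candidate list
actually contains the true compound — because a compound missing from
the candidate database can never be ranked, whatever the predictor does.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .annotate import (
    CompoundRecord,
    SearchConfig,
    filter_by_formula,
    rank_candidates,
    retrieve_candidates,
    topk_hit,
)
from .fingerprints import Fingerprint, f1, tanimoto
from .preprocess import BinningSpec, PreprocessConfig, Rejection, bin_spectrum, filter_spectrum
from .spectra_io import SpectrumRecord, first_block

DEFAULT_KS = (1, 3, 5, 10)


@dataclass
class EvalReport:
    """Aggregate annotation metrics for a set of queries."""

    mean_f1: float
    mean_tanimoto: float
    topk_accuracy: dict[int, float]
    basis: str  # "mass" | "formula"
    n_queries: int
    n_excluded_true_missing: int = 0

    def __post_init__(self) -> None:
        ks = sorted(self.topk_accuracy)
        values = [self.topk_accuracy[k] for k in ks]
        if any(b < a - 1e-12 for a, b in zip(values, values[1:])):
            raise ValueError("top-k accuracy must be non-decreasing in k")

    def to_dict(self) -> dict:
        return {
            "mean_f1": self.mean_f1,
            "mean_tanimoto": self.mean_tanimoto,
            "topk_accuracy": {str(k): v for k, v in self.topk_accuracy.items()},
            "basis": self.basis,
            "n_queries": self.n_queries,
            "n_excluded_true_missing": self.n_excluded_true_missing,
        }


def write_report(reports: dict[str, EvalReport], path: str | Path) -> None:
    path = Path(path)
    path.write_text(json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=2))


def structure_disjoint_split(
    inchikeys: Sequence[str],
    train_fraction: float,
    seed: int,
) -> tuple[set[str], set[str]]:
    """Partition compounds so no InChIKey first block spans the sides.

    Blocks are shuffled with the given seed and assigned greedily to the
    training side until its share of compounds reaches ``train_fraction``.
    Returns (train keys, test keys) as sets of full InChIKeys.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    blocks: dict[str, list[str]] = {}
    for key in inchikeys:
        blocks.setdefault(first_block(key), []).append(key)
    if len(blocks) < 2:
        raise ValueError("need at least 2 distinct InChIKey first blocks to split")
    rng = np.random.default_rng(seed)
    order = list(blocks)
    rng.shuffle(order)
    total = len(inchikeys)
    train: set[str] = set()
    for block in order:
        if len(train) >= train_fraction * total:
            break
        train.update(blocks[block])
    test = set(inchikeys) - train
    if not test:  # greedy overshoot on tiny corpora: peel the last block back
        train -= set(blocks[order[0]])
        test = set(inchikeys) - train
    return train, test


def kfold_indices(inchikeys: Sequence[str], k_folds: int, seed: int) -> list[np.ndarray]:
    """Structure-disjoint fold assignment: shuffled first blocks are dealt
    round-robin to folds; returns per-fold index arrays into the input."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    blocks: dict[str, list[int]] = {}
    for i, key in enumerate(inchikeys):
        blocks.setdefault(first_block(key), []).append(i)
    if len(blocks) < k_folds:
        raise ValueError(f"only {len(blocks)} distinct first blocks for {k_folds} folds")
    rng = np.random.default_rng(seed)
    order = list(blocks)
    rng.shuffle(order)
    folds: list[list[int]] = [[] for _ in range(k_folds)]
    for j, block in enumerate(order):
        folds[j % k_folds].extend(blocks[block])
    return [np.asarray(sorted(f), dtype=int) for f in folds]


@dataclass
class FoldResult:
    fold: int
    per_spectrum_f1: list[float] = field(default_factory=list)
    per_spectrum_tanimoto: list[float] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.per_spectrum_f1)) if self.per_spectrum_f1 else 0.0

    @property
    def mean_tanimoto(self) -> float:
        return float(np.mean(self.per_spectrum_tanimoto)) if self.per_spectrum_tanimoto else 0.0


def kfold_cv(
    inchikeys: Sequence[str],
    X: np.ndarray,
    Y: np.ndarray,
    k_folds: int,
    trainer: Callable[[np.ndarray, np.ndarray], Callable[[np.ndarray], np.ndarray]],
    seed: int,
) -> tuple[list[FoldResult], FoldResult]:
    """Structure-disjoint k-fold cross-validation of fingerprint prediction.

    ``trainer(X_train, Y_train)`` must return a ``predict(X) -> bits``
    callable.  Every spectrum is validated exactly once; the pooled result
    averages per-spectrum F1/Tanimoto over all validation predictions.
    """
    X, Y = np.asarray(X), np.asarray(Y)
    folds = kfold_indices(inchikeys, k_folds, seed)
    all_idx = np.arange(len(inchikeys))
    results: list[FoldResult] = []
    pooled = FoldResult(fold=-1)
    for f, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, val_idx)
        predict = trainer(X[train_idx], Y[train_idx])
        bits = np.asarray(predict(X[val_idx]))
        result = FoldResult(fold=f)
        for row_pred, row_true in zip(bits, Y[val_idx]):
            result.per_spectrum_f1.append(f1(row_pred, row_true))
            result.per_spectrum_tanimoto.append(tanimoto(row_pred, row_true))
        results.append(result)
        pooled.per_spectrum_f1.extend(result.per_spectrum_f1)
        pooled.per_spectrum_tanimoto.extend(result.per_spectrum_tanimoto)
    return results, pooled


def evaluate_annotation(
    queries: list[tuple[SpectrumRecord, str]],
    predictor: Callable[[SpectrumRecord, np.ndarray], Fingerprint],
    db: list[CompoundRecord],
    search_cfg: SearchConfig = SearchConfig(),
    preprocess_cfg: PreprocessConfig = PreprocessConfig(),
    binning: BinningSpec = BinningSpec(),
    ks: Sequence[int] = DEFAULT_KS,
    basis: str = "mass",
    formula_of: Callable[[str], str | None] | None = None,
    true_fingerprints: dict[str, Fingerprint] | None = None,
) -> dict[str, EvalReport]:
    """Score an annotation pipeline on (spectrum, true InChIKey) queries.

    Each query is preprocessed *without merging* (evaluation judges
    individual spectra), binned, passed to ``predictor`` for a fingerprint,
    matched against the database by precursor mass (and, when
    ``basis="formula"``, filtered to the true compound's formula via
    ``formula_of(inchikey)``), and ranked by Tanimoto.

    Returns two report variants: ``"all"`` uses every query as the
    denominator; ``"true_present"`` excludes queries whose candidate list
    does not contain the true compound.  Mean F1/Tanimoto of the
    fingerprint prediction itself are computed where ``true_fingerprints``
    provides the ground truth.
    """
    hits_all: dict[int, list[bool]] = {k: [] for k in ks}
    hits_present: dict[int, list[bool]] = {k: [] for k in ks}
    f1s: list[float] = []
    tanimotos: list[float] = []
    n_queries = 0
    n_missing = 0
    for record, true_key in queries:
        filtered = filter_spectrum(record, preprocess_cfg)
        if isinstance(filtered, Rejection):
            continue
        n_queries += 1
        values = bin_spectrum(filtered.peaks, binning).values
        predicted = predictor(filtered, values)
        if true_fingerprints and true_key in true_fingerprints:
            truth = true_fingerprints[true_key]
            f1s.append(f1(predicted, truth))
            tanimotos.append(tanimoto(predicted, truth))
        candidates = retrieve_candidates(record.precursor_mz, record.ionization_mode, db, search_cfg)
        if basis == "formula":
            formula = formula_of(true_key) if formula_of else None
            if formula:
                candidates = filter_by_formula(candidates, formula)
        ranked = rank_candidates(predicted, candidates, query_id=record.spectrum_id, basis=basis)
        true_in_list = any(
            first_block(m.compound.inchikey) == first_block(true_key) for m, _ in ranked.entries
        )
        if not true_in_list:
            n_missing += 1
        for k in ks:
            hit = topk_hit(ranked, true_key, k)
            hits_all[k].append(hit)
            if true_in_list:
                hits_present[k].append(hit)
    mean_f1 = float(np.mean(f1s)) if f1s else 0.0
    mean_tan = float(np.mean(tanimotos)) if tanimotos else 0.0

    def make(hits: dict[int, list[bool]], n: int, excluded: int) -> EvalReport:
        return EvalReport(
            mean_f1=mean_f1,
            mean_tanimoto=mean_tan,
            topk_accuracy={k: (float(np.mean(v)) if v else 0.0) for k, v in hits.items()},
            basis=basis,
            n_queries=n,
            n_excluded_true_missing=excluded,
        )

    return {
        "all": make(hits_all, n_queries, 0),
        "true_present": make(hits_present, n_queries - n_missing, n_missing),
    }


@dataclass(frozen=True)
class ReferenceCorpus:
    """Accounting of the large public training resource the pipeline is
    designed for: per-library LC-MS/MS spectrum counts by ionization mode
    (MoNA repository and the NIST 20 library) and the structure-disjoint
    compound split used for training versus independent testing."""

    mona_positive: int = 79_404
    mona_negative: int = 32_269
    nist20_positive: int = 401_985
    nist20_negative: int = 136_895
    train_compounds: int = 29_588
    test_compounds: int = 6_290

    @property
    def total_spectra(self) -> int:
        return self.mona_positive + self.mona_negative + self.nist20_positive + self.nist20_negative

    @property
    def total_compounds(self) -> int:
        return self.train_compounds + self.test_compounds

    @property
    def positive_spectra(self) -> int:
        return self.mona_positive + self.nist20_positive

    @property
    def negative_spectra(self) -> int:
        return self.mona_negative + self.nist20_negative

    @property
    def train_fraction(self) -> float:
        return self.train_compounds / self.total_compounds


def report_table(reports: dict[str, EvalReport]) -> pd.DataFrame:
    """Flatten report variants into a tidy frame (one row per variant)."""
    rows = []
    for name, rep in reports.items():
        row = {
            "variant": name,
            "basis": rep.basis,
            "n_queries": rep.n_queries,
            "n_excluded_true_missing": rep.n_excluded_true_missing,
            "mean_f1": rep.mean_f1,
            "mean_tanimoto": rep.mean_tanimoto,
        }
        for k, v in sorted(rep.topk_accuracy.items()):
            row[f"top{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
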