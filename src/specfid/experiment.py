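"""The standard desk-scale benchmark experiment, end to end.

Bundles corpus generation, preprocessing, CNN training, baseline
comparison, and annotation scoring into one reproducible function so the
same experiment backs both the test suite and the reproduction script.

The network runs at desk scale: reduced filter counts and a slimmer
dense head than the full-scale defaults, trained for 25 epochs on
~1,200 spectra.  These sizes are the package's standard
miniature-experiment settings; every knob remains overridable through
``CnnConfig``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import rank_candidates, retrieve_candidates, topk_hit
from .evaluate import evaluate_annotation
from .fingerprints import Fingerprint, f1, tanimoto
from .models import CnnConfig, TrainingItem, fit_strategy
from .preprocess import BinningSpec, preprocess_corpus
from .synthetic import Benchmark, make_benchmark

#: reduced network for desk-scale runs (one CPU, minutes not days)
DESK_CNN = dict(
    conv_filters=(16, 32),
    conv_kernels=(5, 5),
    pool_sizes=(2, 2),
    dense_sizes=(256, 128, 128, 528),
    dropout_rate=0.5,
    epochs=25,
    batch_size=16,
    learning_rate=3e-3,
)


@dataclass
class ExperimentResult:
    """Everything the benchmark experiment measures."""

    benchmark: Benchmark
    mean_test_tanimoto: float
    mean_test_f1: float
    baseline_allzeros_tanimoto: float
    baseline_prevalence_tanimoto: float
    top1_mass: float
    random_top1_expectation: float
    mean_candidates: float
    oracle_topk_mass: dict[int, float] = field(default_factory=dict)
    oracle_topk_formula: dict[int, float] = field(default_factory=dict)
    reports: dict = field(default_factory=dict)
    n_test_queries: int = 0


def run_benchmark_experiment(
    seed: int,
    n_compounds: int = 300,
    spectra_per_compound: int = 5,
    strategy: str = "single",
    cnn_overrides: dict | None = None,
) -> ExperimentResult:
    """Train the CNN on the planted benchmark and score annotation.

    Measures (all on the structure-disjoint test spectra):

    - mean Tanimoto/F1 of the CNN's predicted fingerprints against truth,
      next to two trivial predictors: all-zeros and per-bit-prevalence
      (bit set iff its training prevalence exceeds 1/2);
    - mass-based top-1 ranking accuracy against the random-choice
      expectation ``mean(1/|candidate list|)``;
    - top-k curves for the oracle predictor (predicted := true
      fingerprint) under mass-based and formula-based retrieval;
    - the dual-denominator annotation reports for the CNN predictor.
    """
    binning = BinningSpec()
    bench = make_benchmark(seed, n_compounds=n_compounds, spectra_per_compound=spectra_per_compound, binning=binning)
    fps = bench.fingerprints_by_key
    cfg = CnnConfig(seed=seed, **{**DESK_CNN, **(cnn_overrides or {})})

    train_corpus = preprocess_corpus(bench.train_records, binning=binning, merge=False)
    items = [
        TrainingItem(record=rec, values=row, bits=fps[rec.inchikey].bits)
        for rec, row in zip(train_corpus.records, train_corpus.matrix)
    ]
    bundle = fit_strategy(items, strategy, cfg)

    test_corpus = preprocess_corpus(bench.test_records, binning=binning, merge=False)
    Y_test = np.vstack([fps[k].bits for k in test_corpus.inchikeys])
    prevalence_bits = (
        np.vstack([it.bits for it in items]).mean(axis=0) > 0.5
    ).astype(np.uint8)

    cnn_tans, cnn_f1s, zeros_tans, prev_tans = [], [], [], []
    top1_hits, inv_list_lengths, list_lengths = [], [], []
    zero_fp = np.zeros(Y_test.shape[1], dtype=np.uint8)
    for rec, values, truth in zip(test_corpus.records, test_corpus.matrix, Y_test):
        _, fp = bundle.predict(rec, values)
        cnn_tans.append(tanimoto(fp.bits, truth))
        cnn_f1s.append(f1(fp.bits, truth))
        zeros_tans.append(tanimoto(zero_fp, truth))
        prev_tans.append(tanimoto(prevalence_bits, truth))
        candidates = retrieve_candidates(rec.precursor_mz, rec.ionization_mode, bench.compounds)
        if candidates:
            inv_list_lengths.append(1.0 / len(candidates))
            list_lengths.append(len(candidates))
        ranked = rank_candidates(fp, candidates, query_id=rec.spectrum_id)
        top1_hits.append(topk_hit(ranked, rec.inchikey, 1))

    queries = [(rec, bench.truth[rec.spectrum_id]) for rec in bench.test_records]
    formulas = {c.inchikey: c.formula for c in bench.compounds}
    oracle = lambda rec, values: fps[rec.inchikey]  # noqa: E731
    oracle_mass = evaluate_annotation(queries, oracle, bench.compounds, binning=binning, true_fingerprints=fps)
    oracle_formula = evaluate_annotation(
        queries, oracle, bench.compounds, binning=binning,
        basis="formula", formula_of=formulas.get, true_fingerprints=fps,
    )
    cnn_reports = evaluate_annotation(
        queries,
        lambda rec, values: bundle.predict(rec, values)[1],
        bench.compounds,
        binning=binning,
        true_fingerprints=fps,
    )
    return ExperimentResult(
        benchmark=bench,
        mean_test_tanimoto=float(np.mean(cnn_tans)),
        mean_test_f1=float(np.mean(cnn_f1s)),
        baseline_allzeros_tanimoto=float(np.mean(zeros_tans)),
        baseline_prevalence_tanimoto=float(np.mean(prev_tans)),
        top1_mass=float(np.mean(top1_hits)),
        random_top1_expectation=float(np.mean(inv_list_lengths)) if inv_list_lengths else 0.0,
        mean_candidates=float(np.mean(list_lengths)) if list_lengths else 0.0,
        oracle_topk_mass=oracle_mass["all"].topk_accuracy,
        oracle_topk_formula=oracle_formula["all"].topk_accuracy,
        reports=cnn_reports,
        n_test_queries=len(queries),
    )
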