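"""Structure-disjoint splitting, k-fold CV, and annotation scoring."""

import numpy as np
import pytest

from specfid.evaluate import (
    EvalReport,
    ReferenceCorpus,
    evaluate_annotation,
    kfold_cv,
    kfold_indices,
    structure_disjoint_split,
)
from specfid.fingerprints import TOTAL_BITS, Fingerprint
from specfid.spectra_io import first_block
from specfid.synthetic import generate_compound_table, generate_spectra, make_mapping


def keys(n, rng, shared_pairs=0):
    table = generate_compound_table(n, seed=int(rng.integers(2**31)), shared_block_groups=shared_pairs)
    return [c.inchikey for c in table]


class TestStructureDisjointSplit:
    def test_shared_block_stays_together(self, rng):
        ks = keys(10, rng, shared_pairs=1)
        blocks = [first_block(k) for k in ks]
        shared = [k for k in ks if blocks.count(first_block(k)) > 1]
        assert len(shared) == 2
        train, test = structure_disjoint_split(ks, 0.8, seed=0)
        assert {k in train for k in shared} in ({True}, {False})

    def test_no_block_spans_sides(self, rng):
        ks = keys(60, rng, shared_pairs=10)
        train, test = structure_disjoint_split(ks, 0.7, seed=5)
        assert {first_block(k) for k in train}.isdisjoint({first_block(k) for k in test})
        assert train | test == set(ks)

    def test_deterministic_for_seed(self, rng):
        ks = keys(40, rng)
        assert structure_disjoint_split(ks, 0.8, seed=9) == structure_disjoint_split(ks, 0.8, seed=9)
        assert structure_disjoint_split(ks, 0.8, seed=9) != structure_disjoint_split(ks, 0.8, seed=10)

    def test_realized_fraction_within_tolerance(self, rng):
        ks = keys(100, rng)
        for seed in range(20):
            train, _ = structure_disjoint_split(ks, 0.8, seed=seed)
            assert 0.7 <= len(train) / len(ks) <= 0.9

    def test_single_block_errors(self):
        ks = ["AAAAAAAAAAAAAA-BBBBBBBBBB-N", "AAAAAAAAAAAAAA-CCCCCCCCCC-N"]
        with pytest.raises(ValueError):
            structure_disjoint_split(ks, 0.5, seed=0)


class TestKFold:
    def test_every_compound_validated_exactly_once(self, rng):
        ks = keys(50, rng)
        folds = kfold_indices(ks, 5, seed=1)
        covered = np.concatenate(folds)
        assert sorted(covered) == list(range(50))

    def test_folds_structure_disjoint(self, rng):
        ks = keys(30, rng, shared_pairs=5)
        folds = kfold_indices(ks, 3, seed=2)
        blocks_per_fold = [{first_block(ks[i]) for i in fold} for fold in folds]
        for a in range(3):
            for b in range(a + 1, 3):
                assert blocks_per_fold[a].isdisjoint(blocks_per_fold[b])

    def test_two_blocks_two_folds(self):
        ks = ["AAAAAAAAAAAAAA-XXXXXXXXXX-N", "BBBBBBBBBBBBBB-YYYYYYYYYY-N"]
        folds = kfold_indices(ks, 2, seed=0)
        assert sorted(len(f) for f in folds) == [1, 1]

    def test_deterministic(self, rng):
        ks = keys(25, rng)
        a = kfold_indices(ks, 5, seed=3)
        b = kfold_indices(ks, 5, seed=3)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_too_few_blocks_errors(self):
        ks = ["AAAAAAAAAAAAAA-XXXXXXXXXX-N", "BBBBBBBBBBBBBB-YYYYYYYYYY-N"]
        with pytest.raises(ValueError):
            kfold_indices(ks, 3, seed=0)

    def test_cv_runs_a_trainer_per_fold(self, rng):
        """kfold_cv validates every spectrum once with a trivial trainer."""
        ks = keys(20, rng)
        X = rng.uniform(0, 1, (20, 10))
        Y = (rng.random((20, TOTAL_BITS)) < 0.1).astype(float)
        calls = []

        def trainer(Xtr, Ytr):
            calls.append(len(Xtr))
            return lambda Xv: np.zeros((len(Xv), TOTAL_BITS))

        per_fold, pooled = kfold_cv(ks, X, Y, 4, trainer, seed=0)
        assert len(per_fold) == 4 and len(calls) == 4
        assert len(pooled.per_spectrum_f1) == 20


def oracle_setup(rng, n=12, drop_truth_for=0):
    """Queries + db where the predictor is the oracle (true fingerprint)."""
    compounds = generate_compound_table(n, seed=7, mass_range=(500.0, 1000.0))
    mapping = make_mapping(seed=8)
    records = generate_spectra(compounds, mapping, seed=9)
    fps = {c.inchikey: c.fingerprint for c in compounds}
    queries = [(r, r.inchikey) for r in records]
    db = compounds[drop_truth_for:]  # drop first k compounds from the db
    dropped = {c.inchikey for c in compounds[:drop_truth_for]}
    return queries, db, fps, dropped


class TestEvaluateAnnotation:
    def predictor(self, fps):
        return lambda rec, values: fps[rec.inchikey]

    def test_variants_coincide_when_truth_always_present(self, rng):
        queries, db, fps, _ = oracle_setup(rng)
        reports = evaluate_annotation(queries, self.predictor(fps), db, true_fingerprints=fps)
        assert reports["all"].topk_accuracy == reports["true_present"].topk_accuracy
        assert reports["all"].n_excluded_true_missing == 0

    def test_denominator_bookkeeping_when_truth_missing(self, rng):
        queries, db, fps, dropped = oracle_setup(rng, n=10, drop_truth_for=2)
        reports = evaluate_annotation(queries, self.predictor(fps), db, true_fingerprints=fps)
        n = reports["all"].n_queries
        assert reports["true_present"].n_queries == n - reports["true_present"].n_excluded_true_missing
        assert reports["true_present"].n_excluded_true_missing >= 2
        # excluded-denominator percentages dominate the all-queries ones
        for k in reports["all"].topk_accuracy:
            assert reports["true_present"].topk_accuracy[k] >= reports["all"].topk_accuracy[k]

    def test_oracle_predictor_perfect_fingerprint_metrics(self, rng):
        queries, db, fps, _ = oracle_setup(rng)
        reports = evaluate_annotation(queries, self.predictor(fps), db, true_fingerprints=fps)
        assert reports["all"].mean_f1 == 1.0
        assert reports["all"].mean_tanimoto == 1.0

    def test_formula_basis_at_least_as_good_with_oracle(self, rng):
        queries, db, fps, _ = oracle_setup(rng, n=20)
        formulas = {c.inchikey: c.formula for c in db}
        mass_rep = evaluate_annotation(queries, self.predictor(fps), db, true_fingerprints=fps)
        formula_rep = evaluate_annotation(
            queries,
            self.predictor(fps),
            db,
            basis="formula",
            formula_of=formulas.get,
            true_fingerprints=fps,
        )
        for k in mass_rep["all"].topk_accuracy:
            assert formula_rep["all"].topk_accuracy[k] >= mass_rep["all"].topk_accuracy[k]


class TestEvalReport:
    def test_topk_monotonicity_enforced(self):
        with pytest.raises(ValueError):
            EvalReport(
                mean_f1=0.5,
                mean_tanimoto=0.5,
                topk_accuracy={1: 0.9, 3: 0.5},
                basis="mass",
                n_queries=10,
            )


class TestReferenceCorpus:
    def test_printed_count_arithmetic(self):
        ref = ReferenceCorpus()
        assert ref.total_spectra == ref.positive_spectra + ref.negative_spectra == 650_553
        assert ref.total_compounds == 35_878
        assert 0.80 <= ref.train_fraction <= 0.85
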