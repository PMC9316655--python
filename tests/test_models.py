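"""Model layer: context resolution, CNN architecture, training sanity,
baselines, and strategy routing."""

import warnings

import numpy as np
import pytest

from specfid.fingerprints import TOTAL_BITS
from specfid.models import (
    CnnConfig,
    InstrumentContext,
    ModelBundle,
    TrainingItem,
    build_baseline,
    build_cnn,
    fit_strategy,
    predict_fingerprint,
    quantize_for_embedding,
    resolve_context,
    train,
)
from specfid.spectra_io import Peak, SpectrumRecord


def record(mode="positive", ce=None, itype="Orbitrap", key="AAAAAAAAAAAAAA-AAAAAAAAAA-N"):
    return SpectrumRecord(
        peaks=[Peak(50.0, 100.0)],
        ionization_mode=mode,
        collision_energy_ev=ce,
        instrument_type=itype,
        inchikey=key,
        spectrum_id="r",
    )


SMALL = CnnConfig(
    input_length=64,
    conv_filters=(4, 8),
    conv_kernels=(3, 3),
    pool_sizes=(2, 2),
    dense_sizes=(32, 32, 32, 32),
    epochs=2,
    batch_size=8,
    seed=0,
)


class TestResolveContext:
    def test_high_energy_orbitrap_positive(self):
        ctx = resolve_context(record(ce=35.0, itype="Orbitrap"))
        assert (ctx.energy, ctx.resolution, ctx.mode) == ("high", "high", "positive")

    @pytest.mark.parametrize(("ce", "expected"), [(29.9, "low"), (30.0, "high")])
    def test_strict_30ev_boundary(self, ce, expected):
        assert resolve_context(record(ce=ce)).energy == expected

    @pytest.mark.parametrize(
        ("itype", "expected"),
        [("Orbitrap", "high"), ("Q-TOF", "high"), ("QqQ", "low"), ("IT", "low"), ("Ion Trap", "low")],
    )
    def test_resolution_map(self, itype, expected):
        assert resolve_context(record(itype=itype)).resolution == expected

    def test_absent_energy_takes_default_with_flag(self):
        ctx = resolve_context(record(ce=None), default_energy="low")
        assert ctx.energy == "low" and ctx.energy_defaulted

    def test_missing_mode_errors(self):
        with pytest.raises(ValueError):
            resolve_context(record(mode=None))

    def test_routing_total_over_all_cells(self):
        """Every metadata combination lands in exactly one of 8 cells."""
        seen = set()
        for ce in (10.0, 45.0):
            for itype in ("Orbitrap", "QqQ"):
                for mode in ("positive", "negative"):
                    ctx = resolve_context(record(mode=mode, ce=ce, itype=itype))
                    assert 0 <= ctx.index <= 7
                    seen.add(ctx.index)
        assert seen == set(range(8))


class TestBuildCnn:
    def test_twelve_layer_sequence(self):
        model = build_cnn(SMALL)
        assert model.layer_names == [
            "embedding",
            "conv1d",
            "maxpool1d",
            "conv1d",
            "maxpool1d",
            "dropout",
            "flatten",
            "dense",
            "dense",
            "dense",
            "dense",
            "dense",
        ]
        assert len(model.layers) == 12

    def test_output_width_and_sigmoid_range(self):
        model = build_cnn(SMALL)
        X = np.zeros((4, 64), dtype=int)
        out = model.forward(X)
        assert out.shape == (4, TOTAL_BITS)
        assert np.all((out > 0) & (out < 1))

    def test_same_seed_identical_initial_weights(self):
        a, b = build_cnn(SMALL), build_cnn(SMALL)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa, pb)

    def test_inconsistent_config_rejected(self):
        bad = CnnConfig(
            input_length=8,
            conv_kernels=(5, 5),
            pool_sizes=(4, 4),
            conv_filters=(4, 8),
            dense_sizes=(8, 8, 8, 8),
        )
        with pytest.raises(ValueError):
            build_cnn(bad)

    def test_raw_intensity_mode_swaps_front_end(self):
        model = build_cnn(CnnConfig(
            input_length=64, conv_filters=(4, 8), conv_kernels=(3, 3), pool_sizes=(2, 2),
            dense_sizes=(32, 32, 32, 32), use_embedding=False,
        ))
        assert model.layer_names[0] == "raw_channel"
        out = model.forward(np.random.default_rng(0).uniform(0, 100, (2, 64)))
        assert out.shape == (2, TOTAL_BITS)


class TestQuantize:
    def test_rounding_rule(self):
        assert list(quantize_for_embedding(np.array([0.0, 2.4, 99.6]), 101)) == [0, 2, 100]

    def test_zeros_stay_zero_and_boundary(self):
        assert list(quantize_for_embedding(np.array([0.0, 100.0]), 101)) == [0, 100]


def planted_task(n=200, length=TOTAL_BITS, prevalence=0.2, seed=0):
    """Noiseless separable mapping: bit j excited by bin j (injective).

    With ``length < 528`` only the first ``length`` bits are ever set;
    the rest are constant zero (still separable)."""
    rng = np.random.default_rng(seed)
    Y = np.zeros((n, TOTAL_BITS))
    Y[:, :length] = (rng.random((n, length)) < prevalence).astype(float)
    X = np.where(Y[:, :length] > 0, 100.0, 0.0)
    return X, Y


class TestTraining:
    def test_separable_task_reaches_high_accuracy(self):
        """On a planted noiseless mapping, 30 epochs exceed 0.95 training
        binary accuracy."""
        X, Y = planted_task()
        # all-zeros predictor would sit at 1 - 0.2 = 0.80 accuracy
        cfg = CnnConfig(
            input_length=TOTAL_BITS, conv_filters=(8, 16), conv_kernels=(3, 3), pool_sizes=(2, 2),
            dense_sizes=(256, 128, 128, 528), dropout_rate=0.2, epochs=30, batch_size=16,
            learning_rate=3e-3, seed=1,
        )
        model = build_cnn(cfg)
        _, log = train(model, X, Y, cfg)
        assert log[-1]["binary_accuracy"] > 0.95

    def test_constant_zero_targets_converge_to_zero_bits(self):
        X, _ = planted_task(n=40, length=64)
        Y = np.zeros((40, TOTAL_BITS))
        cfg = CnnConfig(
            input_length=64, conv_filters=(4, 8), conv_kernels=(3, 3), pool_sizes=(2, 2),
            dense_sizes=(16, 16, 16, 16), epochs=20, batch_size=8, learning_rate=1e-2, seed=0,
        )
        model = build_cnn(cfg)
        train(model, X, Y, cfg)
        _, fp = predict_fingerprint(model, X[0], cfg)
        assert fp.bits.sum() == 0

    def test_identical_runs_identical_logs(self):
        X, Y = planted_task(n=40, length=64)
        logs = []
        for _ in range(2):
            cfg = CnnConfig(
                input_length=64, conv_filters=(4, 8), conv_kernels=(3, 3), pool_sizes=(2, 2),
                dense_sizes=(16, 16, 16, 16), epochs=3, batch_size=8, seed=7,
            )
            model = build_cnn(cfg)
            _, log = train(model, X, Y, cfg)
            logs.append(log)
        assert logs[0] == logs[1]


class TestPredict:
    def test_threshold_boundary_convention(self):
        probs = np.array([0.49, 0.5, 0.51])
        bits = (probs >= 0.5).astype(int)
        assert list(bits) == [0, 1, 1]

    def test_impossible_threshold_gives_all_zero(self):
        X, Y = planted_task(n=20, length=64)
        cfg = CnnConfig(
            input_length=64, conv_filters=(4, 8), conv_kernels=(3, 3), pool_sizes=(2, 2),
            dense_sizes=(16, 16, 16, 16), epochs=1, batch_size=8, seed=0,
        )
        model = build_cnn(cfg)
        train(model, X, Y, cfg)
        _, fp = predict_fingerprint(model, X[0], cfg, threshold=1.01)
        assert fp.bits.sum() == 0

    def test_length_mismatch_rejected(self):
        model = build_cnn(SMALL)
        with pytest.raises(ValueError):
            predict_fingerprint(model, np.zeros(65), SMALL)


class TestBaselines:
    def test_slp_parameter_count(self):
        slp = build_baseline("SLP").build(10)
        assert slp.n_parameters == (10 + 1) * TOTAL_BITS

    def test_lr_and_slp_learn_separable_toy_task(self):
        from specfid.fingerprints import f1 as f1_score

        X, Y = planted_task(n=150, length=64, prevalence=0.3, seed=3)
        for kind in ("LR", "SLP"):
            model = build_baseline(kind, seed=0)
            if kind == "SLP":
                model.epochs = 200
            model.fit(X, Y)
            bits = model.predict_bits(X)
            scores = [f1_score(p, t) for p, t in zip(bits, Y) if t.any()]
            assert np.mean(scores) > 0.95, kind

    def test_svm_constant_label_column_predicted_constant(self):
        X = np.random.default_rng(0).uniform(0, 1, (30, 5))
        Y = np.zeros((30, TOTAL_BITS))
        Y[:, 3] = 1.0
        svm = build_baseline("SVM").fit(X, Y)
        bits = svm.predict_bits(X)
        assert np.all(bits[:, 3] == 1) and np.all(bits[:, 0] == 0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            build_baseline("RandomForest")


def make_items(contexts, n_keys=4, length=32, seed=0):
    """Training items covering the requested context cells."""
    rng = np.random.default_rng(seed)
    items = []
    heads = ["".join(rng.choice(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"), 14)) for _ in range(n_keys)]
    for cell in contexts:
        e, r, m = (cell >> 2) & 1, (cell >> 1) & 1, cell & 1
        for key_i in range(n_keys):
            rec = record(
                mode="positive" if m else "negative",
                ce=45.0 if e else 10.0,
                itype="Orbitrap" if r else "QqQ",
                key=f"{heads[key_i]}-AAAAAAAAAA-N",
            )
            items.append(
                TrainingItem(
                    record=rec,
                    values=rng.uniform(0, 100, length),
                    bits=(rng.random(TOTAL_BITS) < 0.05).astype(np.uint8),
                )
            )
    return items


TINY = CnnConfig(
    input_length=32, conv_filters=(2, 4), conv_kernels=(3, 3), pool_sizes=(2, 2),
    dense_sizes=(8, 8, 8, 8), epochs=1, batch_size=8, seed=0,
)


class TestStrategies:
    def test_eight_members_when_all_cells_populated(self):
        items = make_items(range(8), n_keys=3)
        bundle = fit_strategy(items, "eight", TINY, min_cell_compounds=2)
        assert len(bundle.members) == 8

    def test_positive_only_corpus_yields_at_most_four_with_warnings(self):
        items = make_items([1, 3, 5, 7], n_keys=3)  # positive-mode cells only
        bundle = fit_strategy(items, "eight", TINY, min_cell_compounds=2)
        assert set(bundle.members) <= {"1", "3", "5", "7"}
        # prediction for an absent (negative-mode) cell falls back, preferring
        # matching resolution and energy among populated cells
        rec = record(mode="negative", ce=45.0, itype="Orbitrap")
        probs, fp = bundle.predict(rec, items[0].values)
        assert fp.bits.shape == (TOTAL_BITS,)

    def test_sparse_cell_skipped_with_warning(self):
        items = make_items([0], n_keys=1)
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                fit_strategy(items, "eight", TINY, min_cell_compounds=2)

    def test_context_strategy_widens_input_by_three(self):
        items = make_items([0, 7], n_keys=2)
        bundle = fit_strategy(items, "single_with_context", TINY)
        assert bundle.config.input_length == 32 + 3
        probs, fp = bundle.predict(items[0].record, items[0].values)
        assert fp.bits.shape == (TOTAL_BITS,)

    def test_single_strategy_one_member(self):
        items = make_items([0, 7], n_keys=2)
        bundle = fit_strategy(items, "single", TINY)
        assert set(bundle.members) == {"all"}

    def test_bundle_save_load_round_trip(self, tmp_path):
        items = make_items([0, 7], n_keys=2)
        bundle = fit_strategy(items, "single", TINY)
        bundle.save(tmp_path / "model")
        loaded = ModelBundle.load(tmp_path / "model")
        rec, values = items[0].record, items[0].values
        p1, _ = bundle.predict(rec, values)
        p2, _ = loaded.predict(rec, values)
        assert np.allclose(p1, p2)
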