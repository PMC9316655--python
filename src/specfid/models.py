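"""Fingerprint predictors: the 1-D CNN, flat baselines, and model routing.

The predictor maps a binned MS/MS intensity vector to 528 independent
bit probabilities (multi-label classification with sigmoid outputs and
binary cross-entropy).  The convolutional architecture is, in order:
embedding, two convolution/max-pooling stages, dropout, flatten, four
ReLU dense layers, and a 528-unit sigmoid output — twelve layers in the
stack, counting the output layer.  All entries of the fingerprint are
predicted simultaneously by one network.

The embedding front-end consumes integer tokens, so scaled intensities
(0..100) are quantized to a 101-symbol vocabulary first
(:func:`quantize_for_embedding`).  An alternative mode feeds raw
intensities as a single channel with no embedding
(``CnnConfig.use_embedding = False``); both interpretations are kept
because the choice materially shapes the network's first layer.

Three deployment strategies exist: a single model on plain bins; a
single model whose input is extended by three binary instrument-context
entries (collision-energy regime, resolution, ionization mode); and
eight models, one per context cell, with routing at prediction time.
The context derives from spectrum metadata: energy is low below 30 eV
and high at or above it; Orbitrap and Q-TOF count as high resolution,
ion trap and QqQ as low.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC

from . import nn
from .fingerprints import TOTAL_BITS, Fingerprint
from .preprocess import BinnedSpectrum, normalize_instrument_type
from .spectra_io import SpectrumRecord, first_block

ENERGY_SPLIT_EV = 30.0

RESOLUTION_BY_INSTRUMENT = {
    "Orbitrap": "high",
    "Q-TOF": "high",
    "IT": "low",
    "QqQ": "low",
}


@dataclass(frozen=True)
class InstrumentContext:
    """One of the 8 instrument-method cells: (energy, resolution, mode)."""

    energy: str  # "low" | "high"
    resolution: str  # "low" | "high"
    mode: str  # "positive" | "negative"
    energy_defaulted: bool = field(default=False, compare=False)
    resolution_defaulted: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.energy not in ("low", "high"):
            raise ValueError(f"energy must be low/high, got {self.energy!r}")
        if self.resolution not in ("low", "high"):
            raise ValueError(f"resolution must be low/high, got {self.resolution!r}")
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"mode must be positive/negative, got {self.mode!r}")

    def as_bits(self) -> tuple[int, int, int]:
        """Binary encoding in the fixed order (energy, resolution, mode)."""
        return (
            int(self.energy == "high"),
            int(self.resolution == "high"),
            int(self.mode == "positive"),
        )

    @property
    def index(self) -> int:
        e, r, m = self.as_bits()
        return 4 * e + 2 * r + m

    @property
    def key(self) -> str:
        return f"{self.energy}E_{self.resolution}R_{self.mode}"


def resolve_context(
    record: SpectrumRecord,
    default_energy: str = "low",
    default_resolution: str = "high",
) -> InstrumentContext:
    """Derive the instrument context of a spectrum from its metadata.

    Energy splits at 30 eV (strictly below -> low); records without a
    parseable collision energy take ``default_energy`` and are flagged.
    Resolution comes from the instrument-type lookup; unknown types take
    ``default_resolution`` and are flagged.  A missing ionization mode is
    an error — polarity cannot be defaulted meaningfully.
    """
    if record.ionization_mode is None:
        raise ValueError(f"record {record.spectrum_id!r} has no ionization mode")
    if record.collision_energy_ev is None:
        energy, e_flag = default_energy, True
    else:
        energy, e_flag = ("high" if record.collision_energy_ev >= ENERGY_SPLIT_EV else "low"), False
    itype = normalize_instrument_type(record.instrument_type)
    resolution = RESOLUTION_BY_INSTRUMENT.get(itype) if itype else None
    r_flag = resolution is None
    if resolution is None:
        resolution = default_resolution
    return InstrumentContext(
        energy=energy,
        resolution=resolution,
        mode=record.ionization_mode,
        energy_defaulted=e_flag,
        resolution_defaulted=r_flag,
    )


@dataclass(frozen=True)
class CnnConfig:
    """Hyperparameters of the convolutional predictor.

    ``input_length`` is the bin count (1174) or bin count + 3 when the
    context entries are appended.  Defaults not fixed by the architecture
    description (filter counts, kernel widths, pool sizes, dense widths,
    epochs, batch size) are documented package choices, all overridable.
    """

    input_length: int = 1174
    embedding_vocab: int = 101
    embedding_dim: int = 32
    conv_filters: tuple[int, int] = (32, 64)
    conv_kernels: tuple[int, int] = (5, 5)
    pool_sizes: tuple[int, int] = (2, 2)
    dropout_rate: float = 0.5
    dense_sizes: tuple[int, int, int, int] = (1024, 512, 512, 528)
    output_size: int = TOTAL_BITS
    optimizer: str = "adam"
    loss: str = "binary_crossentropy"
    metric: str = "binary_accuracy"
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    use_embedding: bool = True
    scale_max: float = 100.0

    def __post_init__(self) -> None:
        if self.output_size != TOTAL_BITS:
            raise ValueError(f"output_size must be {TOTAL_BITS}")
        if len(self.conv_filters) != 2 or len(self.conv_kernels) != 2 or len(self.pool_sizes) != 2:
            raise ValueError("exactly two convolution and two pooling stages are required")
        if len(self.dense_sizes) != 4:
            raise ValueError("exactly four dense hidden layers are required")

    def flatten_length(self) -> int:
        length = self.input_length
        for kernel, pool in zip(self.conv_kernels, self.pool_sizes):
            length = length - kernel + 1
            if length < 1:
                raise ValueError("kernel larger than remaining sequence")
            length //= pool
            if length < 1:
                raise ValueError("pool larger than remaining sequence")
        return length * self.conv_filters[1]


class _RawChannel(nn.Layer):
    """(B, L) intensities -> (B, L, 1) channel, scaled to [0, 1]."""

    name = "raw_channel"

    def __init__(self, scale_max: float):
        self.scale_max = scale_max

    def forward(self, x, training, rng):
        return (x / self.scale_max)[..., None]

    def backward(self, grad):
        return grad[..., 0] / self.scale_max


def build_cnn(cfg: CnnConfig) -> nn.Sequential:
    """Assemble the 12-layer convolutional stack from a config.

    Same seed, same config -> bit-identical initial weights.
    """
    cfg.flatten_length()  # validates kernel/pool consistency early
    rng = np.random.default_rng(cfg.seed)
    layers: list[nn.Layer] = []
    if cfg.use_embedding:
        layers.append(nn.Embedding(cfg.embedding_vocab, cfg.embedding_dim, rng))
        channels = cfg.embedding_dim
    else:
        layers.append(_RawChannel(cfg.scale_max))
        channels = 1
    layers.append(nn.Conv1D(channels, cfg.conv_filters[0], cfg.conv_kernels[0], rng))
    layers.append(nn.MaxPool1D(cfg.pool_sizes[0]))
    layers.append(nn.Conv1D(cfg.conv_filters[0], cfg.conv_filters[1], cfg.conv_kernels[1], rng))
    layers.append(nn.MaxPool1D(cfg.pool_sizes[1]))
    layers.append(nn.Dropout(cfg.dropout_rate))
    layers.append(nn.Flatten())
    n_in = cfg.flatten_length()
    for width in cfg.dense_sizes:
        layers.append(nn.Dense(n_in, width, "relu", rng))
        n_in = width
    layers.append(nn.Dense(n_in, cfg.output_size, "sigmoid", rng))
    return nn.Sequential(layers=layers, seed=cfg.seed)


def quantize_for_embedding(values: np.ndarray, vocab: int = 101) -> np.ndarray:
    """Round scaled intensities to integer tokens in [0, vocab-1]."""
    return np.clip(np.rint(np.asarray(values)), 0, vocab - 1).astype(np.int64)


def _prepare_inputs(X: np.ndarray, cfg: CnnConfig) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != cfg.input_length:
        raise ValueError(f"input length {X.shape[1]} != configured {cfg.input_length}")
    return quantize_for_embedding(X, cfg.embedding_vocab) if cfg.use_embedding else X


def train(model: nn.Sequential, X: np.ndarray, Y: np.ndarray, cfg: CnnConfig) -> tuple[nn.Sequential, list[dict]]:
    """Train on binned spectra X (n, input_length) against 528-bit rows Y."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != cfg.output_size:
        raise ValueError(f"Y must be (n, {cfg.output_size})")
    Xp = _prepare_inputs(X, cfg)
    if len(Xp) != len(Y):
        raise ValueError("X and Y must have equal length")
    log = model.fit(Xp, Y, epochs=cfg.epochs, batch_size=cfg.batch_size, lr=cfg.learning_rate)
    return model, log


def predict_fingerprint(
    model: nn.Sequential,
    binned: "BinnedSpectrum | np.ndarray",
    cfg: CnnConfig,
    threshold: float = 0.5,
) -> tuple[np.ndarray, Fingerprint]:
    """Bit probabilities and the thresholded fingerprint for one spectrum.

    ``bits[i] = 1`` iff ``probabilities[i] >= threshold``.
    """
    values = binned.values if isinstance(binned, BinnedSpectrum) else np.asarray(binned)
    probs = model.forward(_prepare_inputs(values, cfg), training=False)[0]
    bits = (probs >= threshold).astype(np.uint8)
    return probs, Fingerprint(bits=bits, source="predicted")


# --------------------------------------------------------------------------
# Flat baselines (consume drop_zero_bins-reduced inputs)
# --------------------------------------------------------------------------


class _PerBitWrapper:
    """Fits one binary classifier per fingerprint bit, tolerating bits that
    are constant in the training labels (predicted as that constant)."""

    def __init__(self, factory):
        self._factory = factory
        self._models: list = []
        self._constants: list[int | None] = []

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "_PerBitWrapper":
        X, Y = np.asarray(X, dtype=float), np.asarray(Y)
        self._models, self._constants = [], []
        for j in range(Y.shape[1]):
            y = Y[:, j]
            classes = np.unique(y)
            if classes.size == 1:
                self._models.append(None)
                self._constants.append(int(classes[0]))
            else:
                clf = self._factory()
                clf.fit(X, y)
                self._models.append(clf)
                self._constants.append(None)
        return self

    def predict_bits(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.zeros((X.shape[0], len(self._models)), dtype=np.uint8)
        for j, (clf, const) in enumerate(zip(self._models, self._constants)):
            if clf is None:
                out[:, j] = const
            elif hasattr(clf, "predict_proba"):
                out[:, j] = (clf.predict_proba(X)[:, 1] >= threshold).astype(np.uint8)
            else:
                out[:, j] = (clf.decision_function(X) > 0).astype(np.uint8)
        return out


class SLPBaseline:
    """Single dense sigmoid layer trained with BCE under Adam."""

    def __init__(self, n_out: int = TOTAL_BITS, epochs: int = 50, batch_size: int = 32, lr: float = 1e-2, seed: int = 0):
        self.n_out, self.epochs, self.batch_size, self.lr, self.seed = n_out, epochs, batch_size, lr, seed
        self.model: nn.Sequential | None = None

    def build(self, n_in: int) -> "SLPBaseline":
        rng = np.random.default_rng(self.seed)
        self.model = nn.Sequential(layers=[nn.Dense(n_in, self.n_out, "sigmoid", rng)], seed=self.seed)
        return self

    @property
    def n_parameters(self) -> int:
        if self.model is None:
            raise RuntimeError("call build() or fit() first")
        return self.model.n_parameters()

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "SLPBaseline":
        X, Y = np.asarray(X, dtype=float), np.asarray(Y, dtype=float)
        if self.model is None:
            self.build(X.shape[1])
        self.model.fit(X, Y, epochs=self.epochs, batch_size=self.batch_size, lr=self.lr)
        return self

    def predict_bits(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        probs = self.model.forward(np.asarray(X, dtype=float), training=False)
        return (probs >= threshold).astype(np.uint8)


class MLPBaseline:
    """Dense hidden layers + sigmoid outputs (sklearn multilabel MLP)."""

    def __init__(self, hidden: tuple[int, ...] = (256,), max_iter: int = 200, seed: int = 0):
        self.clf = MLPClassifier(hidden_layer_sizes=hidden, max_iter=max_iter, random_state=seed)

    def fit(self, X, Y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.clf.fit(np.asarray(X, dtype=float), np.asarray(Y, dtype=int))
        return self

    def predict_bits(self, X, threshold: float = 0.5) -> np.ndarray:
        return np.asarray(self.clf.predict(np.asarray(X, dtype=float)), dtype=np.uint8)


def build_baseline(kind: str, seed: int = 0):
    """LR / SLP / SVM / MLP baseline with a common fit/predict_bits API.

    All consume zero-bin-reduced inputs; the convolutional model alone
    requires the full consecutive bin vector.
    """
    kind = kind.upper()
    if kind == "LR":
        return _PerBitWrapper(lambda: LogisticRegression(max_iter=500, random_state=seed))
    if kind == "SVM":
        return _PerBitWrapper(lambda: LinearSVC(random_state=seed))
    if kind == "SLP":
        return SLPBaseline(seed=seed)
    if kind == "MLP":
        return MLPBaseline(seed=seed)
    raise ValueError(f"unknown baseline kind {kind!r}; expected LR, SLP, SVM, or MLP")


# --------------------------------------------------------------------------
# Strategies and routing
# --------------------------------------------------------------------------


@dataclass
class TrainingItem:
    """One preprocessed training example: the source record (for context
    resolution), its binned values, and its true fingerprint bits."""

    record: SpectrumRecord
    values: np.ndarray
    bits: np.ndarray


@dataclass
class ModelBundle:
    """A trained deployment unit: one model ("all"), or up to eight keyed
    by context index, plus everything needed to route and predict."""

    strategy: str  # "single" | "single_with_context" | "eight"
    members: dict[str, nn.Sequential]
    config: CnnConfig
    training_logs: dict[str, list[dict]] = field(default_factory=dict)
    bin_count: int = 1174
    default_energy: str = "low"
    default_resolution: str = "high"

    def _route(self, ctx: InstrumentContext) -> str:
        key = str(ctx.index)
        if key in self.members:
            return key
        # fallback priority when a cell is unpopulated: mode > resolution > energy
        want = ctx.as_bits()

        def score(k: str) -> tuple[int, int]:
            e, r, m = (int(k) >> 2) & 1, (int(k) >> 1) & 1, int(k) & 1
            return (
                4 * (m == want[2]) + 2 * (r == want[1]) + (e == want[0]),
                -int(k),
            )

        return max(self.members, key=score)

    def predict(self, record: SpectrumRecord, values: np.ndarray, threshold: float = 0.5) -> tuple[np.ndarray, Fingerprint]:
        values = np.asarray(values, dtype=float)
        if self.strategy == "single":
            return predict_fingerprint(self.members["all"], values, self.config, threshold)
        ctx = resolve_context(record, self.default_energy, self.default_resolution)
        if self.strategy == "single_with_context":
            extended = np.concatenate([values, np.asarray(ctx.as_bits(), dtype=float)])
            return predict_fingerprint(self.members["all"], extended, self.config, threshold)
        if self.strategy == "eight":
            member = self.members[self._route(ctx)]
            return predict_fingerprint(member, values, self.config, threshold)
        raise ValueError(f"unknown strategy {self.strategy!r}")

    # --- serialization -------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "strategy": self.strategy,
            "config": asdict(self.config),
            "members": sorted(self.members),
            "bin_count": self.bin_count,
            "default_energy": self.default_energy,
            "default_resolution": self.default_resolution,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        for key, model in self.members.items():
            np.savez(directory / f"member_{key}.npz", **model.get_weights())
            log = self.training_logs.get(key, [])
            if log:
                pd.DataFrame(log).to_csv(directory / f"log_{key}.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        raw = manifest["config"]
        for key in ("conv_filters", "conv_kernels", "pool_sizes", "dense_sizes"):
            raw[key] = tuple(raw[key])
        cfg = CnnConfig(**raw)
        members: dict[str, nn.Sequential] = {}
        logs: dict[str, list[dict]] = {}
        for key in manifest["members"]:
            model = build_cnn(cfg)
            with np.load(directory / f"member_{key}.npz") as data:
                model.set_weights({k: data[k] for k in data.files})
            members[key] = model
            log_path = directory / f"log_{key}.tsv"
            if log_path.exists():
                logs[key] = pd.read_csv(log_path, sep="\t").to_dict("records")
        return cls(
            strategy=manifest["strategy"],
            members=members,
            config=cfg,
            training_logs=logs,
            bin_count=manifest["bin_count"],
            default_energy=manifest["default_energy"],
            default_resolution=manifest["default_resolution"],
        )


def fit_strategy(
    items: list[TrainingItem],
    strategy: str,
    cfg: CnnConfig,
    min_cell_compounds: int = 3,
    default_energy: str = "low",
    default_resolution: str = "high",
) -> ModelBundle:
    """Train a deployment bundle under one of the three strategies.

    ``single`` trains one model on plain bin vectors; ``single_with_context``
    appends the three binary context entries to every input; ``eight``
    trains one model per populated context cell (a cell needs at least
    ``min_cell_compounds`` distinct compound skeletons, otherwise it is
    skipped with a warning and prediction falls back to the nearest
    populated cell, matching mode first, then resolution, then energy).
    """
    if not items:
        raise ValueError("no training items")
    bin_count = int(items[0].values.shape[0])
    Y = np.vstack([it.bits for it in items]).astype(float)
    members: dict[str, nn.Sequential] = {}
    logs: dict[str, list[dict]] = {}
    if strategy == "single":
        use_cfg = replace(cfg, input_length=bin_count)
        X = np.vstack([it.values for it in items])
        model = build_cnn(use_cfg)
        _, log = train(model, X, Y, use_cfg)
        members["all"], logs["all"] = model, log
    elif strategy == "single_with_context":
        use_cfg = replace(cfg, input_length=bin_count + 3)
        rows = []
        for it in items:
            ctx = resolve_context(it.record, default_energy, default_resolution)
            rows.append(np.concatenate([it.values, np.asarray(ctx.as_bits(), dtype=float)]))
        model = build_cnn(use_cfg)
        _, log = train(model, np.vstack(rows), Y, use_cfg)
        members["all"], logs["all"] = model, log
    elif strategy == "eight":
        use_cfg = replace(cfg, input_length=bin_count)
        cells: dict[int, list[int]] = {}
        for i, it in enumerate(items):
            ctx = resolve_context(it.record, default_energy, default_resolution)
            cells.setdefault(ctx.index, []).append(i)
        for index in sorted(cells):
            idx = cells[index]
            keys = {
                first_block(items[i].record.inchikey)
                for i in idx
                if items[i].record.inchikey
            }
            if len(keys) < min_cell_compounds:
                warnings.warn(
                    f"context cell {index} holds only {len(keys)} compounds (<{min_cell_compounds}); skipped",
                    stacklevel=2,
                )
                continue
            X = np.vstack([items[i].values for i in idx])
            model = build_cnn(replace(use_cfg, seed=cfg.seed + index))
            _, log = train(model, X, Y[idx], use_cfg)
            members[str(index)], logs[str(index)] = model, log
        if not members:
            raise ValueError("no context cell met the minimum compound count")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return ModelBundle(
        strategy=strategy,
        members=members,
        config=use_cfg,
        training_logs=logs,
        bin_count=bin_count,
        default_energy=default_energy,
        default_resolution=default_resolution,
    )
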