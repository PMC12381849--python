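"""Classifier architectures and the training protocol.

Three architectures map a fixed per-atom vector plus the molecule's
variable-length shift sequence to a probability over substructure classes:

* ``mlp_lstm`` — the sequence passes through two stacked bidirectional LSTM
  layers (50 units per direction); the concatenated final forward/backward
  states feed two dense layers ending in a 500-node layer, which is
  concatenated with a dense encoding of the fixed input and passed through
  a dense stack to a softmax output;
* ``mlp_rnn``  — identical topology with simple tanh recurrent cells;
* ``cnn``      — the sequence is zero-padded to a fixed length and passed
  through convolution/max-pool blocks (pool divisor 2 halves the length,
  rounding up); the flattened maps are concatenated with the fixed input
  and classified by a dense stack.

Training is mini-batch softmax cross-entropy.  For the recurrent models,
batches are formed within groups of equal sequence length so that padding
never enters the recurrent stack.  With a fixed seed, single-threaded
training is bit-reproducible.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, train_test_split

from . import nn

ARCHITECTURES = ("mlp_lstm", "cnn", "mlp_rnn")


@dataclass
class ModelSpec:
    """Architecture hyperparameters; defaults follow the package protocol."""

    architecture: str = "mlp_lstm"
    output_classes: int = 2
    recurrent_units: int = 50
    mlp_widths: tuple = (100, 500)       # variable-branch dense widths
    fixed_hidden: int = 64               # dense width on the fixed branch
    head_widths: tuple = (128,)          # dense stack after concatenation
    conv_blocks: tuple = ((32, 3, 2), (64, 3, 2))  # (filters, kernel, pool)
    cnn_dense_width: int = 128
    activation: str = "relu"
    optimizer: str = "adam"
    optimizer_kwargs: dict = field(default_factory=dict)
    epochs: int = 120
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.output_classes < 2:
            raise ValueError("need at least 2 output classes")


@dataclass
class TrainingProtocol:
    """Split/cross-validation settings and tuning grids."""

    test_fraction: float = 0.2
    cv_folds: int = 3
    seed: int = 0
    grids: dict = field(default_factory=dict)  # param name -> list of values

    #: canonical tuning ranges: epochs window 100-150, batch 30-6000,
    #: seven optimizer families, momentum-like beta sampled 0..1 step 0.2
    EPOCH_WINDOW = (100, 150)
    BATCH_RANGE = (30, 6000)
    OPTIMIZER_FAMILIES = (
        "sgd", "adadelta", "adagrad", "rmsprop", "adam", "adamax", "nadam"
    )
    MOMENTUM_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


class _HybridRecurrentNet:
    """Shared implementation for mlp_lstm / mlp_rnn."""

    def __init__(self, spec: ModelSpec, fixed_dim: int,
                 rng: np.random.Generator) -> None:
        cell = nn.LSTM if spec.architecture == "mlp_lstm" else nn.SimpleRNN
        u = spec.recurrent_units
        act = spec.activation
        self.rnn1 = nn.Bidirectional(cell, 2, u, rng, return_sequences=True)
        self.rnn2 = nn.Bidirectional(cell, 2 * u, u, rng,
                                     return_sequences=False)
        widths = list(spec.mlp_widths)
        self.var_dense = []
        prev = 2 * u
        for w in widths:
            self.var_dense.append(nn.Dense(prev, w, act, rng))
            prev = w
        self.fixed_dense = nn.Dense(fixed_dim, spec.fixed_hidden, act, rng)
        self._var_out = prev
        self.head = []
        prev = self._var_out + spec.fixed_hidden
        for w in spec.head_widths:
            self.head.append(nn.Dense(prev, w, act, rng))
            prev = w
        self.head.append(nn.Dense(prev, spec.output_classes, "linear", rng))
        self.needs_padded_input = False

    def layers(self):
        return ([self.rnn1, self.rnn2] + self.var_dense
                + [self.fixed_dense] + self.head)

    def forward(self, fixed: np.ndarray, seq: np.ndarray) -> np.ndarray:
        v = self.rnn2.forward(self.rnn1.forward(seq))
        for layer in self.var_dense:
            v = layer.forward(v)
        f = self.fixed_dense.forward(fixed)
        h = np.concatenate([v, f], axis=1)
        for layer in self.head:
            h = layer.forward(h)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        dh = dlogits
        for layer in reversed(self.head):
            dh = layer.backward(dh)
        dv, df = dh[:, : self._var_out], dh[:, self._var_out :]
        self.fixed_dense.backward(df)
        for layer in reversed(self.var_dense):
            dv = layer.backward(dv)
        self.rnn1.backward(self.rnn2.backward(dv))


class _ConvNet:
    """CNN over the zero-padded sequence, fixed input joined after flatten."""

    def __init__(self, spec: ModelSpec, fixed_dim: int, max_len: int,
                 rng: np.random.Generator) -> None:
        act = spec.activation
        self.blocks = []
        c_in, length = 2, max_len
        for filters, kernel, pool in spec.conv_blocks:
            self.blocks.append(nn.Conv1D(c_in, filters, kernel, act, rng))
            self.blocks.append(nn.MaxPool1D(pool))
            c_in = filters
            length = -(-length // pool)
        self.flatten = nn.Flatten()
        flat_dim = c_in * length
        self._flat_dim = flat_dim
        # the handful of fixed inputs would be swamped by the conv maps if
        # concatenated raw, so they get their own dense expansion first
        self.fixed_dense = nn.Dense(fixed_dim, spec.fixed_hidden, act, rng)
        self.dense1 = nn.Dense(flat_dim + spec.fixed_hidden,
                               spec.cnn_dense_width, act, rng)
        self.dense_out = nn.Dense(spec.cnn_dense_width, spec.output_classes,
                                  "linear", rng)
        self.needs_padded_input = True

    def layers(self):
        return self.blocks + [self.fixed_dense, self.dense1, self.dense_out]

    def forward(self, fixed: np.ndarray, seq: np.ndarray) -> np.ndarray:
        h = seq
        for layer in self.blocks:
            h = layer.forward(h)
        h = self.flatten.forward(h)
        f = self.fixed_dense.forward(fixed)
        h = np.concatenate([h, f], axis=1)
        h = self.dense1.forward(h)
        return self.dense_out.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.dense1.backward(self.dense_out.backward(dlogits))
        dflat = self.flatten.backward(dh[:, : self._flat_dim])
        self.fixed_dense.backward(dh[:, self._flat_dim :])
        for layer in reversed(self.blocks):
            dflat = layer.backward(dflat)


def build_model(spec: ModelSpec, fixed_dim: int,
                max_len: Optional[int] = None):
    """Instantiate an untrained network for a feature layout."""
    rng = np.random.default_rng(spec.seed)
    if spec.architecture == "cnn":
        if max_len is None:
            raise ValueError("cnn needs max_len (padded input length)")
        return _ConvNet(spec, fixed_dim, max_len, rng)
    return _HybridRecurrentNet(spec, fixed_dim, rng)


@dataclass
class TrainedModel:
    net: object
    spec: ModelSpec
    history: dict
    feature_config: Optional[object] = None
    vocabulary: Optional[object] = None

    def save(self, directory) -> None:
        import pathlib

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for li, layer in enumerate(nn._expand(self.net.layers())):
            for name, value in layer.params.items():
                arrays[f"{li}.{name}"] = value
        np.savez(directory / "weights.npz", **arrays)
        manifest = {"spec": _spec_to_json(self.spec),
                    "history": {k: list(map(float, v))
                                for k, v in self.history.items()}}
        (directory / "model.json").write_text(json.dumps(manifest, indent=1))
        pd.DataFrame(self.history).to_csv(directory / "history.csv",
                                          index=False)


def _spec_to_json(spec: ModelSpec) -> dict:
    d = asdict(spec)
    d["mlp_widths"] = list(d["mlp_widths"])
    d["head_widths"] = list(d["head_widths"])
    d["conv_blocks"] = [list(b) for b in d["conv_blocks"]]
    return d


def load_model(directory, fixed_dim: int, max_len: Optional[int] = None
               ) -> TrainedModel:
    import pathlib

    directory = pathlib.Path(directory)
    manifest = json.loads((directory / "model.json").read_text())
    d = manifest["spec"]
    d["mlp_widths"] = tuple(d["mlp_widths"])
    d["head_widths"] = tuple(d["head_widths"])
    d["conv_blocks"] = tuple(tuple(b) for b in d["conv_blocks"])
    spec = ModelSpec(**d)
    net = build_model(spec, fixed_dim, max_len)
    with np.load(directory / "weights.npz") as data:
        for li, layer in enumerate(nn._expand(net.layers())):
            for name in layer.params:
                layer.params[name][...] = data[f"{li}.{name}"]
    return TrainedModel(net, spec, manifest["history"])


# ---------------------------------------------------------------------------
# data plumbing


def _as_labels(targets: np.ndarray) -> np.ndarray:
    """Accept integer labels or one-hot rows (exactly one 1 per row)."""
    targets = np.asarray(targets)
    if targets.ndim == 1:
        return targets.astype(int)
    if not np.all(np.sum(targets == 1, axis=1) == 1):
        raise ValueError("one-hot targets must have exactly one 1 per row")
    return targets.argmax(axis=1)


def take(features: dict, idx) -> dict:
    return {k: v[idx] for k, v in features.items()}


def split_train_test(features: dict, targets: np.ndarray,
                     test_fraction: float = 0.2, seed: int = 0) -> tuple:
    """Disjoint train/test split of the per-atom instances."""
    n = features["fixed"].shape[0]
    tr, te = train_test_split(np.arange(n), test_size=test_fraction,
                              random_state=seed, shuffle=True)
    y = _as_labels(targets)
    return take(features, tr), y[tr], take(features, te), y[te]


def _sequence_input(features: dict) -> np.ndarray:
    return np.stack([features["seq_shifts"], features["seq_mults"]], axis=2)


def _batches(features: dict, order: np.ndarray, batch_size: int,
             equal_length: bool) -> list:
    """Index batches; for recurrent nets only equal-length samples share one."""
    if not equal_length:
        return [order[i : i + batch_size]
                for i in range(0, len(order), batch_size)]
    batches = []
    lengths = features["lengths"]
    by_len: dict = {}
    for i in order:
        by_len.setdefault(lengths[i], []).append(i)
    for length in sorted(by_len):
        group = by_len[length]
        for i in range(0, len(group), batch_size):
            batches.append(np.asarray(group[i : i + batch_size]))
    return batches


def _forward_batch(net, features: dict, idx: np.ndarray) -> np.ndarray:
    fixed = features["fixed"][idx]
    seq = _sequence_input(take(features, idx))
    if not net.needs_padded_input:
        seq = seq[:, : int(features["lengths"][idx].max()), :]
    return net.forward(fixed, seq)


def train(net, features: dict, targets: np.ndarray,
          spec: ModelSpec,
          validation: Optional[tuple] = None) -> TrainedModel:
    """Mini-batch training; returns the model with per-epoch history.

    ``targets`` may be one-hot rows or integer labels.  A non-finite loss
    aborts with diagnostics rather than continuing silently.
    """
    labels = _as_labels(targets)
    n = features["fixed"].shape[0]
    if labels.shape[0] != n:
        raise ValueError(
            f"features ({n}) and targets ({labels.shape[0]}) misaligned"
        )
    if labels.max() >= spec.output_classes:
        raise ValueError("label outside the model's class range")
    rng = np.random.default_rng(spec.seed + 1)
    optimizer = nn.make_optimizer(spec.optimizer, **spec.optimizer_kwargs)
    history: dict = {"epoch": [], "loss": [], "accuracy": []}
    if validation is not None:
        history["val_loss"] = []
        history["val_accuracy"] = []
    equal_length = not net.needs_padded_input
    layers = net.layers()
    for epoch in range(spec.epochs):
        order = rng.permutation(n)
        batches = _batches(features, order, spec.batch_size, equal_length)
        rng.shuffle(batches)
        total_loss = 0.0
        correct = 0
        for idx in batches:
            logits = _forward_batch(net, features, idx)
            loss, dlogits = nn.softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise nn.TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, batch of {len(idx)}"
                )
            for layer in layers:
                layer.zero_grads()
            net.backward(dlogits)
            optimizer.step(layers)
            total_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == labels[idx]).sum())
        history["epoch"].append(epoch)
        history["loss"].append(total_loss / n)
        history["accuracy"].append(correct / n)
        if validation is not None:
            vf, vy = validation
            vprobs = predict_on(net, vf)
            vloss, _ = nn.softmax_cross_entropy(np.log(vprobs + 1e-12),
                                                _as_labels(vy))
            history["val_loss"].append(vloss)
            history["val_accuracy"].append(
                float((vprobs.argmax(axis=1) == _as_labels(vy)).mean())
            )
    return TrainedModel(net, spec, history)


def predict_on(net, features: dict, batch_size: int = 256) -> np.ndarray:
    """Per-atom class probabilities, rows summing to 1, order preserved."""
    n = features["fixed"].shape[0]
    out = np.zeros((n, net.layers()[-1].params["b"].shape[0]))
    order = np.arange(n)
    equal_length = not net.needs_padded_input
    for idx in _batches(features, order, batch_size, equal_length):
        out[idx] = nn.softmax(_forward_batch(net, features, idx))
    return out


def predict(trained: TrainedModel, features: dict) -> np.ndarray:
    return predict_on(trained.net, features)


def accuracy_of(net, features: dict, targets: np.ndarray) -> float:
    probs = predict_on(net, features)
    return float((probs.argmax(axis=1) == _as_labels(targets)).mean())


# ---------------------------------------------------------------------------
# grid search


def grid_search(protocol: TrainingProtocol, builder, features: dict,
                targets: np.ndarray) -> tuple:
    """Exhaustive grid × k-fold cross-validation.

    ``protocol.grids`` maps hyperparameter names to value lists and
    ``builder(**params)`` returns a :class:`ModelSpec`.  Every combination
    is scored by mean validation accuracy over ``cv_folds`` folds of the
    supplied data; a failing fold marks the combination failed and the
    search continues.  Ties prefer the smallest ``batch_size``, then the
    fewest ``epochs``.  Returns ``(best_params, table)``.
    """
    labels = _as_labels(targets)
    names = sorted(protocol.grids)
    combos = [dict(zip(names, values))
              for values in itertools.product(*(protocol.grids[k]
                                                for k in names))]
    if not combos:
        raise ValueError("empty grid")
    kf = KFold(n_splits=protocol.cv_folds, shuffle=True,
               random_state=protocol.seed)
    n = features["fixed"].shape[0]
    rows = []
    for params in combos:
        scores = []
        failed = False
        for tr, va in kf.split(np.arange(n)):
            try:
                spec = builder(**params)
                net = build_model(
                    spec, features["fixed"].shape[1],
                    features["seq_shifts"].shape[1],
                )
                train(net, take(features, tr), labels[tr], spec)
                scores.append(accuracy_of(net, take(features, va), labels[va]))
            except Exception:
                failed = True
                break
        rows.append({**params,
                     "mean_val_accuracy": float(np.mean(scores))
                     if scores and not failed else np.nan,
                     "failed": failed})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]].copy()
    if ok.empty:
        raise RuntimeError("every grid combination failed")
    def tiebreak(row):
        return (-row["mean_val_accuracy"],
                row.get("batch_size", 0), row.get("epochs", 0))
    best_row = min(ok.to_dict("records"), key=tiebreak)
    best = {k: best_row[k] for k in names}
    return best, table
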