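"""Bidirectional recurrent network for per-residue binding prediction.

Architecture
------------
Each residue j of a region carries a 26-channel input vector ``i_j``: 21
sequence channels (a 20-way one-hot over the standard amino acids plus one
channel encoding the parent-sequence length) and 5 structural channels
(helix/strand/coil probabilities, disorder score, normalised docking score).

Three two-layer feed-forward networks parametrise the model:

* the forward update computes a hidden chain left to right,
  ``h^f_j = N_fwd(i_j, h^f_{j-1})`` with ``h^f_0 = 0``;
* the backward update computes a chain right to left,
  ``h^b_j = N_bwd(i_j, h^b_{j+1})`` with ``h^b_{L+1} = 0``;
* the output network sees a local window of inputs around j plus both
  hidden states, ``o_j = sigmoid(N_out(i_{j-w..j+w}, h^f_j, h^b_j))``,
  so every output is informed by the whole sequence on both sides.

Hidden layers use tanh; the chain outputs are tanh-squashed and the final
output is a logistic unit read as a binding probability.  Training is
full-batch gradient descent on mean binary cross-entropy, with the learning
rate halved after every 50-epoch stretch without improvement of the best
error seen so far.  Ensembles average three models that differ in the input
window width (7, 9, 11 residues), and cross-validation reserves a different
tenth of the regions for testing in each of ten runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .regions import ProteinRegion
from .structures import AMINO_ACIDS

N_SEQ_CHANNELS = 21  # 20 one-hot + 1 length channel
N_STRUCT_CHANNELS = 5  # helix, strand, coil, disorder, docking score
N_CHANNELS = N_SEQ_CHANNELS + N_STRUCT_CHANNELS

#: fixed channel layout of the feature matrix
CHANNELS = {
    **{aa: i for i, aa in enumerate(AMINO_ACIDS)},
    "length": 20,
    "ss_helix": 21,
    "ss_strand": 22,
    "ss_coil": 23,
    "disorder": 24,
    "vina": 25,
}

ALL_FEATURES = frozenset({"ss", "disorder", "vina"})

#: the seven structural-feature combinations benchmarked alongside sequence
FEATURE_COMBOS: tuple[tuple[str, frozenset[str]], ...] = (
    ("sequence, secondary structure and disorder", frozenset({"ss", "disorder"})),
    ("sequence and secondary structure", frozenset({"ss"})),
    ("sequence and disorder", frozenset({"disorder"})),
    ("sequence and vina", frozenset({"vina"})),
    ("sequence, secondary structure and vina", frozenset({"ss", "vina"})),
    ("sequence, disorder and vina", frozenset({"disorder", "vina"})),
    ("sequence, secondary structure, disorder and vina", ALL_FEATURES),
)


# ---------------------------------------------------------------------------
# Input encoding
# ---------------------------------------------------------------------------

def encode_inputs(
    region: ProteinRegion,
    ss: np.ndarray | None = None,
    disorder: np.ndarray | None = None,
    vina: np.ndarray | None = None,
    features: Iterable[str] = ALL_FEATURES,
) -> np.ndarray:
    """Build the (L, 26) feature matrix for one region.

    ``features`` selects which structural channels are filled; deselected
    (or absent) channels stay zero so the same network shape serves every
    ablation.  Non-standard residues (e.g. X) get an all-zero one-hot block.
    """
    features = frozenset(features)
    unknown = features - ALL_FEATURES
    if unknown:
        raise ValidationError(f"unknown feature flags {sorted(unknown)}")
    L = len(region)
    x = np.zeros((L, N_CHANNELS), dtype=float)
    for j, aa in enumerate(region.seq):
        idx = CHANNELS.get(aa)
        if idx is None or aa not in AMINO_ACIDS:
            warnings.warn(
                f"non-standard residue {aa!r} at region position {j + 1}; "
                "one-hot block left zero",
                stacklevel=2,
            )
        else:
            x[j, idx] = 1.0
    x[:, CHANNELS["length"]] = min(region.parent_length / 1000.0, 1.0)

    def _track(values, name, n_col=1):
        arr = np.asarray(values, dtype=float)
        if arr.shape[0] != L:
            raise ValidationError(
                f"{name} track length {arr.shape[0]} does not match region length {L}"
            )
        return arr

    if "ss" in features:
        if ss is None:
            raise ValidationError("feature 'ss' selected but no track supplied")
        arr = _track(ss, "secondary-structure")
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError("secondary-structure track must be (L, 3)")
        if np.any(arr < -1e-9) or np.max(np.abs(arr.sum(axis=1) - 1.0)) > 1e-6:
            raise ValidationError(
                "secondary-structure probabilities must be non-negative and sum to 1"
            )
        x[:, CHANNELS["ss_helix"] : CHANNELS["ss_coil"] + 1] = arr
    if "disorder" in features:
        if disorder is None:
            raise ValidationError("feature 'disorder' selected but no track supplied")
        x[:, CHANNELS["disorder"]] = _track(disorder, "disorder")
    if "vina" in features:
        if vina is None:
            raise ValidationError("feature 'vina' selected but no track supplied")
        x[:, CHANNELS["vina"]] = _track(vina, "docking-score")
    return x


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class TwoLayerNet:
    """A dense net with one tanh hidden layer; the output squash is optional."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    squash: bool  # tanh on the output (chain updates) or raw logit (output net)

    @classmethod
    def init(cls, rng: np.random.Generator, d_in: int, d_hidden: int, d_out: int,
             squash: bool, scale: float = 0.1) -> "TwoLayerNet":
        return cls(
            W1=rng.uniform(-scale, scale, size=(d_hidden, d_in)),
            b1=rng.uniform(-scale, scale, size=d_hidden),
            W2=rng.uniform(-scale, scale, size=(d_out, d_hidden)),
            b2=rng.uniform(-scale, scale, size=d_out),
            squash=squash,
        )

    def apply(self, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (hidden activations, output) for a batch of rows."""
        h1 = np.tanh(a @ self.W1.T + self.b1)
        out = h1 @ self.W2.T + self.b2
        if self.squash:
            out = np.tanh(out)
        return h1, out


@dataclass
class BRNNModel:
    """All weights plus the hyperparameters that fix the shapes."""

    window: int
    hidden: int
    ff_hidden: int
    n_channels: int
    fwd: TwoLayerNet
    bwd: TwoLayerNet
    out: TwoLayerNet

    @classmethod
    def init(
        cls,
        rng: np.random.Generator | int,
        window: int = 9,
        hidden: int = 11,
        ff_hidden: int = 20,
        n_channels: int = N_CHANNELS,
    ) -> "BRNNModel":
        if window < 1 or window % 2 == 0:
            raise ConfigurationError("input window must be a positive odd width")
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(int(rng))
        d_chain = n_channels + hidden
        d_out = n_channels * window + 2 * hidden
        return cls(
            window=window,
            hidden=hidden,
            ff_hidden=ff_hidden,
            n_channels=n_channels,
            fwd=TwoLayerNet.init(rng, d_chain, ff_hidden, hidden, squash=True),
            bwd=TwoLayerNet.init(rng, d_chain, ff_hidden, hidden, squash=True),
            out=TwoLayerNet.init(rng, d_out, ff_hidden, 1, squash=False),
        )

    def parameters(self) -> dict[str, np.ndarray]:
        params = {}
        for net_name in ("fwd", "bwd", "out"):
            net = getattr(self, net_name)
            for p_name in ("W1", "b1", "W2", "b2"):
                params[f"{net_name}.{p_name}"] = getattr(net, p_name)
        return params

    def copy(self) -> "BRNNModel":
        def _c(net: TwoLayerNet) -> TwoLayerNet:
            return TwoLayerNet(net.W1.copy(), net.b1.copy(), net.W2.copy(),
                               net.b2.copy(), net.squash)

        return replace(self, fwd=_c(self.fwd), bwd=_c(self.bwd), out=_c(self.out))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-residue binding probabilities for one (L, C) feature matrix."""
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.n_channels:
            raise ValidationError(
                f"expected (L, {self.n_channels}) feature matrix, got {x.shape}"
            )
        _, logit = _forward(self, x[None, :, :])
        return _sigmoid(logit[0])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _window_view(x: np.ndarray, w: int) -> np.ndarray:
    """Zero-padded local windows: (B, L, C) -> (B, L, w*C)."""
    B, L, C = x.shape
    half = w // 2
    pad = np.zeros((B, half, C))
    xp = np.concatenate([pad, x, pad], axis=1)
    return np.stack(
        [xp[:, j : j + w, :].reshape(B, w * C) for j in range(L)], axis=1
    )


def _forward(
    model: BRNNModel,
    x: np.ndarray,
    cache: dict | None = None,
    xw: np.ndarray | None = None,
):
    """Batched forward pass over equal-length sequences.

    ``x`` has shape (B, L, C); returns the output-net input matrix is kept in
    ``cache`` when supplied so the backward pass can reuse it.
    """
    B, L, C = x.shape
    H = model.hidden
    hf = np.zeros((B, H))
    hf_states, hf_hidden, hf_inputs = [], [], []
    for j in range(L):
        a = np.concatenate([x[:, j, :], hf], axis=1)
        h1, hf = model.fwd.apply(a)
        hf_inputs.append(a)
        hf_hidden.append(h1)
        hf_states.append(hf)
    hb = np.zeros((B, H))
    hb_states: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    hb_hidden: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    hb_inputs: list[np.ndarray] = [None] * L  # type: ignore[list-item]
    for j in range(L - 1, -1, -1):
        a = np.concatenate([x[:, j, :], hb], axis=1)
        h1, hb = model.bwd.apply(a)
        hb_inputs[j] = a
        hb_hidden[j] = h1
        hb_states[j] = hb

    if xw is None:
        xw = _window_view(x, model.window)
    HF = np.stack(hf_states, axis=1)  # (B, L, H)
    HB = np.stack(hb_states, axis=1)
    a_out = np.concatenate([xw, HF, HB], axis=2)  # (B, L, D)
    flat = a_out.reshape(B * L, -1)
    h1o, logit = model.out.apply(flat)
    logit = logit.reshape(B, L)
    if cache is not None:
        cache.update(
            hf_inputs=hf_inputs, hf_hidden=hf_hidden, hf_states=hf_states,
            hb_inputs=hb_inputs, hb_hidden=hb_hidden, hb_states=hb_states,
            a_out=flat, h1o=h1o,
        )
    return None, logit


def _bce_with_logits(logit: np.ndarray, y: np.ndarray) -> float:
    # numerically stable sum of per-residue binary cross-entropies
    return float(np.sum(np.maximum(logit, 0) - logit * y + np.log1p(np.exp(-np.abs(logit)))))


def loss_and_gradients(
    model: BRNNModel, x: np.ndarray, y: np.ndarray, xw: np.ndarray | None = None
) -> tuple[float, dict[str, np.ndarray]]:
    """Summed cross-entropy and its analytic gradients for one batch.

    ``x``: (B, L, C) equal-length feature matrices; ``y``: (B, L) binary
    labels.  Gradients are backpropagated through the output net and through
    time along both hidden chains.  The loss and gradients are sums over
    residues; callers normalise by the residue count.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    B, L, C = x.shape
    H = model.hidden
    cache: dict = {}
    _, logit = _forward(model, x, cache, xw=xw)
    loss = _bce_with_logits(logit, y)
    dlogit = (_sigmoid(logit) - y).reshape(B * L, 1)

    grads = {name: np.zeros_like(p) for name, p in model.parameters().items()}

    # output network
    h1o = cache["h1o"]
    a_out = cache["a_out"]
    grads["out.W2"] += dlogit.T @ h1o
    grads["out.b2"] += dlogit.sum(axis=0)
    dz1 = (dlogit @ model.out.W2) * (1.0 - h1o**2)
    grads["out.W1"] += dz1.T @ a_out
    grads["out.b1"] += dz1.sum(axis=0)
    da = (dz1 @ model.out.W1).reshape(B, L, -1)
    wC = model.window * C
    dHF = da[:, :, wC : wC + H]
    dHB = da[:, :, wC + H :]

    # forward chain, backpropagated right to left
    delta = np.zeros((B, H))
    for j in range(L - 1, -1, -1):
        g = dHF[:, j, :] + delta
        dz2 = g * (1.0 - cache["hf_states"][j] ** 2)
        grads["fwd.W2"] += dz2.T @ cache["hf_hidden"][j]
        grads["fwd.b2"] += dz2.sum(axis=0)
        dz1 = (dz2 @ model.fwd.W2) * (1.0 - cache["hf_hidden"][j] ** 2)
        grads["fwd.W1"] += dz1.T @ cache["hf_inputs"][j]
        grads["fwd.b1"] += dz1.sum(axis=0)
        delta = (dz1 @ model.fwd.W1)[:, C:]

    # backward chain, backpropagated left to right
    delta = np.zeros((B, H))
    for j in range(L):
        g = dHB[:, j, :] + delta
        dz2 = g * (1.0 - cache["hb_states"][j] ** 2)
        grads["bwd.W2"] += dz2.T @ cache["hb_hidden"][j]
        grads["bwd.b2"] += dz2.sum(axis=0)
        dz1 = (dz2 @ model.bwd.W2) * (1.0 - cache["hb_hidden"][j] ** 2)
        grads["bwd.W1"] += dz1.T @ cache["hb_inputs"][j]
        grads["bwd.b1"] += dz1.sum(axis=0)
        delta = (dz1 @ model.bwd.W1)[:, C:]

    return loss, grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainingConfig:
    """Training and cross-validation hyperparameters.

    ``epochs=10_000`` with ``lr=0.01`` is the reference schedule; desk-scale
    experiments pass smaller values.  ``patience`` is the number of
    consecutive epochs without a new best training error after which the
    learning rate is halved.
    """

    epochs: int = 10_000
    lr: float = 0.01
    patience: int = 50
    folds: int = 10
    ensemble_windows: tuple[int, ...] = (7, 9, 11)
    hidden: int = 11
    ff_hidden: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.patience < 1 or self.folds < 2:
            raise ConfigurationError(
                "epochs must be >= 0, patience >= 1 and folds >= 2"
            )


class LRScheduler:
    """Halve the learning rate after each ``patience``-epoch stagnation run.

    An epoch counts as stagnant when its error does not improve on the best
    error seen so far; after a halving the stagnation counter restarts, so a
    single long plateau triggers one halving per full ``patience`` stretch.
    """

    def __init__(self, lr: float, patience: int) -> None:
        self.lr = lr
        self.patience = patience
        self.best = np.inf
        self.stall = 0

    def update(self, error: float) -> float:
        if error < self.best:
            self.best = error
            self.stall = 0
        else:
            self.stall += 1
            if self.stall >= self.patience:
                self.lr /= 2.0
                self.stall = 0
        return self.lr


def learning_rate_trace(errors: Sequence[float], lr: float, patience: int) -> list[float]:
    """Learning rate in effect after observing each error in a series."""
    sched = LRScheduler(lr, patience)
    return [sched.update(e) for e in errors]


@dataclass
class TrainingLog:
    rows: list[tuple[int, float, float]] = field(default_factory=list)  # epoch, loss, lr

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\tloss\tlearning_rate\n")
            for epoch, loss, lr in self.rows:
                fh.write(f"{epoch}\t{loss:.8g}\t{lr:.8g}\n")


def _group_by_length(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    groups: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for x, y in dataset:
        groups.setdefault(x.shape[0], []).append((np.asarray(x, float), np.asarray(y, float)))
    return [
        (np.stack([x for x, _ in items]), np.stack([y for _, y in items]))
        for _, items in sorted(groups.items())
    ]


def train_brnn(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig,
    window: int = 9,
    log: TrainingLog | None = None,
) -> BRNNModel:
    """Full-batch gradient descent on mean per-residue cross-entropy.

    Sequences are grouped by length so each group runs as one vectorised
    batch; the loss and gradients are means over all residues in the
    dataset.  Fully reproducible from ``config.seed``.
    """
    if not dataset:
        raise ConfigurationError("empty training dataset")
    all_labels = np.concatenate([np.asarray(y) for _, y in dataset])
    if all_labels.min() == all_labels.max():
        raise ConfigurationError("training labels contain a single class")
    model = BRNNModel.init(
        np.random.default_rng(config.seed),
        window=window,
        hidden=config.hidden,
        ff_hidden=config.ff_hidden,
        n_channels=dataset[0][0].shape[1],
    )
    groups = _group_by_length(dataset)
    # the windowed input view is constant across epochs; build it once
    windows = [_window_view(xb, window) for xb, _ in groups]
    n_res = sum(x.shape[0] * x.shape[1] for x, _ in groups)
    sched = LRScheduler(config.lr, config.patience)
    params = model.parameters()
    for epoch in range(1, config.epochs + 1):
        total_loss = 0.0
        total_grads = {name: np.zeros_like(p) for name, p in params.items()}
        for (xb, yb), xw in zip(groups, windows):
            loss, grads = loss_and_gradients(model, xb, yb, xw=xw)
            total_loss += loss
            for name, g in grads.items():
                total_grads[name] += g
        mean_loss = total_loss / n_res
        lr = sched.lr
        for name, p in params.items():
            p -= lr * (total_grads[name] / n_res)
        sched.update(mean_loss)
        if log is not None:
            log.rows.append((epoch, mean_loss, lr))
    return model


def ensemble_predict(models: Sequence[BRNNModel], x: np.ndarray) -> np.ndarray:
    """Arithmetic mean of member predictions per residue."""
    if not models:
        raise ConfigurationError("empty model ensemble")
    return np.mean([m.predict(x) for m in models], axis=0)


def train_ensemble(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig,
) -> list[BRNNModel]:
    """Train one model per ensemble window width (default 7, 9, 11)."""
    models = []
    for i, w in enumerate(config.ensemble_windows):
        member_cfg = replace(config, seed=config.seed + 1000 * (i + 1))
        models.append(train_brnn(dataset, member_cfg, window=w))
    return models


def make_folds(n_items: int, folds: int, seed: int) -> list[np.ndarray]:
    """Shuffled partition into ``folds`` disjoint chunks of near-equal size."""
    if n_items < folds:
        raise ConfigurationError(
            f"cannot split {n_items} items into {folds} folds"
        )
    perm = np.random.default_rng(seed).permutation(n_items)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def cross_validate(
    dataset: Sequence[tuple[np.ndarray, np.ndarray]],
    config: TrainingConfig,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Out-of-fold ensemble predictions for every item.

    Each item is predicted exactly once, by the ensemble trained on the
    folds it does not belong to.  Returns (per-item prediction tracks, fold
    assignment per item).
    """
    n = len(dataset)
    folds = make_folds(n, config.folds, config.seed)
    predictions: list[np.ndarray | None] = [None] * n
    assignment = np.empty(n, dtype=int)
    for f, test_idx in enumerate(folds):
        test_set = set(int(i) for i in test_idx)
        train_items = [dataset[i] for i in range(n) if i not in test_set]
        fold_cfg = replace(config, seed=config.seed + 7919 * (f + 1))
        models = train_ensemble(train_items, fold_cfg)
        for i in test_idx:
            predictions[i] = ensemble_predict(models, dataset[i][0])
            assignment[i] = f
    return predictions, assignment  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: BRNNModel, path: str | Path) -> None:
    """Serialise a model (shapes + weights) as JSON."""
    payload = {
        "window": model.window,
        "hidden": model.hidden,
        "ff_hidden": model.ff_hidden,
        "n_channels": model.n_channels,
        "weights": {name: p.tolist() for name, p in model.parameters().items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> BRNNModel:
    payload = json.loads(Path(path).read_text())
    model = BRNNModel.init(
        0,
        window=payload["window"],
        hidden=payload["hidden"],
        ff_hidden=payload["ff_hidden"],
        n_channels=payload["n_channels"],
    )
    params = model.parameters()
    for name, values in payload["weights"].items():
        params[name][...] = np.asarray(values, dtype=float)
    return model
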