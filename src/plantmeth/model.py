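"""The two-branch bidirectional LSTM methylation classifier.

Sequence features (per-base nucleotide plus signal mean/std/count) and
signal features (m sampled current values per base) are each fed through a
bidirectional LSTM followed by a per-timestep fully connected layer.  The
branch outputs are concatenated per timestep and passed through a stack of
bidirectional LSTM layers, then two fully connected layers and a softmax
that yields (P_um, P_m) with P_m + P_um = 1.  A site in a read is called
methylated when P_m > P_um.

Training minimizes cross-entropy with the Adam optimizer; dropout is active
in the LSTM stack and the fully connected head; the parameters with the best
validation accuracy are retained, and early stopping halts training as soon
as an epoch's validation accuracy drops below the best seen.

The ``mode`` switch selects the full two-branch network or a single-branch
variant (``signal_only`` is the variant used inside training-set denoising).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from ._layers import (
    Adam,
    BiLSTM,
    Dense,
    Dropout,
    Embedding,
    Param,
    ReLU,
    TimeDense,
    softmax,
    softmax_cross_entropy,
)
from .features import SiteSample

MODES = ("full", "signal_only", "sequence_only")


@dataclass
class ModelConfig:
    k: int = 13
    m: int = 16
    embed_dim: int = 4
    branch_hidden: int = 256
    branch_fc: int = 128
    merged_layers: int = 3
    merged_hidden: int = 256
    head_hidden: int = 128
    dropout_rate: float = 0.5
    learning_rate: float = 0.001
    batch_size: int = 512
    max_epochs: int = 10
    early_stopping: bool = True
    seed: int = 1
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.merged_layers < 1:
            raise ValueError("merged_layers must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class Prediction:
    p_methylated: float
    p_unmethylated: float


class MethylationNet:
    """See the module docstring for the architecture."""

    def __init__(self, cfg: ModelConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        merged_in = 0
        if cfg.mode in ("full", "sequence_only"):
            self.embed = Embedding(4, cfg.embed_dim, rng)
            self.seq_rnn = BiLSTM(cfg.embed_dim + 3, cfg.branch_hidden, rng)
            self.seq_fc = TimeDense(2 * cfg.branch_hidden, cfg.branch_fc, rng)
            self.seq_relu = ReLU()
            merged_in += cfg.branch_fc
        if cfg.mode in ("full", "signal_only"):
            self.sig_rnn = BiLSTM(cfg.m, cfg.branch_hidden, rng)
            self.sig_fc = TimeDense(2 * cfg.branch_hidden, cfg.branch_fc, rng)
            self.sig_relu = ReLU()
            merged_in += cfg.branch_fc
        self.merged: list[BiLSTM] = []
        self.merged_drop: list[Dropout] = []
        n_in = merged_in
        for _ in range(cfg.merged_layers):
            self.merged.append(BiLSTM(n_in, cfg.merged_hidden, rng))
            self.merged_drop.append(Dropout(cfg.dropout_rate))
            n_in = 2 * cfg.merged_hidden
        self.head1 = Dense(2 * cfg.merged_hidden, cfg.head_hidden, rng)
        self.head_relu = ReLU()
        self.head_drop = Dropout(cfg.dropout_rate)
        self.head2 = Dense(cfg.head_hidden, 2, rng)

    # -- plumbing -----------------------------------------------------------

    def params(self) -> list[Param]:
        out: list[Param] = []
        if self.cfg.mode in ("full", "sequence_only"):
            out += self.embed.params() + self.seq_rnn.params() + self.seq_fc.params()
        if self.cfg.mode in ("full", "signal_only"):
            out += self.sig_rnn.params() + self.sig_fc.params()
        for layer in self.merged:
            out += layer.params()
        out += self.head1.params() + self.head2.params()
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    # -- forward / backward -------------------------------------------------

    def forward(
        self,
        codes: np.ndarray | None,
        numeric: np.ndarray | None,
        signals: np.ndarray | None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        parts = []
        if self.cfg.mode in ("full", "sequence_only"):
            if codes is None or numeric is None:
                raise ValueError(f"mode {self.cfg.mode!r} requires sequence features")
            if numeric.shape[1:] != (self.cfg.k, 3):
                raise ValueError(
                    f"sequence numeric features must be (N, {self.cfg.k}, 3), got {numeric.shape}"
                )
            x = np.concatenate([self.embed.forward(codes), numeric], axis=2)
            x = self.seq_relu.forward(self.seq_fc.forward(self.seq_rnn.forward(x)))
            parts.append(x)
        if self.cfg.mode in ("full", "signal_only"):
            if signals is None:
                raise ValueError(f"mode {self.cfg.mode!r} requires signal features")
            if signals.shape[1:] != (self.cfg.k, self.cfg.m):
                raise ValueError(
                    f"signal features must be (N, {self.cfg.k}, {self.cfg.m}), got {signals.shape}"
                )
            x = self.sig_relu.forward(self.sig_fc.forward(self.sig_rnn.forward(signals)))
            parts.append(x)
        x = parts[0] if len(parts) == 1 else np.concatenate(parts, axis=2)
        for layer, drop in zip(self.merged, self.merged_drop):
            x = drop.forward(layer.forward(x), train, rng)
        h = self.cfg.merged_hidden
        # final forward state is at the last timestep, final backward state at the first
        last = np.concatenate([x[:, -1, :h], x[:, 0, h:]], axis=1)
        z = self.head_drop.forward(self.head_relu.forward(self.head1.forward(last)), train, rng)
        return self.head2.forward(z)

    def backward(self, dlogits: np.ndarray) -> None:
        dz = self.head1.backward(self.head_relu.backward(self.head_drop.backward(self.head2.backward(dlogits))))
        n = dz.shape[0]
        h = self.cfg.merged_hidden
        t = self.cfg.k
        dx = np.zeros((n, t, 2 * h))
        dx[:, -1, :h] += dz[:, :h]
        dx[:, 0, h:] += dz[:, h:]
        for layer, drop in zip(reversed(self.merged), reversed(self.merged_drop)):
            dx = layer.backward(drop.backward(dx))
        if self.cfg.mode == "full":
            d_seq, d_sig = dx[:, :, : self.cfg.branch_fc], dx[:, :, self.cfg.branch_fc :]
        elif self.cfg.mode == "sequence_only":
            d_seq, d_sig = dx, None
        else:
            d_seq, d_sig = None, dx
        if d_seq is not None:
            dxs = self.seq_rnn.backward(self.seq_fc.backward(self.seq_relu.backward(d_seq)))
            self.embed.backward(dxs[:, :, : self.cfg.embed_dim])
        if d_sig is not None:
            self.sig_rnn.backward(self.sig_fc.backward(self.sig_relu.backward(d_sig)))

    # -- checkpointing ------------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params()]

    def set_state(self, state: Sequence[np.ndarray]) -> None:
        for p, arr in zip(self.params(), state):
            p.data[...] = arr


def build_model(cfg: ModelConfig) -> MethylationNet:
    return MethylationNet(cfg)


def save_model(model: MethylationNet, path: str | Path) -> None:
    """Self-describing checkpoint: config JSON plus weight arrays."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params())}
    np.savez(path, config=np.array(json.dumps(asdict(model.cfg))), **arrays)


def load_model(path: str | Path) -> MethylationNet:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["config"])))
        model = MethylationNet(cfg)
        model.set_state([data[f"param_{i}"] for i in range(len(model.params()))])
    return model


# ---------------------------------------------------------------------------
# Sample batching


def stack_samples(
    samples: Sequence[SiteSample], mode: str
) -> tuple[np.ndarray | None, np.ndarray | None, np.ndarray | None, np.ndarray | None]:
    """Stack SiteSamples into (codes, numeric, signals, labels) arrays."""
    codes = numeric = signals = labels = None
    if mode in ("full", "sequence_only"):
        seq = np.stack([s.seq_features for s in samples])
        codes = seq[:, :, 0].astype(np.int64)
        numeric = seq[:, :, 1:]
    if mode in ("full", "signal_only"):
        signals = np.stack([s.signal_features for s in samples])
    if all(s.label is not None for s in samples):
        labels = np.array([s.label for s in samples], dtype=np.int64)
    return codes, numeric, signals, labels


def _batches(n: int, batch_size: int, order: np.ndarray | None = None):
    idx = np.arange(n) if order is None else order
    for lo in range(0, n, batch_size):
        yield idx[lo : lo + batch_size]


# ---------------------------------------------------------------------------
# Training and prediction


def split_train_valid(
    samples: Sequence[SiteSample], ratio: float = 0.99, seed: int = 1
) -> tuple[list[SiteSample], list[SiteSample]]:
    """Seed-reproducible disjoint, exhaustive split; train gets floor(n*ratio)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(len(samples) * ratio)
    train = [samples[i] for i in order[:n_train]]
    valid = [samples[i] for i in order[n_train:]]
    return train, valid


def train_model(
    model: MethylationNet,
    train_samples: Sequence[SiteSample],
    valid_samples: Sequence[SiteSample],
    cfg: ModelConfig | None = None,
) -> tuple[MethylationNet, list[dict]]:
    """Adam / cross-entropy training with validation-based model selection.

    Returns the model (restored to its best-validation parameters) and a
    per-epoch history of mean training loss and validation accuracy.
    """
    cfg = cfg or model.cfg
    if len(train_samples) == 0:
        raise ValueError("empty training set")
    codes, numeric, signals, labels = stack_samples(train_samples, cfg.mode)
    if labels is None:
        raise ValueError("training samples must all be labelled")
    if len(valid_samples) > 0:
        v_codes, v_numeric, v_signals, v_labels = stack_samples(valid_samples, cfg.mode)
    else:
        v_codes = v_numeric = v_signals = v_labels = None
    optimizer = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: list[dict] = []
    best_acc = -1.0
    best_state = model.get_state()
    n = len(train_samples)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for idx in _batches(n, cfg.batch_size, order):
            optimizer.zero_grad()
            logits = model.forward(
                None if codes is None else codes[idx],
                None if numeric is None else numeric[idx],
                None if signals is None else signals[idx],
                train=True,
                rng=rng,
            )
            loss, dlogits = softmax_cross_entropy(logits, labels[idx])
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
        if len(valid_samples) > 0 and v_labels is not None:
            v_probs = _predict_arrays(model, v_codes, v_numeric, v_signals, cfg.batch_size)
            val_acc = float(((v_probs[:, 1] > v_probs[:, 0]).astype(int) == v_labels).mean())
        else:
            val_acc = float("nan")
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_acc": val_acc})
        if np.isnan(val_acc):
            best_state = model.get_state()  # no validation set: keep latest
        elif val_acc > best_acc:
            best_acc = val_acc
            best_state = model.get_state()
        elif cfg.early_stopping and val_acc < best_acc:
            break
    model.set_state(best_state)
    return model, history


def _predict_arrays(
    model: MethylationNet,
    codes: np.ndarray | None,
    numeric: np.ndarray | None,
    signals: np.ndarray | None,
    batch_size: int,
) -> np.ndarray:
    n = next(a.shape[0] for a in (codes, numeric, signals) if a is not None)
    out = np.empty((n, 2))
    for idx in _batches(n, batch_size):
        logits = model.forward(
            None if codes is None else codes[idx],
            None if numeric is None else numeric[idx],
            None if signals is None else signals[idx],
            train=False,
        )
        out[idx] = softmax(logits)
    return out


def predict(model: MethylationNet, samples: Sequence[SiteSample]) -> list[Prediction]:
    """Per-sample (P_m, P_um) in input order; P_m + P_um = 1 by construction."""
    if len(samples) == 0:
        return []
    codes, numeric, signals, _ = stack_samples(samples, model.cfg.mode)
    probs = _predict_arrays(model, codes, numeric, signals, model.cfg.batch_size)
    return [Prediction(p_methylated=float(p[1]), p_unmethylated=float(p[0])) for p in probs]


def predict_proba(model: MethylationNet, samples: Sequence[SiteSample]) -> np.ndarray:
    """Methylation probabilities P_m as a flat array, in input order."""
    if len(samples) == 0:
        return np.empty(0)
    codes, numeric, signals, _ = stack_samples(samples, model.cfg.mode)
    return _predict_arrays(model, codes, numeric, signals, model.cfg.batch_size)[:, 1]


def make_denoise_trainer(cfg: ModelConfig):
    """A fit-and-score callable for training-set denoising.

    Returns ``fit_score(train, to_score, epochs, seed) -> P_m array`` that
    trains a freshly initialized model (no early stopping, fixed epochs) and
    scores held-out samples.  Denoising uses the signal-only model variant.
    """

    def fit_score(
        train: Sequence[SiteSample], to_score: Sequence[SiteSample], epochs: int, seed: int
    ) -> np.ndarray:
        from dataclasses import replace

        run_cfg = replace(cfg, max_epochs=epochs, early_stopping=False, seed=seed)
        model = MethylationNet(run_cfg)
        train_model(model, train, [], run_cfg)
        return predict_proba(model, to_score)

    return fit_score
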