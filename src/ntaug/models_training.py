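"""Reference CNN and transformer models plus the training disciplines.

Two model families are provided, each in a regression (-R) and a
classification (-C) flavour:

* **Transformer** — ngram token ids -> embedding -> sinusoidal positional
  encoding -> transformer encoder layer(s) with a key padding mask ->
  flatten (PAD positions zeroed) -> linear -> ReLU/dropout -> linear(1).
* **CNN** — one-hot ngram input -> 1-D convolution + batch norm + ReLU +
  max pooling (per layer) -> flatten -> linear -> ReLU/dropout -> linear(1).

The ``paper`` size preset carries the published hyperparameters
(Transformer-R: embedding 256 / 8 heads / hidden 1024 / linear 1024;
Transformer-C: 32 / 2 / 128 / 512; CNN-R: kernels 5,3 with 1024,512 filters;
CNN-C: kernel 5 with 64 filters; dropout 0.3). The ``desk`` preset keeps the
layer structure but shrinks widths so a full experiment grid trains on one
CPU in minutes.

Training uses SGD with momentum 0.9 throughout; MSE loss for regression and
binary cross entropy for classification. *Offline* runs employ early
stopping on the validation metric (Spearman's Rho or MCC). *Online* runs
apply probabilistic codon substitution to every mini-batch before the
gradient step and train a fixed number of epochs (no early stopping), so
augmented and baseline models see the same number of gradient updates.
Models are built to a fixed input length; batches are padded to it, which
makes predictions invariant to how much right-padding an input batch
carries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import nn
from .augmentation import OnlineAugmentConfig, augment_online_batch
from .dataset import LabeledDataset
from .encoding import EncodedBatch, Vocabulary, encode_sequences
from .errors import ConfigError
from .evaluation import mcc, spearman_rho

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainResult",
    "build_model",
    "train",
    "predict",
    "predict_class",
]


# architecture widths: (embed, heads, hidden, linear) / (filters, kernels, linear)
_TRANSFORMER_PRESETS = {
    ("paper", "regression"): dict(embed=256, heads=8, hidden=1024, linear=1024, layers=1),
    ("paper", "classification"): dict(embed=32, heads=2, hidden=128, linear=512, layers=1),
    ("desk", "regression"): dict(embed=32, heads=2, hidden=64, linear=64, layers=1),
    ("desk", "classification"): dict(embed=16, heads=2, hidden=32, linear=32, layers=1),
}
_CNN_PRESETS = {
    ("paper", "regression"): dict(filters=(1024, 512), kernels=(5, 3), linear=512),
    ("paper", "classification"): dict(filters=(64,), kernels=(5,), linear=512),
    ("desk", "regression"): dict(filters=(64, 32), kernels=(5, 3), linear=64),
    ("desk", "classification"): dict(filters=(16,), kernels=(5,), linear=32),
}


@dataclass(frozen=True)
class ModelConfig:
    """Model family, task and size preset."""

    family: Literal["transformer", "cnn"]
    task: Literal["regression", "classification"]
    preset: Literal["paper", "desk"] = "desk"
    dropout: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in ("transformer", "cnn"):
            raise ConfigError(f"unknown model family {self.family!r}")
        if self.task not in ("regression", "classification"):
            raise ConfigError(f"unknown task {self.task!r}")
        if self.preset not in ("paper", "desk"):
            raise ConfigError(f"unknown preset {self.preset!r}")


class _SequenceModel(nn.Module):
    """Common interface: encode raw sequences, forward to a (B, 1) output."""

    def __init__(self, cfg: ModelConfig, vocab: Vocabulary, max_len: int):
        super().__init__()
        self.cfg = cfg
        self.vocab = vocab
        self.max_len = max_len

    def encode(self, sequences: list[str]) -> EncodedBatch:
        return encode_sequences(
            sequences,
            self.vocab.scheme,
            self.vocab,
            max_len=self.max_len,
            one_hot=self.cfg.family == "cnn",
        )

    def forward(self, batch: EncodedBatch, rng: np.random.Generator) -> nn.Tensor:
        raise NotImplementedError


class TransformerModel(_SequenceModel):
    def __init__(self, cfg: ModelConfig, vocab: Vocabulary, max_len: int):
        super().__init__(cfg, vocab, max_len)
        p = _TRANSFORMER_PRESETS[(cfg.preset, cfg.task)]
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
        self.embed = nn.Embedding(vocab.content_size + 1, p["embed"], rng)
        self.pos = nn.positional_encoding(max_len, p["embed"])
        self.encoder = [
            nn.TransformerEncoderLayer(p["embed"], p["heads"], p["hidden"], cfg.dropout, rng)
            for _ in range(p["layers"])
        ]
        self.head1 = nn.Linear(max_len * p["embed"], p["linear"], rng)
        self.head2 = nn.Linear(p["linear"], 1, rng)

    def forward(self, batch: EncodedBatch, rng: np.random.Generator) -> nn.Tensor:
        B, T = batch.token_ids.shape
        x = self.embed(batch.token_ids).add_const(self.pos[None, :T, :])
        for layer in self.encoder:
            x = layer(x, batch.mask, rng)
        # zero PAD positions so flattening is independent of padding content
        x = x * (~batch.mask)[:, :, None].astype(float)
        x = x.reshape(B, -1)
        x = self.head1(x).relu().dropout(self.cfg.dropout, rng, self.training)
        return self.head2(x)


class CNNModel(_SequenceModel):
    def __init__(self, cfg: ModelConfig, vocab: Vocabulary, max_len: int):
        super().__init__(cfg, vocab, max_len)
        p = _CNN_PRESETS[(cfg.preset, cfg.task)]
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        self.convs: list[nn.Module] = []
        self.norms: list[nn.Module] = []
        c_in, length = vocab.content_size, max_len
        for f, k in zip(p["filters"], p["kernels"]):
            self.convs.append(nn.Conv1dSame(c_in, f, k, rng))
            self.norms.append(nn.BatchNorm1d(f))
            c_in = f
            length = max(1, length // 2)  # maxpool halves (floor), never to zero
        self.flat_dim = c_in * length
        self.head1 = nn.Linear(self.flat_dim, p["linear"], rng)
        self.head2 = nn.Linear(p["linear"], 1, rng)

    def forward(self, batch: EncodedBatch, rng: np.random.Generator) -> nn.Tensor:
        if batch.one_hot is None:
            raise ConfigError("CNN input requires one-hot encoding")
        x = nn.Tensor(batch.one_hot).transpose(0, 2, 1)  # (B, V, L)
        for conv, norm in zip(self.convs, self.norms):
            x = norm(conv(x)).relu()
            if x.shape[-1] >= 2:
                x = x.maxpool1d(2)
        x = x.reshape(x.shape[0], -1)
        x = self.head1(x).relu().dropout(self.cfg.dropout, rng, self.training)
        return self.head2(x)


def build_model(cfg: ModelConfig, vocab: Vocabulary, max_len: int) -> _SequenceModel:
    """Construct a model for a vocabulary and fixed token length.

    ``max_len`` is in tokens (use :func:`ntaug.encoding.n_tokens` to derive it
    from a sequence length); batches are padded to it internally.
    """
    if cfg.family == "transformer":
        return TransformerModel(cfg, vocab, max_len)
    return CNNModel(cfg, vocab, max_len)


@dataclass(frozen=True)
class TrainConfig:
    """Training discipline.

    ``offline`` mode uses validation-metric early stopping with the given
    patience and restores the best epoch's weights; ``online`` mode applies
    per-batch codon substitution (``online_cfg``) and always runs ``epochs``
    epochs. ``class_weighted_sampling`` draws mini-batch examples with
    probability inversely proportional to class frequency to balance batches
    under imbalance.
    """

    mode: Literal["offline", "online"] = "offline"
    epochs: int = 30
    patience: int = 10
    batch_size: int = 32
    lr: float = 1e-3
    momentum: float = 0.9
    seed: int = 0
    online_cfg: OnlineAugmentConfig | None = None
    class_weighted_sampling: bool = False
    clip_norm: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("offline", "online"):
            raise ConfigError(f"unknown training mode {self.mode!r}")
        if self.mode == "online" and self.online_cfg is None:
            raise ConfigError("online mode requires online_cfg")


@dataclass
class TrainResult:
    model: _SequenceModel
    train_loss: list[float]
    valid_loss: list[float]
    valid_metric: list[float]
    best_epoch: int
    stopped_epoch: int
    seed: int
    config: TrainConfig

    @property
    def history(self) -> dict:
        return {
            "train_loss": self.train_loss,
            "valid_loss": self.valid_loss,
            "valid_metric": self.valid_metric,
            "best_epoch": self.best_epoch,
            "stopped_epoch": self.stopped_epoch,
        }


def _loss(outputs: nn.Tensor, labels: np.ndarray, task: str) -> nn.Tensor:
    if task == "regression":
        return outputs.mse_loss(labels.reshape(-1, 1))
    return outputs.bce_with_logits(labels.reshape(-1, 1))


def _valid_metric(preds: np.ndarray, labels: np.ndarray, task: str) -> float:
    """Validation metric for early stopping; -inf when undefined."""
    try:
        if task == "regression":
            return spearman_rho(preds, labels)
        return mcc((preds > 0).astype(int), labels.astype(int))
    except Exception:
        return float("-inf")


def train(
    model: _SequenceModel,
    train_data: LabeledDataset,
    valid_data: LabeledDataset,
    tc: TrainConfig,
) -> TrainResult:
    """Train a model; see :class:`TrainConfig` for the offline/online contract.

    Three independent seeded random streams (batch order, model dropout,
    online augmentation) are derived from ``tc.seed``, so disabling online
    augmentation (``t_aug = 1.0``) reproduces the corresponding un-augmented
    run bit for bit.
    """
    if len(train_data) == 0:
        raise ConfigError("empty training set")
    task = model.cfg.task
    ss = np.random.SeedSequence(tc.seed)
    rng_batch, rng_model, rng_aug = (np.random.default_rng(s) for s in ss.spawn(3))
    opt = nn.SGD(model.parameters(), lr=tc.lr, momentum=tc.momentum, clip_norm=tc.clip_norm)

    sequences = train_data.sequences
    labels = train_data.labels
    n = len(sequences)
    weights = None
    if tc.class_weighted_sampling:
        if task != "classification":
            raise ConfigError("class-weighted sampling applies to classification")
        counts = {c: int((labels == c).sum()) for c in (0.0, 1.0)}
        if min(counts.values()) == 0:
            raise ConfigError("class-weighted sampling requires both classes present")
        weights = np.array([1.0 / counts[y] for y in labels])
        weights = weights / weights.sum()

    train_losses: list[float] = []
    valid_losses: list[float] = []
    valid_metrics: list[float] = []
    best_metric = float("-inf")
    best_epoch = -1
    best_state: list[np.ndarray] | None = None
    epochs_since_best = 0
    stopped = tc.epochs

    for epoch in range(tc.epochs):
        model.set_training(True)
        if weights is not None:
            order = rng_batch.choice(n, size=n, replace=True, p=weights)
        else:
            order = rng_batch.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            seqs = [sequences[i] for i in idx]
            if tc.mode == "online":
                seqs = augment_online_batch(seqs, tc.online_cfg, rng_aug)
            batch = model.encode(seqs)
            out = model.forward(batch, rng_model)
            loss = _loss(out, labels[idx], task)
            if not math.isfinite(float(loss.data)):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "reduce the learning rate or enable clip_norm"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_losses.append(epoch_loss / n_batches)

        vpred = predict(model, valid_data.sequences)
        model.set_training(False)
        vloss = float(
            _loss(nn.Tensor(vpred.reshape(-1, 1)), valid_data.labels, task).data
        ) if len(valid_data) else float("nan")
        metric = _valid_metric(vpred, valid_data.labels, task) if len(valid_data) else float("nan")
        valid_losses.append(vloss)
        valid_metrics.append(metric)

        if tc.mode == "offline":
            if metric > best_metric:
                best_metric = metric
                best_epoch = epoch
                best_state = model.state()
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best > tc.patience:
                    stopped = epoch + 1
                    break

    if tc.mode == "offline" and best_state is not None:
        model.load_state(best_state)
    else:
        best_epoch = tc.epochs - 1
    return TrainResult(
        model=model,
        train_loss=train_losses,
        valid_loss=valid_losses,
        valid_metric=valid_metrics,
        best_epoch=best_epoch,
        stopped_epoch=stopped if tc.mode == "offline" else tc.epochs,
        seed=tc.seed,
        config=tc,
    )


def predict(model: _SequenceModel, sequences: list[str], batch_size: int = 256) -> np.ndarray:
    """Deterministic eval-mode predictions, order-aligned with the input.

    Returns raw model outputs: fitness estimates for regression, pre-sigmoid
    logits for classification.
    """
    model.set_training(False)
    rng = np.random.default_rng(0)  # unused in eval mode (dropout off)
    chunks = []
    for start in range(0, len(sequences), batch_size):
        batch = model.encode(sequences[start : start + batch_size])
        chunks.append(model.forward(batch, rng).data.reshape(-1))
    return np.concatenate(chunks) if chunks else np.empty(0)


def predict_class(model: _SequenceModel, sequences: list[str], threshold: float = 0.5) -> np.ndarray:
    """Binary class predictions from the sigmoid of the logit output."""
    logits = predict(model, sequences)
    prob = 1.0 / (1.0 + np.exp(-logits))
    return (prob > threshold).astype(int)
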