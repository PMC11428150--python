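"""Masked feed-forward network: forward pass, gradient-masked ADAM training,
AUROC evaluation and the fully connected comparator.

The network has no bias terms — every parameter is an edge between two
labelled nodes, so edge counts are exactly the mask sums (a fully connected
138/67/42/19/1 architecture has 9246 + 2814 + 798 + 19 = 12877 edges).
Hidden layers use tanh, the output sigmoid, and training minimizes binary
cross-entropy with ADAM.  Gradients are multiplied by the binary edge masks
at every step, so discarded edges stay exactly zero through all epochs.
All randomness (batch shuffling, fold splits, comparator init) derives from
the config seed; single-threaded numpy execution makes runs bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .archinit import LayerArchitecture, SlemModel, xavier_sigma
from .exceptions import (
    InvalidArgumentError,
    SchemaError,
    TrainingError,
    UndefinedMetricError,
)
from .synthdata import EndToEndDataset

__all__ = [
    "TrainConfig",
    "NodeActivations",
    "forward",
    "predict_proba",
    "train",
    "auroc",
    "cross_validate",
    "CVResult",
    "average_auroc",
    "fully_connected_baseline",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters; defaults are the tuned study values
    (learning rate 0.005, batch size 250, 750 epochs, 10-fold CV, 100-model
    averaging)."""

    learning_rate: float = 0.005
    batch_size: int = 250
    epochs: int = 750
    folds: int = 10
    repeats: int = 100
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.learning_rate < 0:
            raise InvalidArgumentError("learning_rate must be >= 0")
        for name in ("batch_size", "epochs", "folds", "repeats"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be >= 1")


@dataclass
class NodeActivations:
    """Per-layer activations for a batch: three tanh layers plus the output
    probability.  ``on_off`` reports each intermediate node's binary status
    as the sign of its activation (tanh is symmetric about 0)."""

    hidden: list[np.ndarray]
    output: np.ndarray

    def on_off(self, layer: int) -> np.ndarray:
        return (self.hidden[layer] > 0).astype(int)


def _as_input_matrix(model: SlemModel, genotypes) -> np.ndarray:
    snp_labels = list(model.architecture.layer("snp"))
    if isinstance(genotypes, pd.DataFrame):
        missing = [s for s in snp_labels if s not in genotypes.columns]
        if missing:
            raise SchemaError(f"genotype columns missing SNPs: {missing}")
        return genotypes[snp_labels].to_numpy(float)
    X = np.asarray(genotypes, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(snp_labels):
        raise SchemaError(
            f"expected {len(snp_labels)} SNP columns, got {X.shape[1]}"
        )
    return X


def forward(model: SlemModel, genotypes) -> NodeActivations:
    """Run a genotype batch through the masked network.

    h1 = tanh(x (W1*M1)), h2 = tanh(h1 (W2*M2)), h3 = tanh(h2 (W3*M3)),
    yhat = sigmoid(h3 w4); no bias terms anywhere.
    """
    X = _as_input_matrix(model, genotypes)
    Wm = model.masked_weights()
    h = X
    hidden = []
    for W in Wm[:3]:
        h = np.tanh(h @ W)
        hidden.append(h)
    z = (h @ Wm[3]).ravel()
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return NodeActivations(hidden=hidden, output=out)


def predict_proba(model: SlemModel, genotypes) -> np.ndarray:
    return forward(model, genotypes).output


def train(
    model: SlemModel, data: EndToEndDataset, config: TrainConfig = TrainConfig()
) -> SlemModel:
    """Train a copy of the model with gradient-masked ADAM on BCE loss.

    Masks multiply the gradients every step, so masked weights remain
    exactly zero at every epoch.  The input model is not modified; the same
    seed reproduces the same trained weights bit for bit.
    """
    y_all = data.labels.to_numpy(float)
    if len(np.unique(y_all)) < 2:
        raise TrainingError("training data contain a single class")
    X_all = _as_input_matrix(model, data.genotypes)
    return _train_arrays(model, X_all, y_all, config)


def _train_arrays(
    model: SlemModel, X_all: np.ndarray, y_all: np.ndarray, config: TrainConfig
) -> SlemModel:
    out = model.copy()
    W = [w.astype(float) for w in out.weights]
    M = [m.astype(float) for m in out.masks]
    m1 = [np.zeros_like(w) for w in W]
    m2 = [np.zeros_like(w) for w in W]
    rng = np.random.default_rng([41, config.seed])
    n = len(X_all)
    t = 0
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            X, y = X_all[idx], y_all[idx]
            B = len(idx)
            # forward
            z1 = X @ W[0]
            h1 = np.tanh(z1)
            z2 = h1 @ W[1]
            h2 = np.tanh(z2)
            z3 = h2 @ W[2]
            h3 = np.tanh(z3)
            z4 = (h3 @ W[3]).ravel()
            yhat = np.empty_like(z4)
            pos = z4 >= 0
            yhat[pos] = 1.0 / (1.0 + np.exp(-z4[pos]))
            ez = np.exp(z4[~pos])
            yhat[~pos] = ez / (1.0 + ez)
            # backward (BCE + sigmoid collapses to yhat - y)
            dz4 = (yhat - y)[:, None] / B
            g4 = h3.T @ dz4
            dh3 = dz4 @ W[3].T
            dz3 = dh3 * (1.0 - h3 * h3)
            g3 = h2.T @ dz3
            dh2 = dz3 @ W[2].T
            dz2 = dh2 * (1.0 - h2 * h2)
            g2 = h1.T @ dz2
            dh1 = dz2 @ W[1].T
            dz1 = dh1 * (1.0 - h1 * h1)
            g1 = X.T @ dz1
            grads = [g1 * M[0], g2 * M[1], g3 * M[2], g4 * M[3]]
            t += 1
            for i in range(4):
                m1[i] = config.beta1 * m1[i] + (1 - config.beta1) * grads[i]
                m2[i] = config.beta2 * m2[i] + (1 - config.beta2) * grads[i] ** 2
                mhat = m1[i] / (1 - config.beta1**t)
                vhat = m2[i] / (1 - config.beta2**t)
                W[i] -= config.learning_rate * mhat / (np.sqrt(vhat) + config.eps)
                W[i] *= M[i]  # keep masked entries exactly zero
    out.weights = [w for w in W]
    out.training_state = dict(out.training_state)
    out.training_state.update(
        {
            "epochs_trained": out.training_state.get("epochs_trained", 0) + config.epochs,
            "learning_rate": config.learning_rate,
            "batch_size": config.batch_size,
            "train_seed": config.seed,
        }
    )
    return out


def bce_loss(model: SlemModel, data: EndToEndDataset) -> float:
    """Mean binary cross-entropy of the model on a labelled dataset."""
    p = np.clip(predict_proba(model, data.genotypes), 1e-12, 1 - 1e-12)
    y = data.labels.to_numpy(float)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random positive outscores a random negative (ties 1/2);
    the Mann–Whitney U normalization."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("AUROC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


@dataclass
class CVResult:
    """Cross-validated AUROC summary."""

    per_fold: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self):
        arr = np.asarray(self.per_fold)
        self.mean = float(arr.mean())
        self.sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def cross_validate(
    model_template: SlemModel, data: EndToEndDataset, config: TrainConfig = TrainConfig()
) -> CVResult:
    """Stratified k-fold cross-validation of freshly trained template copies.

    Each fold trains a fresh copy of the template on the remaining folds and
    scores AUROC on the held-out fold; folds are stratified by label and
    fully determined by the seed.
    """
    y = data.labels.to_numpy(int)
    n = len(y)
    if config.folds > n:
        raise InvalidArgumentError("folds may not exceed the sample count")
    X = _as_input_matrix(model_template, data.genotypes)
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed % (2**32))
    aucs = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        fold_cfg = TrainConfig(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            epochs=config.epochs,
            folds=config.folds,
            repeats=config.repeats,
            seed=(config.seed * 1009 + fold) % (2**31),
        )
        if len(np.unique(y[tr])) < 2:
            raise TrainingError("a training fold contains a single class")
        trained = _train_arrays(model_template, X[tr], y[tr].astype(float), fold_cfg)
        scores = forward(trained, X[te]).output
        aucs.append(auroc(scores, y[te]))
    return CVResult(per_fold=aucs)


def average_auroc(
    model_template: SlemModel, data: EndToEndDataset, config: TrainConfig = TrainConfig()
) -> CVResult:
    """Average test AUROC of ``config.repeats`` independently trained models,
    each on a fresh stratified 90/10 split."""
    from sklearn.model_selection import StratifiedShuffleSplit

    y = data.labels.to_numpy(int)
    X = _as_input_matrix(model_template, data.genotypes)
    sss = StratifiedShuffleSplit(
        n_splits=config.repeats, test_size=0.1, random_state=config.seed % (2**32)
    )
    aucs = []
    for rep, (tr, te) in enumerate(sss.split(X, y)):
        rep_cfg = TrainConfig(
            learning_rate=config.learning_rate,
            batch_size=config.batch_size,
            epochs=config.epochs,
            seed=(config.seed * 2003 + rep) % (2**31),
        )
        trained = _train_arrays(model_template, X[tr], y[tr].astype(float), rep_cfg)
        aucs.append(auroc(forward(trained, X[te]).output, y[te]))
    return CVResult(per_fold=aucs)


def fully_connected_baseline(architecture: LayerArchitecture, seed: int = 0) -> SlemModel:
    """The conventional comparator: same layers and nodes, all-ones masks,
    Xavier-normal weights throughout (no association information)."""
    sizes = architecture.sizes
    rng = np.random.default_rng([43, seed])
    weights, masks = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        sigma = xavier_sigma(fan_in, fan_out)
        weights.append(rng.normal(0, sigma, size=(fan_in, fan_out)))
        masks.append(np.ones((fan_in, fan_out), dtype=np.int8))
    return SlemModel(
        architecture=architecture,
        weights=weights,
        masks=masks,
        training_state={"seed": seed, "epochs_trained": 0},
    )
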