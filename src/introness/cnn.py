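"""The convolutional intron-sequence essentiality classifier.

The model scores an intron window s as f(s) = net(pool(rect(conv(s)))):
convolutional filters act as motif detectors, average pooling summarises
each filter's response across the sequence into a single cumulative
motif-presence value, and a fully connected rectified layer feeds a
two-way softmax whose "essential" probability is the essentiality score.

Training follows the protocol of the analysis this package implements:
20% of genes held out as a test set, threefold cross-validation on the
remainder for hyperparameter selection over a 36-point grid (dropout x
convolution window x activation x L2), class-balanced sampling of
training batches, Adam with cross-entropy for 30 epochs at batch size 64.
Splits are made at the gene level so that all introns of a gene share one
partition and no gene-specific information leaks into the test set.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .scoring import roc_auc

__all__ = [
    "CnnConfig",
    "CnnModel",
    "build_model",
    "SplitPlan",
    "grouped_split",
    "balanced_batches",
    "default_grid",
    "grid_search",
    "train",
    "score_introns",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CnnConfig:
    """Hyperparameters of the convolutional classifier.

    Defaults are the winning configuration of the hyperparameter search:
    128 filters of window 24, a 128-unit fully connected layer, dropout
    0.2, L2 1e-6, ReLU, trained 30 epochs at batch size 64.
    """

    n_filters: int = 128
    window: int = 24
    fc_units: int = 128
    dropout: float = 0.2
    l2: float = 1e-6
    l1: float = 0.0
    activation: str = "relu"
    epochs: int = 30
    batch: int = 64
    # average pooling divides conv gradients by the number of positions,
    # so a larger Adam step than the usual 1e-3 is needed to train in
    # 30 epochs
    lr: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("regularization strengths must be >= 0")
        if self.activation not in nn.ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass
class CnnModel:
    """A (possibly trained) convolutional classifier bound to a window kind."""

    config: CnnConfig
    input_len: int
    input_kind: str  # {first_window, last_window}
    net: nn.ConvPoolNet

    def n_parameters(self) -> int:
        return self.net.n_parameters()


def build_model(
    config: CnnConfig, input_len: int, input_kind: str = "first_window"
) -> CnnModel:
    """Construct an untrained model; errors if window exceeds input length."""
    if input_kind not in ("first_window", "last_window"):
        raise ValueError("input_kind must be first_window or last_window")
    net = nn.ConvPoolNet(
        input_len=input_len,
        n_filters=config.n_filters,
        window=config.window,
        fc_units=config.fc_units,
        activation=config.activation,
        dropout=config.dropout,
        l1=config.l1,
        l2=config.l2,
        seed=config.seed,
    )
    return CnnModel(config=config, input_len=input_len, input_kind=input_kind, net=net)


# ---------------------------------------------------------------------------
# Gene-grouped splitting

@dataclass
class SplitPlan:
    """Gene-level partition: every intron of a gene shares its partition."""

    assignment: dict[str, str]  # gene_id -> test | cv1..cvK
    test_fraction: float
    n_folds: int

    def genes(self, *parts: str) -> list[str]:
        return [g for g, p in self.assignment.items() if p in parts]

    def train_genes(self, held_out_fold: int | None = None) -> list[str]:
        """All non-test genes, optionally excluding one CV fold."""
        skip = {f"cv{held_out_fold}"} if held_out_fold else set()
        return [
            g
            for g, p in self.assignment.items()
            if p != "test" and p not in skip
        ]


def grouped_split(
    gene_ids,
    binary_labels,
    test_fraction: float = 0.2,
    n_folds: int = 3,
    seed: int = 0,
) -> SplitPlan:
    """Stratified gene-level split into a test set and CV folds.

    Within each binary class, genes are shuffled deterministically
    (``seed``), ``test_fraction`` of them set aside for the test set and
    the rest dealt round-robin into folds cv1..cvK.
    """
    gene_ids = list(gene_ids)
    binary_labels = list(binary_labels)
    if len(gene_ids) != len(binary_labels):
        raise ValueError("gene_ids and binary_labels must align")
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for cls in sorted(set(binary_labels)):
        members = sorted(g for g, y in zip(gene_ids, binary_labels) if y == cls)
        if len(members) < n_folds + 1:
            raise ValueError(
                f"class {cls!r} has {len(members)} genes; need >= {n_folds + 1}"
            )
        members = [members[i] for i in rng.permutation(len(members))]
        n_test = int(round(test_fraction * len(members)))
        for g in members[:n_test]:
            assignment[g] = "test"
        for k, g in enumerate(members[n_test:]):
            assignment[g] = f"cv{k % n_folds + 1}"
    return SplitPlan(assignment=assignment, test_fraction=test_fraction,
                     n_folds=n_folds)


def balanced_batches(labels, batch: int, rng: np.random.Generator):
    """Yield index batches for one epoch with equal class representation.

    The minority class is oversampled with replacement to the majority
    count; within every batch the two classes are interleaved so each
    batch is 50/50 within +-1.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("balanced_batches requires exactly two classes")
    idx0 = np.flatnonzero(labels == classes[0])
    idx1 = np.flatnonzero(labels == classes[1])
    m = max(len(idx0), len(idx1))

    def _epoch_sample(idx):
        if len(idx) < m:
            extra = rng.choice(idx, size=m - len(idx), replace=True)
            idx = np.concatenate([idx, extra])
        return idx[rng.permutation(m)]

    a, b = _epoch_sample(idx0), _epoch_sample(idx1)
    inter = np.empty(2 * m, dtype=np.int64)
    inter[0::2] = a
    inter[1::2] = b
    for s in range(0, 2 * m, batch):
        chunk = inter[s : s + batch]
        if len(chunk):
            yield chunk


# ---------------------------------------------------------------------------
# Hyperparameter grid

#: Grid axes searched for the convolutional model (36 combinations).
DEFAULT_GRID_AXES = {
    "dropout": [0.0, 0.2, 0.5],
    "window": [16, 24],
    "activation": ["relu", "elu"],
    "l2": [1e-4, 1e-6, 0.0],
}


def default_grid(base: CnnConfig | None = None) -> list[CnnConfig]:
    """The 36-configuration default grid (3 dropout x 2 window x 2
    activation x 3 L2), all other fields taken from ``base``."""
    base = base or CnnConfig()
    keys = list(DEFAULT_GRID_AXES)
    combos = itertools.product(*(DEFAULT_GRID_AXES[k] for k in keys))
    return [replace(base, **dict(zip(keys, c))) for c in combos]


def grid_search(grid, evaluate, n_folds: int = 3) -> tuple[CnnConfig, pd.DataFrame]:
    """Select the configuration with the best mean validation AUC.

    ``evaluate(config, fold)`` must return the validation AUC of
    ``config`` with CV fold ``fold`` (1-based) held out.  Ties are broken
    toward smaller l2, then smaller dropout.  Returns the winning config
    and the full results table.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    rows = []
    for cfg in grid:
        aucs = [evaluate(cfg, fold) for fold in range(1, n_folds + 1)]
        rows.append({"config": cfg, "mean_val_auc": float(np.mean(aucs))})
    table = pd.DataFrame(rows)
    best = max(
        rows,
        key=lambda r: (r["mean_val_auc"], -r["config"].l2, -r["config"].dropout),
    )
    return best["config"], table


# ---------------------------------------------------------------------------
# Training and scoring

def train(
    model: CnnModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Train in place with balanced batches; returns the epoch history.

    Deterministic given ``seed`` (defaults to the config seed).  History
    columns: epoch, loss, and val_auc when a validation set is supplied.
    """
    cfg = model.config
    seed = cfg.seed if seed is None else seed

    def batches(_epoch: int, rng: np.random.Generator):
        return balanced_batches(y_train, cfg.batch, rng)

    history = nn.fit_classifier(
        model.net,
        np.asarray(X_train, dtype=np.float32),
        np.asarray(y_train),
        epochs=cfg.epochs,
        batch_iter_fn=batches,
        lr=cfg.lr,
        seed=seed,
        X_val=X_val,
        y_val=y_val,
        val_metric=(lambda s, y: roc_auc(s, y).auc) if X_val is not None else None,
    )
    df = pd.DataFrame(history)
    if "val_metric" in df.columns:
        df = df.rename(columns={"val_metric": "val_auc"})
    return df


def score_introns(model: CnnModel, X: np.ndarray, batch: int = 256) -> np.ndarray:
    """Essentiality scores (softmax probability of the essential class)."""
    return model.net.predict_proba(np.asarray(X, dtype=np.float32), batch)[:, 1]


def save_model(model: CnnModel, path: str | Path) -> None:
    """Serialize weights (npz) with the config embedded as JSON."""
    meta = {
        "config": asdict(model.config),
        "input_len": model.input_len,
        "input_kind": model.input_kind,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.net.params)


def load_model(path: str | Path) -> CnnModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = build_model(
            CnnConfig(**meta["config"]), meta["input_len"], meta["input_kind"]
        )
        for k in model.net.params:
            model.net.params[k] = data[k].copy()
    return model
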