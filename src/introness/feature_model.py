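"""The 7-feature gene-essentiality network and its 10-model ensemble.

Per-gene feature vectors (average intron size, intron count, total
intronic bp, first/later GC-motif densities, first/later motif-excluded
GC content) are z-scored with training-set statistics, missing
later-intron entries of single-intron genes are imputed with the training
median and flagged with an appended missingness indicator, and a small
fully connected softmax network is trained with Adam + cross-entropy.
Final predictions average an ensemble of networks that differ by
initialization seed and bootstrap-resampled training sets, which reduces
the variance of any single fit.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .cnn import balanced_batches, grid_search
from .features import FEATURE_COLUMNS
from .scoring import roc_auc

__all__ = [
    "FeatureNetConfig",
    "Normalizer",
    "train_feature_net",
    "FeatureEnsemble",
    "fit_ensemble",
    "ensemble_predict",
    "default_feature_grid",
]


@dataclass(frozen=True)
class FeatureNetConfig:
    hidden_layers: tuple[int, ...] = (32,)
    dropout: float = 0.2
    l2: float = 1e-4
    l1: float = 0.0
    activation: str = "relu"
    epochs: int = 30
    batch: int = 64
    lr: float = 1e-3
    n_ensemble: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


#: architecture grid for the feature net: {1,2} layers x {32,128} units x
#: dropout x l2 = 16 combinations
FEATURE_GRID_AXES = {
    "hidden_layers": [(32,), (128,), (32, 32), (128, 128)],
    "dropout": [0.0, 0.2],
    "l2": [0.0, 1e-4],
    "n_ensemble": [1],  # grid search scores single members
}


def default_feature_grid(base: FeatureNetConfig | None = None):
    base = base or FeatureNetConfig()
    keys = [k for k in FEATURE_GRID_AXES if k != "n_ensemble"]
    combos = itertools.product(*(FEATURE_GRID_AXES[k] for k in keys))
    return [replace(base, **dict(zip(keys, c))) for c in combos]


class Normalizer:
    """Train-statistics z-scoring with median imputation of later features.

    Columns that are NaN (later-intron features of single-intron genes)
    are filled with the training median and a 0/1 missingness indicator
    column is appended.  Constant features are mapped to 0.
    """

    def __init__(self) -> None:
        self.loc: np.ndarray | None = None
        self.scale: np.ndarray | None = None
        self.medians: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=float)
        self.medians = np.nanmedian(X, axis=0)
        filled = self._impute(X)
        self.loc = filled.mean(axis=0)
        scale = filled.std(axis=0)
        self.scale = np.where(scale > 0, scale, 1.0)  # constant -> output 0
        return self

    def _impute(self, X: np.ndarray) -> np.ndarray:
        filled = X.copy()
        for j in range(X.shape[1]):
            mask = np.isnan(X[:, j])
            filled[mask, j] = self.medians[j]
        return filled

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.loc is None:
            raise RuntimeError("Normalizer not fitted")
        X = np.asarray(X, dtype=float)
        missing = np.isnan(X).any(axis=1, keepdims=True).astype(float)
        z = (self._impute(X) - self.loc) / self.scale
        return np.hstack([z, missing]).astype(np.float32)

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def feature_matrix(gene_df: pd.DataFrame) -> np.ndarray:
    """Raw (unnormalized) 7-column feature matrix from a per-gene table."""
    return gene_df[FEATURE_COLUMNS].to_numpy(dtype=float)


def _build_net(config: FeatureNetConfig, n_inputs: int, seed: int) -> nn.MLP:
    dims = [n_inputs, *config.hidden_layers, 2]
    return nn.MLP(
        dims,
        activation=config.activation,
        dropout=config.dropout,
        l1=config.l1,
        l2=config.l2,
        seed=seed,
    )


def train_feature_net(
    X: np.ndarray,
    y: np.ndarray,
    config: FeatureNetConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[nn.MLP, pd.DataFrame]:
    """Train one member network on normalized features; returns net + history."""
    seed = config.seed if seed is None else seed
    net = _build_net(config, X.shape[1], seed)

    def batches(_epoch: int, rng: np.random.Generator):
        return balanced_batches(y, config.batch, rng)

    history = nn.fit_classifier(
        net,
        np.asarray(X, dtype=np.float32),
        np.asarray(y),
        epochs=config.epochs,
        batch_iter_fn=batches,
        lr=config.lr,
        seed=seed,
        X_val=X_val,
        y_val=y_val,
        val_metric=(lambda s, yy: roc_auc(s, yy).auc) if X_val is not None else None,
    )
    return net, pd.DataFrame(history)


@dataclass
class FeatureEnsemble:
    config: FeatureNetConfig
    normalizer: Normalizer
    members: list = field(default_factory=list)

    def predict(self, raw_X: np.ndarray) -> np.ndarray:
        Z = self.normalizer.transform(raw_X)
        return ensemble_predict(self.members, Z)


def ensemble_predict(members, X: np.ndarray) -> np.ndarray:
    """Unweighted mean of member essentiality scores (order-invariant)."""
    if not members:
        raise ValueError("empty ensemble")
    scores = np.stack([m.predict_proba(X)[:, 1] for m in members])
    return scores.mean(axis=0)


def fit_ensemble(
    raw_X: np.ndarray, y: np.ndarray, config: FeatureNetConfig
) -> FeatureEnsemble:
    """Fit the normalizer plus ``n_ensemble`` bootstrap-trained members.

    Members differ by initialization seed and by a bootstrap resample of
    the training set, both derived deterministically from ``config.seed``.
    """
    norm = Normalizer()
    Z = norm.fit_transform(raw_X)
    y = np.asarray(y)
    ss = np.random.SeedSequence(config.seed)
    members = []
    for k, child in enumerate(ss.spawn(config.n_ensemble)):
        rng = np.random.default_rng(child)
        boot = rng.integers(0, len(Z), size=len(Z))
        # guard: a bootstrap draw must contain both classes
        while len(np.unique(y[boot])) < 2:
            boot = rng.integers(0, len(Z), size=len(Z))
        member_seed = int(rng.integers(0, 2**31 - 1))
        net, _ = train_feature_net(Z[boot], y[boot], config, seed=member_seed)
        members.append(net)
    return FeatureEnsemble(config=config, normalizer=norm, members=members)


def cv_select_config(
    raw_X: np.ndarray,
    y: np.ndarray,
    grid=None,
    n_folds: int = 3,
    seed: int = 0,
) -> FeatureNetConfig:
    """Threefold CV grid search over the feature-net architecture axes."""
    grid = list(grid) if grid is not None else default_feature_grid()
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    fold_of = rng.integers(1, n_folds + 1, size=len(y))

    def evaluate(cfg: FeatureNetConfig, fold: int) -> float:
        tr, va = fold_of != fold, fold_of == fold
        norm = Normalizer()
        Ztr = norm.fit_transform(raw_X[tr])
        Zva = norm.transform(raw_X[va])
        net, _ = train_feature_net(Ztr, y[tr], cfg, seed=seed + fold)
        return roc_auc(net.predict_proba(Zva)[:, 1], y[va]).auc

    best, _table = grid_search(grid, evaluate, n_folds=n_folds)
    return best
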