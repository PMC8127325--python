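"""Small numpy neural-network core: dense/conv softmax classifiers + Adam.

Two model families are provided, both trained with Adam on a softmax
cross-entropy objective with optional L1/L2 weight penalties and inverted
dropout:

* :class:`ConvPoolNet` — a DeepBind-style 1-D convolution over one-hot DNA
  (filters as motif detectors), rectifier, *average* pooling across
  sequence positions (one value per filter, the cumulative motif
  presence), then a fully connected rectified layer and a two-way softmax.
* :class:`MLP` — a stack of fully connected rectified layers with a
  two-way softmax output, used for the per-gene feature model.

Everything is float32 and deterministic given the seeds handed in; there
is no implicit global random state.
"""

from __future__ import annotations

import numpy as np

__all__ = ["ACTIVATIONS", "softmax", "Adam", "MLP", "ConvPoolNet", "fit_classifier"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _drelu(x: np.ndarray) -> np.ndarray:
    return (x > 0.0).astype(x.dtype)


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0.0, x, np.expm1(x)).astype(x.dtype)


def _delu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0.0, 1.0, np.exp(x)).astype(x.dtype)


#: name -> (activation, derivative wrt pre-activation)
ACTIVATIONS = {"relu": (_relu, _drelu), "elu": (_elu, _delu)}


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def xent(probs: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy of integer labels ``y`` under ``probs``."""
    p = probs[np.arange(len(y)), y]
    return float(-np.log(np.clip(p, 1e-12, None)).mean())


class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )


def _he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


def _reg_grads(params: dict, grads: dict, l1: float, l2: float) -> None:
    """Add d/dW of  l2*sum(W^2) + l1*sum(|W|)  to weight (not bias) grads."""
    for k, w in params.items():
        if k.startswith("W"):
            if l2:
                grads[k] += 2.0 * l2 * w
            if l1:
                grads[k] += l1 * np.sign(w)


class MLP:
    """Fully connected softmax classifier over tabular inputs."""

    def __init__(self, dims: list[int], activation: str = "relu",
                 dropout: float = 0.0, l1: float = 0.0, l2: float = 0.0,
                 seed: int = 0):
        if len(dims) < 2 or dims[-1] != 2:
            raise ValueError("dims must end in a 2-way output")
        self.dims = list(dims)
        self.act, self.dact = ACTIVATIONS[activation]
        self.dropout, self.l1, self.l2 = dropout, l1, l2
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        for i, (a, b) in enumerate(zip(dims, dims[1:])):
            self.params[f"W{i}"] = _he_init(rng, a, (a, b))
            self.params[f"b{i}"] = np.zeros(b, dtype=np.float32)
        self._cache: dict = {}

    def forward(self, X: np.ndarray, train: bool = False,
                drop_rng: np.random.Generator | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        h = X
        cache = {"acts": [X], "pres": [], "masks": []}
        n_layers = len(self.dims) - 1
        for i in range(n_layers):
            z = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < n_layers - 1:
                cache["pres"].append(z)
                h = self.act(z)
                if train and self.dropout > 0.0:
                    mask = (drop_rng.random(h.shape) >= self.dropout) / (
                        1.0 - self.dropout
                    )
                    mask = mask.astype(np.float32)
                    h = h * mask
                else:
                    mask = None
                cache["masks"].append(mask)
                cache["acts"].append(h)
            else:
                logits = z
        probs = softmax(logits)
        cache["probs"] = probs
        self._cache = cache
        return probs

    def backward(self, y: np.ndarray) -> dict[str, np.ndarray]:
        cache = self._cache
        probs = cache["probs"]
        n = len(y)
        d = probs.copy()
        d[np.arange(n), y] -= 1.0
        d /= n
        grads: dict[str, np.ndarray] = {}
        n_layers = len(self.dims) - 1
        for i in range(n_layers - 1, -1, -1):
            a_prev = cache["acts"][i]
            grads[f"W{i}"] = a_prev.T @ d
            grads[f"b{i}"] = d.sum(axis=0)
            if i > 0:
                d = d @ self.params[f"W{i}"].T
                mask = cache["masks"][i - 1]
                if mask is not None:
                    d = d * mask
                d = d * self.dact(cache["pres"][i - 1])
        _reg_grads(self.params, grads, self.l1, self.l2)
        return grads

    def predict_proba(self, X: np.ndarray, batch: int = 4096) -> np.ndarray:
        out = []
        for s in range(0, len(X), batch):
            out.append(self.forward(X[s : s + batch], train=False))
        return np.concatenate(out) if out else np.empty((0, 2), dtype=np.float32)


class ConvPoolNet:
    """conv -> rect -> average pool -> dense -> softmax over (N, L, 4) input."""

    def __init__(self, input_len: int, n_filters: int, window: int,
                 fc_units: int, activation: str = "relu", dropout: float = 0.0,
                 l1: float = 0.0, l2: float = 0.0, seed: int = 0):
        if window > input_len:
            raise ValueError(f"window {window} exceeds input length {input_len}")
        self.input_len, self.window = input_len, window
        self.n_filters, self.fc_units = n_filters, fc_units
        self.act, self.dact = ACTIVATIONS[activation]
        self.dropout, self.l1, self.l2 = dropout, l1, l2
        rng = np.random.default_rng(seed)
        w4 = window * 4
        self.params = {
            "Wc": _he_init(rng, w4, (w4, n_filters)),
            "bc": np.zeros(n_filters, dtype=np.float32),
            "W1": _he_init(rng, n_filters, (n_filters, fc_units)),
            "b1": np.zeros(fc_units, dtype=np.float32),
            "W2": _he_init(rng, fc_units, (fc_units, 2)),
            "b2": np.zeros(2, dtype=np.float32),
        }
        self._cache: dict = {}

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def _im2col(self, X: np.ndarray) -> np.ndarray:
        # (N, L, 4) -> (N, P, window*4) with P = L - window + 1
        cols = np.lib.stride_tricks.sliding_window_view(X, self.window, axis=1)
        # cols: (N, P, 4, window) -> (N, P, window, 4)
        return np.ascontiguousarray(cols.transpose(0, 1, 3, 2)).reshape(
            X.shape[0], -1, self.window * 4
        )

    def forward(self, X: np.ndarray, train: bool = False,
                drop_rng: np.random.Generator | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        cols = self._im2col(X)  # (N, P, w4)
        Z = cols @ self.params["Wc"] + self.params["bc"]  # (N, P, F)
        H = self.act(Z)
        pooled = H.mean(axis=1)  # (N, F)
        pre1 = pooled @ self.params["W1"] + self.params["b1"]
        A1 = self.act(pre1)
        if train and self.dropout > 0.0:
            mask = (drop_rng.random(A1.shape) >= self.dropout) / (1.0 - self.dropout)
            mask = mask.astype(np.float32)
            A1d = A1 * mask
        else:
            mask = None
            A1d = A1
        logits = A1d @ self.params["W2"] + self.params["b2"]
        probs = softmax(logits)
        self._cache = dict(cols=cols, Z=Z, pooled=pooled, pre1=pre1,
                           A1d=A1d, mask=mask, probs=probs)
        return probs

    def backward(self, y: np.ndarray) -> dict[str, np.ndarray]:
        c = self._cache
        n = len(y)
        d = c["probs"].copy()
        d[np.arange(n), y] -= 1.0
        d /= n  # (N, 2)
        grads = {
            "W2": c["A1d"].T @ d,
            "b2": d.sum(axis=0),
        }
        dA1 = d @ self.params["W2"].T
        if c["mask"] is not None:
            dA1 = dA1 * c["mask"]
        dpre1 = dA1 * self.dact(c["pre1"])
        grads["W1"] = c["pooled"].T @ dpre1
        grads["b1"] = dpre1.sum(axis=0)
        dpooled = dpre1 @ self.params["W1"].T  # (N, F)
        P = c["Z"].shape[1]
        dZ = (dpooled[:, None, :] / P) * self.dact(c["Z"])  # (N, P, F)
        w4 = self.window * 4
        grads["Wc"] = c["cols"].reshape(-1, w4).T @ dZ.reshape(-1, self.n_filters)
        grads["bc"] = dZ.sum(axis=(0, 1))
        _reg_grads(self.params, grads, self.l1, self.l2)
        return grads

    def predict_proba(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        out = []
        for s in range(0, len(X), batch):
            out.append(self.forward(X[s : s + batch], train=False))
        return np.concatenate(out) if out else np.empty((0, 2), dtype=np.float32)


def fit_classifier(model, X, y, *, epochs: int, batch_iter_fn, lr: float = 1e-3,
                   seed: int = 0, X_val=None, y_val=None, val_metric=None):
    """Generic Adam training loop shared by the CNN and the feature net.

    ``batch_iter_fn(epoch, rng)`` must yield index arrays covering one
    epoch (this is where class balancing is injected).  Returns a list of
    per-epoch records (epoch, mean loss, optional validation metric).
    Aborts with ``RuntimeError`` if the loss turns non-finite.
    """
    y = np.asarray(y)
    opt = Adam(model.params, lr=lr)
    ss = np.random.SeedSequence(seed)
    batch_rng, drop_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    history = []
    for epoch in range(epochs):
        losses = []
        for idx in batch_iter_fn(epoch, batch_rng):
            probs = model.forward(X[idx], train=True, drop_rng=drop_rng)
            loss = xent(probs, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            grads = model.backward(y[idx])
            opt.step(model.params, grads)
            losses.append(loss)
        rec = {"epoch": epoch, "loss": float(np.mean(losses)) if losses else np.nan}
        if X_val is not None and val_metric is not None:
            scores = model.predict_proba(X_val)[:, 1]
            rec["val_metric"] = float(val_metric(scores, y_val))
        history.append(rec)
    return history
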