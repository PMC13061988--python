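"""Shallow fully connected networks for range classification and
concentration regression, implemented directly on numpy.

The models are deliberately small (two or three hidden layers of 32-128
units) and are trained with Adam on mini-batches.  Classifier hidden layers
use batch normalisation, ReLU and dropout and are trained with categorical
cross-entropy on softmax outputs; quantifier hidden layers use ReLU and
dropout (no batch norm) and are trained with either mean squared error or a
per-sample absolute log1p error:

    L = (1/N) * sum_n |log(y_n + 1) - log(y'_n + 1)|,

i.e. the root and the square cancel per sample.  This per-sample form is
what :func:`rmsle_loss` computes; the conventional batch-level RMSLE
(square root of the mean squared log1p error) is available via
``rmsle_loss(..., batch_root=True)``.

Training is deterministic under a fixed seed: weight initialisation
(uniform fan-in), batch shuffling and dropout masks all derive from one
``numpy.random.Generator``.  After every epoch the full training set is
evaluated in inference mode (dropout off, batch-norm running statistics)
and the parameters achieving the lowest such loss are returned.
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

_EPS_PROB = 1e-12
_EPS_BN = 1e-5


# ---------------------------------------------------------------------------
# losses and activations
# ---------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for numerical stability."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cce_loss(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Categorical cross-entropy, mean over the batch.

    ``y_true`` holds one-hot rows, ``y_prob`` rows on the probability
    simplex.  Probabilities at the true class are clipped at 1e-12 (with a
    warning) so a confidently wrong prediction yields a finite loss.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_prob = np.asarray(y_prob, dtype=float)
    p_true = (y_true * y_prob).sum(axis=-1)
    if np.any(p_true <= 0):
        warnings.warn("predicted probability <= 0 at the true class; clipping",
                      RuntimeWarning, stacklevel=2)
    return float(-np.log(np.clip(p_true, _EPS_PROB, None)).mean())


def mse_loss(y: np.ndarray, y_pred: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    return float(((y - y_pred) ** 2).mean())


def rmsle_loss(y: np.ndarray, y_pred: np.ndarray, batch_root: bool = False) -> float:
    """Log1p error (natural log); per-sample absolute form by default.

    With ``batch_root=True`` returns the conventional batch-level RMSLE,
    sqrt(mean((log1p(y) - log1p(y'))**2)).
    """
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.any(y <= -1) or np.any(y_pred <= -1):
        raise ValueError("rmsle requires all values > -1")
    d = np.log1p(y) - np.log1p(y_pred)
    if batch_root:
        return float(np.sqrt((d ** 2).mean()))
    return float(np.abs(d).mean())


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Architecture, loss and training regimen of one network."""

    name: str
    biomarker: str
    stage: str                      # "classifier" | "quantifier"
    features: tuple[str, ...]       # feature-vector columns consumed
    hidden: tuple[int, ...]
    dropout: float
    loss: str                       # "cce" | "mse" | "rmsle"
    n_classes: int = 0              # classifiers only
    range_label: str = ""           # quantifiers: the gated range
    batchnorm: bool = False
    l2: float = 1e-3
    batch_size: int = 4
    lr: float = 1e-3
    lr_factor: float = 0.99
    lr_period: int = 10
    max_epochs: int = 500
    patience: int | None = None     # epochs without >= min_delta improvement
    min_delta: float = 1e-4
    target_transform: str = "none"  # "none" | "scale" | "zscore"
    target_scale: float = 1.0


@dataclass
class TargetTransform:
    """Invertible transform applied to regression targets before training."""

    kind: str = "none"
    scale: float = 1.0
    mean: float = 0.0
    sd: float = 1.0

    @classmethod
    def fit(cls, spec: ModelSpec, y: np.ndarray) -> "TargetTransform":
        if spec.target_transform == "scale":
            return cls("scale", scale=spec.target_scale)
        if spec.target_transform == "zscore":
            sd = float(y.std(ddof=0))
            return cls("zscore", mean=float(y.mean()), sd=sd if sd > 0 else 1.0)
        return cls()

    def apply(self, y):
        y = np.asarray(y, dtype=float)
        if self.kind == "scale":
            return y / self.scale
        if self.kind == "zscore":
            return (y - self.mean) / self.sd
        return y

    def invert(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "scale":
            return t * self.scale
        if self.kind == "zscore":
            return t * self.sd + self.mean
        return t


# ---------------------------------------------------------------------------
# parameters and forward/backward passes
# ---------------------------------------------------------------------------

def _init_params(spec: ModelSpec, n_in: int, rng: np.random.Generator) -> dict:
    sizes = [n_in, *spec.hidden]
    params: dict[str, np.ndarray] = {}
    for i in range(len(spec.hidden)):
        bound = 1.0 / np.sqrt(sizes[i])
        params[f"W{i}"] = rng.uniform(-bound, bound, size=(sizes[i], sizes[i + 1]))
        params[f"b{i}"] = np.zeros(sizes[i + 1])
        if spec.batchnorm:
            params[f"g{i}"] = np.ones(sizes[i + 1])
            params[f"beta{i}"] = np.zeros(sizes[i + 1])
    n_out = spec.n_classes if spec.stage == "classifier" else 1
    bound = 1.0 / np.sqrt(sizes[-1])
    params["Wout"] = rng.uniform(-bound, bound, size=(sizes[-1], n_out))
    params["bout"] = np.zeros(n_out)
    return params


def _forward(spec: ModelSpec, params: dict, bn_stats: dict, X: np.ndarray,
             training: bool, rng: np.random.Generator | None):
    """Forward pass; returns (output, cache) where output is logits or a
    regression column."""
    cache = {"X": X, "layers": []}
    a = X
    for i in range(len(spec.hidden)):
        z = a @ params[f"W{i}"] + params[f"b{i}"]
        layer = {"a_in": a, "z": z}
        if spec.batchnorm:
            if training:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                m = bn_stats["momentum"]
                bn_stats[f"mean{i}"] = (1 - m) * bn_stats[f"mean{i}"] + m * mu
                bn_stats[f"var{i}"] = (1 - m) * bn_stats[f"var{i}"] + m * var
            else:
                mu, var = bn_stats[f"mean{i}"], bn_stats[f"var{i}"]
            inv = 1.0 / np.sqrt(var + _EPS_BN)
            zhat = (z - mu) * inv
            z = params[f"g{i}"] * zhat + params[f"beta{i}"]
            layer.update(zhat=zhat, inv=inv, z_bn=z)
        h = np.maximum(z, 0.0)
        layer["relu_mask"] = z > 0
        if training and spec.dropout > 0:
            keep = 1.0 - spec.dropout
            mask = (rng.random(h.shape) < keep) / keep
            h = h * mask
            layer["drop_mask"] = mask
        layer["h"] = h
        cache["layers"].append(layer)
        a = h
    out = a @ params["Wout"] + params["bout"]
    cache["a_last"] = a
    return out, cache


def _backward(spec: ModelSpec, params: dict, cache: dict,
              d_out: np.ndarray) -> dict:
    """Gradients of the batch loss w.r.t. all parameters (L2 added later)."""
    grads: dict[str, np.ndarray] = {}
    grads["Wout"] = cache["a_last"].T @ d_out
    grads["bout"] = d_out.sum(axis=0)
    da = d_out @ params["Wout"].T
    for i in reversed(range(len(spec.hidden))):
        layer = cache["layers"][i]
        if "drop_mask" in layer:
            da = da * layer["drop_mask"]
        dz = da * layer["relu_mask"]
        if spec.batchnorm:
            n = dz.shape[0]
            zhat, inv = layer["zhat"], layer["inv"]
            grads[f"g{i}"] = (dz * zhat).sum(axis=0)
            grads[f"beta{i}"] = dz.sum(axis=0)
            dzhat = dz * params[f"g{i}"]
            dz = (inv / n) * (n * dzhat - dzhat.sum(axis=0)
                              - zhat * (dzhat * zhat).sum(axis=0))
        grads[f"W{i}"] = layer["a_in"].T @ dz
        grads[f"b{i}"] = dz.sum(axis=0)
        da = dz @ params[f"W{i}"].T
    return grads


def _loss_and_dout(spec: ModelSpec, out: np.ndarray, y: np.ndarray):
    """Batch loss and its gradient w.r.t. the network output."""
    n = out.shape[0]
    if spec.loss == "cce":
        probs = softmax(out)
        loss = cce_loss(y, probs)
        d_out = (probs - y) / n
    elif spec.loss == "mse":
        pred = out[:, 0]
        loss = mse_loss(y, pred)
        d_out = (2.0 * (pred - y) / n)[:, None]
    elif spec.loss == "rmsle":
        pred = np.maximum(out[:, 0], -1.0 + 1e-9)  # keep log1p in domain
        d = np.log1p(pred) - np.log1p(y)
        loss = float(np.abs(d).mean())
        d_out = (np.sign(d) / (1.0 + pred) / n)[:, None]
    else:
        raise ValueError(f"unknown loss {spec.loss}")
    return loss, d_out


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    spec: ModelSpec
    params: dict
    bn_stats: dict
    x_mean: np.ndarray
    x_sd: np.ndarray
    target: TargetTransform
    loss_trace: list[float]
    best_epoch: int
    seed: int

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out, _ = _forward(self.spec, self.params, self.bn_stats,
                          self._standardize(X), training=False, rng=None)
        return softmax(out)

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Class indices for classifiers, concentrations for quantifiers."""
        if self.spec.stage == "classifier":
            return self.predict_class(X)
        out, _ = _forward(self.spec, self.params, self.bn_stats,
                          self._standardize(X), training=False, rng=None)
        return self.target.invert(out[:, 0])


def _eval_loss(spec, params, bn_stats, X, y) -> float:
    out, _ = _forward(spec, params, bn_stats, X, training=False, rng=None)
    loss, _ = _loss_and_dout(spec, out, y)
    return loss


def train_model(spec: ModelSpec, X: np.ndarray, y: np.ndarray,
                seed: int = 0) -> TrainedModel:
    """Train one network; returns the lowest-training-loss checkpoint.

    ``y`` holds integer class indices for classifiers or concentrations
    (untransformed) for quantifiers.  Inputs are standardised to zero mean
    and unit variance with statistics frozen from this training set;
    regression targets pass through the spec's transform.  Quantifiers stop
    early once the epoch loss has not improved by at least ``min_delta``
    for ``patience`` consecutive epochs.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(spec.features):
        raise ValueError(f"X must be (n, {len(spec.features)})")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    Xs = (X - x_mean) / x_sd

    if spec.stage == "classifier":
        y_idx = np.asarray(y, dtype=int)
        present = np.unique(y_idx)
        if len(present) < spec.n_classes:
            raise ValueError(
                f"classifier {spec.name}: empty class in training data "
                f"(present: {present.tolist()} of {spec.n_classes})")
        y_t = np.eye(spec.n_classes)[y_idx]
        target = TargetTransform()
    else:
        y_raw = np.asarray(y, dtype=float)
        target = TargetTransform.fit(spec, y_raw)
        y_t = target.apply(y_raw)

    params = _init_params(spec, X.shape[1], rng)
    bn_stats = {"momentum": 0.1}
    for i, w in enumerate(spec.hidden):
        bn_stats[f"mean{i}"] = np.zeros(w)
        bn_stats[f"var{i}"] = np.ones(w)

    adam_m = {k: np.zeros_like(v) for k, v in params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0

    n = X.shape[0]
    trace: list[float] = []
    best_loss, best_epoch = np.inf, -1
    best_params = copy.deepcopy(params)
    best_bn = copy.deepcopy(bn_stats)
    since_improve = 0

    for epoch in range(spec.max_epochs):
        lr = spec.lr * spec.lr_factor ** (epoch // spec.lr_period)
        order = rng.permutation(n)
        for start in range(0, n, spec.batch_size):
            idx = order[start:start + spec.batch_size]
            out, cache = _forward(spec, params, bn_stats, Xs[idx],
                                  training=True, rng=rng)
            loss, d_out = _loss_and_dout(spec, out, y_t[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"{spec.name}: non-finite loss at epoch {epoch}; trace={trace[-5:]}")
            grads = _backward(spec, params, cache, d_out)
            step += 1
            for k in params:
                g = grads[k]
                if k.startswith("W"):
                    g = g + spec.l2 * params[k]
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * g
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * g * g
                mhat = adam_m[k] / (1 - b1 ** step)
                vhat = adam_v[k] / (1 - b2 ** step)
                params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

        epoch_loss = _eval_loss(spec, params, bn_stats, Xs, y_t)
        trace.append(epoch_loss)
        if epoch_loss < best_loss - spec.min_delta:
            since_improve = 0
        else:
            since_improve += 1
        if epoch_loss < best_loss:
            best_loss, best_epoch = epoch_loss, epoch
            best_params = copy.deepcopy(params)
            best_bn = copy.deepcopy(bn_stats)
        if spec.patience is not None and since_improve >= spec.patience:
            logger.debug("%s: early stop at epoch %d (best %d)",
                         spec.name, epoch, best_epoch)
            break

    return TrainedModel(spec=spec, params=best_params, bn_stats=best_bn,
                        x_mean=x_mean, x_sd=x_sd, target=target,
                        loss_trace=trace, best_epoch=best_epoch, seed=seed)
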