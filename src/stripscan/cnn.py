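"""A compact convolutional network over tabular texture-feature vectors.

Each 22-feature sample is reshaped into a (22, 1) single-channel "image" and
passed through three conv(3x3, same padding) -> batch-norm -> ReLU blocks,
with 2x2 stride-2 max pooling (asymmetric padding (top, bottom, left,
right) = (0, 1, 0, 1)) after the first two blocks, then a fully connected
softmax layer with one unit per class.  The spatial extent along the
feature axis evolves 22 -> 11 -> 6 under the usual pooling arithmetic
``floor((size + pad_sum - window) / stride) + 1``; the width stays 1.

Training is plain stochastic gradient descent with momentum on the
cross-entropy loss, with per-epoch shuffling and a stratified validation
split monitored each epoch.  After training the network doubles as a
feature extractor: :meth:`TabularCNNClassifier.transform` returns the
flattened activations feeding the fully connected layer (the penultimate
representation), which downstream classical classifiers consume as "CNN
features".

Everything is implemented directly in numpy; the arrays involved
(thousands of samples x 22 features) are small enough that vectorised
batch operations train the network in seconds on one CPU.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = ["pool_output_size", "TabularCNNClassifier"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


def pool_output_size(size: int, window: int = 2, stride: int = 2, pad_sum: int = 1) -> int:
    """Closed-form output length of a pooling window sweep."""
    out = (size + pad_sum - window) // stride + 1
    if out < 1:
        raise ValueError(
            f"pooling reduces size {size} below 1 (window={window}, stride={stride})"
        )
    return out


# ---------------------------------------------------------------------------
# layer primitives (forward + backward), all operating on (N, C, H, W)

def _conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    n, c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((n, w.shape[0], h, wd))
    for i in range(3):
        for j in range(3):
            out += np.einsum("nchw,oc->nohw", xp[:, :, i : i + h, j : j + wd], w[:, :, i, j])
    out += b[None, :, None, None]
    return out, xp


def _conv3x3_backward(dout: np.ndarray, xp: np.ndarray, w: np.ndarray):
    n, co, h, wd = dout.shape
    dw = np.zeros_like(w)
    dxp = np.zeros_like(xp)
    for i in range(3):
        for j in range(3):
            patch = xp[:, :, i : i + h, j : j + wd]
            dw[:, :, i, j] = np.einsum("nohw,nchw->oc", dout, patch)
            dxp[:, :, i : i + h, j : j + wd] += np.einsum("nohw,oc->nchw", dout, w[:, :, i, j])
    db = dout.sum(axis=(0, 2, 3))
    return dxp[:, :, 1:-1, 1:-1], dw, db


def _bn_forward(x, gamma, beta, running, training: bool):
    if training:
        mu = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running["mean"] = (1 - _BN_MOMENTUM) * running["mean"] + _BN_MOMENTUM * mu
        running["var"] = (1 - _BN_MOMENTUM) * running["var"] + _BN_MOMENTUM * var
    else:
        mu, var = running["mean"], running["var"]
    std = np.sqrt(var + _BN_EPS)
    xhat = (x - mu[None, :, None, None]) / std[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    cache = (xhat, std, gamma)
    return out, cache


def _bn_backward(dout, cache):
    xhat, std, gamma = cache
    m = dout.shape[0] * dout.shape[2] * dout.shape[3]
    dgamma = np.sum(dout * xhat, axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    dxhat = dout * gamma[None, :, None, None]
    dx = (
        dxhat
        - dxhat.mean(axis=(0, 2, 3), keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
    ) / std[None, :, None, None]
    return dx, dgamma, dbeta


def _pool_forward(x, pad=(0, 1, 0, 1)):
    n, c, h, w = x.shape
    ho = pool_output_size(h, pad_sum=pad[0] + pad[1])
    wo = pool_output_size(w, pad_sum=pad[2] + pad[3])
    xp = np.pad(
        x, ((0, 0), (0, 0), (pad[0], pad[1]), (pad[2], pad[3])),
        constant_values=-np.inf,
    )
    win = xp[:, :, : 2 * ho, : 2 * wo].reshape(n, c, ho, 2, wo, 2)
    flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    cache = (arg, x.shape, pad, (ho, wo))
    return out, cache


def _pool_backward(dout, cache):
    arg, xshape, pad, (ho, wo) = cache
    n, c, h, w = xshape
    hp, wp = pad[0] + h + pad[1], pad[2] + w + pad[3]
    dxp = np.zeros((n, c, hp, wp))
    di, dj = arg // 2, arg % 2
    hh = (np.arange(ho) * 2)[None, None, :, None] + di
    ww = (np.arange(wo) * 2)[None, None, None, :] + dj
    nn = np.arange(n)[:, None, None, None]
    cc = np.arange(c)[None, :, None, None]
    np.add.at(dxp, (nn, cc, hh, ww), dout)
    return dxp[:, :, pad[0] : pad[0] + h, pad[2] : pad[2] + w]


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TabularCNNClassifier(ClassifierMixin, TransformerMixin, BaseEstimator):
    """CNN classifier / feature extractor for fixed-length feature vectors.

    Parameters
    ----------
    conv_filters : tuple of 3 ints, default (8, 16, 32)
        Output channels of the three convolutional blocks.
    lr : float, default 0.01
        SGD learning rate.
    max_epochs : int, default 10
    batch_size : int, default 32
    momentum : float, default 0.9
        Momentum coefficient of the SGD update.
    val_fraction : float, default 0.15
        Stratified fraction held out for per-epoch validation monitoring.
    shuffle_each_epoch : bool, default True
    standardise : bool, default True
        Z-score features with training statistics before the network; kept
        on by default for optimiser stability across feature scales.
    random_state : int, default 0

    Attributes
    ----------
    classes_ : ndarray of shape (n_classes,)
    history_ : list of dict with per-epoch train/val loss and accuracy.
    n_cnn_features_ : int
        Dimension of the penultimate representation returned by
        :meth:`transform` (``pooled_length * conv_filters[2]``).
    """

    def __init__(self, conv_filters=(8, 16, 32), lr: float = 0.01,
                 max_epochs: int = 10, batch_size: int = 32, momentum: float = 0.9,
                 val_fraction: float = 0.15, shuffle_each_epoch: bool = True,
                 standardise: bool = True, random_state: int = 0):
        self.conv_filters = conv_filters
        self.lr = lr
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.momentum = momentum
        self.val_fraction = val_fraction
        self.shuffle_each_epoch = shuffle_each_epoch
        self.standardise = standardise
        self.random_state = random_state

    # -- construction -------------------------------------------------------

    def _build(self, n_features: int, n_classes: int, rng: np.random.Generator):
        f1, f2, f3 = self.conv_filters
        h1 = pool_output_size(n_features)          # after pool 1
        h2 = pool_output_size(h1)                  # after pool 2
        self._shapes_ = (n_features, h1, h2)
        fc_in = h2 * 1 * f3
        self.n_cnn_features_ = fc_in

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        p = {}
        for k, (cin, cout) in enumerate(((1, f1), (f1, f2), (f2, f3)), start=1):
            p[f"w{k}"] = he((cout, cin, 3, 3), 9 * cin)
            p[f"b{k}"] = np.zeros(cout)
            p[f"g{k}"] = np.ones(cout)
            p[f"be{k}"] = np.zeros(cout)
        p["wfc"] = he((fc_in, n_classes), fc_in)
        p["bfc"] = np.zeros(n_classes)
        self.params_ = p
        self.bn_running_ = {
            k: {"mean": np.zeros(c), "var": np.ones(c)}
            for k, c in (("1", f1), ("2", f2), ("3", f3))
        }

    def _forward(self, x4, training: bool):
        p = self.params_
        caches = {}
        a = x4
        for k in ("1", "2", "3"):
            a, caches[f"xp{k}"] = _conv3x3_forward(a, p[f"w{k}"], p[f"b{k}"])
            a, caches[f"bn{k}"] = _bn_forward(a, p[f"g{k}"], p[f"be{k}"],
                                              self.bn_running_[k], training)
            caches[f"relu{k}"] = a > 0
            a = a * caches[f"relu{k}"]
            if k in ("1", "2"):
                a, caches[f"pool{k}"] = _pool_forward(a)
        flat = a.reshape(a.shape[0], -1)
        caches["flat_shape"] = a.shape
        caches["flat"] = flat
        logits = flat @ p["wfc"] + p["bfc"]
        return logits, caches

    def _backward(self, probs, onehot, caches):
        p = self.params_
        n = probs.shape[0]
        grads = {}
        dlogits = (probs - onehot) / n
        grads["wfc"] = caches["flat"].T @ dlogits
        grads["bfc"] = dlogits.sum(axis=0)
        da = (dlogits @ p["wfc"].T).reshape(caches["flat_shape"])
        for k in ("3", "2", "1"):
            if k in ("1", "2"):
                da = _pool_backward(da, caches[f"pool{k}"])
            da = da * caches[f"relu{k}"]
            da, grads[f"g{k}"], grads[f"be{k}"] = _bn_backward(da, caches[f"bn{k}"])
            da, grads[f"w{k}"], grads[f"b{k}"] = _conv3x3_backward(
                da, caches[f"xp{k}"], p[f"w{k}"]
            )
        return grads

    # -- sklearn API --------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError(f"expected 2-D feature matrix, got shape {X.shape}")
        if X.shape[0] < self.batch_size:
            raise ValueError(
                f"need at least batch_size={self.batch_size} samples, got {X.shape[0]}"
            )
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n_classes = len(self.classes_)
        rng = np.random.default_rng(self.random_state)

        if self.standardise:
            self.feat_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.feat_scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.feat_mean_ = np.zeros(X.shape[1])
            self.feat_scale_ = np.ones(X.shape[1])
        Xs = (X - self.feat_mean_) / self.feat_scale_

        self.n_features_in_ = X.shape[1]
        self._build(X.shape[1], n_classes, rng)

        # stratified validation split for epoch monitoring
        val_idx: list[int] = []
        if 0 < self.val_fraction < 1:
            for c in range(n_classes):
                members = np.flatnonzero(y_idx == c)
                members = rng.permutation(members)
                n_val = int(round(self.val_fraction * len(members)))
                val_idx.extend(members[:n_val].tolist())
        val_mask = np.zeros(len(y_idx), dtype=bool)
        val_mask[val_idx] = True
        tr = np.flatnonzero(~val_mask)
        va = np.flatnonzero(val_mask)

        velocity = {k: np.zeros_like(v) for k, v in self.params_.items()}
        onehot_all = np.eye(n_classes)[y_idx]
        self.history_ = []
        for _epoch in range(self.max_epochs):
            order = rng.permutation(tr) if self.shuffle_each_epoch else tr
            losses = []
            correct = 0
            for start in range(0, len(order), self.batch_size):
                bi = order[start : start + self.batch_size]
                xb = Xs[bi].reshape(len(bi), 1, -1, 1)
                logits, caches = self._forward(xb, training=True)
                probs = _softmax(logits)
                loss = -np.mean(
                    np.log(probs[np.arange(len(bi)), y_idx[bi]] + 1e-12)
                )
                if not np.isfinite(loss):
                    raise ArithmeticError(
                        f"non-finite training loss at epoch {_epoch}: {loss}"
                    )
                losses.append(loss * len(bi))
                correct += int((probs.argmax(axis=1) == y_idx[bi]).sum())
                grads = self._backward(probs, onehot_all[bi], caches)
                for k in self.params_:
                    velocity[k] = self.momentum * velocity[k] - self.lr * grads[k]
                    self.params_[k] = self.params_[k] + velocity[k]
            rec = {
                "epoch": _epoch + 1,
                "train_loss": float(np.sum(losses) / len(order)),
                "train_acc": correct / len(order),
            }
            if len(va):
                vprobs = self._predict_proba_std(Xs[va])
                vloss = -np.mean(np.log(vprobs[np.arange(len(va)), y_idx[va]] + 1e-12))
                rec["val_loss"] = float(vloss)
                rec["val_acc"] = float((vprobs.argmax(axis=1) == y_idx[va]).mean())
            self.history_.append(rec)
        return self

    def _predict_proba_std(self, Xs: np.ndarray) -> np.ndarray:
        out = []
        for start in range(0, len(Xs), 512):
            xb = Xs[start : start + 512].reshape(-1, 1, Xs.shape[1], 1)
            logits, _ = self._forward(xb, training=False)
            out.append(_softmax(logits))
        return np.concatenate(out) if out else np.empty((0, len(self.classes_)))

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=np.float64)
        self._check_schema(X)
        Xs = (X - self.feat_mean_) / self.feat_scale_
        return self._predict_proba_std(Xs)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.predict_proba(X).argmax(axis=1)]

    def transform(self, X) -> np.ndarray:
        """Penultimate activations ("CNN features"), one row per sample."""
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=np.float64)
        self._check_schema(X)
        Xs = (X - self.feat_mean_) / self.feat_scale_
        out = []
        for start in range(0, len(Xs), 512):
            xb = Xs[start : start + 512].reshape(-1, 1, Xs.shape[1], 1)
            _, caches = self._forward(xb, training=False)
            out.append(caches["flat"])
        return np.concatenate(out) if out else np.empty((0, self.n_cnn_features_))

    def _check_schema(self, X: np.ndarray) -> None:
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} feature columns, got shape {X.shape}"
            )
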