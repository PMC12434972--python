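"""A small 1-D convolutional network for spectral feature vectors.

The ordered vector of vegetation-index values is treated as a 1-D
sequence (registry order): two convolution blocks (kernel 3, same
padding, ReLU; max-pool of 2 after the first) followed by a dense
softmax layer, trained with cross-entropy and Adam.  Implemented
directly in numpy (forward and backward passes), sized for the few
dozen features and a few hundred trees typical of a crown-level survey.
Fully deterministic given ``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted


def _patches(x: np.ndarray, kernel: int) -> np.ndarray:
    """Sliding windows with zero 'same' padding: (n, L, C) -> (n, L, k*C)."""
    n, L, C = x.shape
    half = kernel // 2
    xp = np.zeros((n, L + 2 * half, C), dtype=x.dtype)
    xp[:, half : half + L] = x
    out = np.empty((n, L, kernel, C), dtype=x.dtype)
    for t in range(kernel):
        out[:, :, t, :] = xp[:, t : t + L, :]
    return out.reshape(n, L, kernel * C)


class Conv1DNetClassifier(BaseEstimator, ClassifierMixin):
    """conv(k3, c1) -> ReLU -> maxpool(2) -> conv(k3, c2) -> ReLU -> dense."""

    def __init__(
        self,
        channels1: int = 16,
        channels2: int = 32,
        kernel: int = 3,
        lr: float = 0.01,
        epochs: int = 120,
        batch_size: int = 32,
        weight_decay: float = 1e-4,
        max_retries: int = 3,
        random_state: int = 0,
    ):
        self.channels1 = channels1
        self.channels2 = channels2
        self.kernel = kernel
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.max_retries = max_retries
        self.random_state = random_state

    # ---------------------------------------------------------------- core
    def _init_params(self, p: int, k: int, rng: np.random.Generator):
        c1, c2, ks = self.channels1, self.channels2, self.kernel
        p2 = (p + 1) // 2
        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)
        return {
            "W1": he((ks * 1, c1), ks),
            "b1": np.zeros(c1),
            "W2": he((ks * c1, c2), ks * c1),
            "b2": np.zeros(c2),
            "W3": he((p2 * c2, k), p2 * c2),
            "b3": np.zeros(k),
        }

    def _forward(self, X: np.ndarray, params, cache: bool = False):
        n, p = X.shape
        x0 = X[:, :, None]
        pat1 = _patches(x0, self.kernel)  # (n, p, k)
        z1 = pat1 @ params["W1"] + params["b1"]  # (n, p, c1)
        a1 = np.maximum(z1, 0.0)
        # max-pool length 2 (pad odd tails with -inf)
        p2 = (p + 1) // 2
        a1p = np.full((n, 2 * p2, self.channels1), -np.inf)
        a1p[:, :p] = a1
        pooled = a1p.reshape(n, p2, 2, self.channels1)
        arg = pooled.argmax(axis=2)
        a1m = pooled.max(axis=2)
        pat2 = _patches(a1m, self.kernel)  # (n, p2, k*c1)
        z2 = pat2 @ params["W2"] + params["b2"]
        a2 = np.maximum(z2, 0.0)
        flat = a2.reshape(n, -1)
        logits = flat @ params["W3"] + params["b3"]
        logits -= logits.max(axis=1, keepdims=True)
        ez = np.exp(logits)
        proba = ez / ez.sum(axis=1, keepdims=True)
        if not cache:
            return proba
        return proba, {
            "pat1": pat1, "z1": z1, "arg": arg, "a1m": a1m,
            "pat2": pat2, "z2": z2, "flat": flat, "p": p, "p2": p2,
        }

    def _backward(self, proba, Y, params, c):
        n = proba.shape[0]
        d_logits = (proba - Y) / n
        g = {
            "W3": c["flat"].T @ d_logits,
            "b3": d_logits.sum(axis=0),
        }
        d_flat = d_logits @ params["W3"].T
        d_a2 = d_flat.reshape(n, c["p2"], self.channels2)
        d_z2 = d_a2 * (c["z2"] > 0)
        g["W2"] = np.einsum("nlk,nlc->kc", c["pat2"], d_z2)
        g["b2"] = d_z2.sum(axis=(0, 1))
        # gradient through the second conv's patches back to a1m
        d_pat2 = d_z2 @ params["W2"].T  # (n, p2, k*c1)
        d_a1m = np.zeros_like(c["a1m"])
        half = self.kernel // 2
        d_pat2 = d_pat2.reshape(n, c["p2"], self.kernel, self.channels1)
        for t in range(self.kernel):
            src = d_pat2[:, :, t, :]
            lo = t - half
            if lo < 0:
                d_a1m[:, : lo + c["p2"], :] += src[:, -lo:, :]
            elif lo == 0:
                d_a1m += src
            else:
                d_a1m[:, lo:, :] += src[:, : c["p2"] - lo, :]
        # unpool
        p, p2 = c["p"], c["p2"]
        d_a1p = np.zeros((n, 2 * p2, self.channels1))
        idx_n, idx_l, idx_c = np.meshgrid(
            np.arange(n), np.arange(p2), np.arange(self.channels1), indexing="ij"
        )
        d_a1p[idx_n, 2 * idx_l + c["arg"], idx_c] = d_a1m
        d_a1 = d_a1p[:, :p, :]
        d_z1 = d_a1 * (c["z1"] > 0)
        g["W1"] = np.einsum("nlk,nlc->kc", c["pat1"], d_z1)
        g["b1"] = d_z1.sum(axis=(0, 1))
        return g

    # ----------------------------------------------------------------- API
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, yi = np.unique(y, return_inverse=True)
        n, p = X.shape
        k = len(self.classes_)
        Y = np.eye(k)[yi]
        lr = self.lr
        for attempt in range(self.max_retries + 1):
            rng = np.random.default_rng(
                (self.random_state + 7919 * attempt) % (2**31)
            )
            params = self._init_params(p, k, rng)
            m = {key: np.zeros_like(v) for key, v in params.items()}
            v = {key: np.zeros_like(val) for key, val in params.items()}
            b1, b2, eps = 0.9, 0.999, 1e-8
            step = 0
            ok = True
            for _ in range(self.epochs):
                order = rng.permutation(n)
                for s in range(0, n, self.batch_size):
                    idx = order[s : s + self.batch_size]
                    proba, cache = self._forward(X[idx], params, cache=True)
                    if not np.all(np.isfinite(proba)):
                        ok = False
                        break
                    grads = self._backward(proba, Y[idx], params, cache)
                    step += 1
                    for key in params:
                        gkey = grads[key] + self.weight_decay * params[key]
                        m[key] = b1 * m[key] + (1 - b1) * gkey
                        v[key] = b2 * v[key] + (1 - b2) * gkey**2
                        mh = m[key] / (1 - b1**step)
                        vh = v[key] / (1 - b2**step)
                        params[key] -= lr * mh / (np.sqrt(vh) + eps)
                if not ok:
                    break
            if ok:
                self.params_ = params
                self.n_features_in_ = p
                return self
            lr /= 2.0  # diverged: retry with a smaller step
        raise RuntimeError("1D-CNN training failed to converge after retries")

    def predict_proba(self, X):
        check_is_fitted(self, "params_")
        return self._forward(np.asarray(X, dtype=float), self.params_)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
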