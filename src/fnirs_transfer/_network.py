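"""NumPy implementation of the compact CNN: forward, backprop, Adam.

Convolutions are evaluated as strided patch extraction followed by a
tensor contraction (an im2col/GEMM formulation), which keeps the whole
training loop inside BLAS.  The engine supports exactly the canonical
topology conv - conv - maxpool - flatten - dense - output with named
parameter groups so individual groups can be frozen during fine-tuning.

Determinism: initialization and mini-batch shuffling derive from explicit
integer seeds; two networks built and trained with the same seeds and data
hold bit-identical parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import TrainingError, ValidationError

GROUPS = ("conv1", "conv2", "dense", "output")


def examples_to_input(X: np.ndarray, dtype=np.float32) -> np.ndarray:
    """Map epoched examples (B, channels, chromophores, samples) to network
    input (B, H=channels, W=samples, depth=chromophores)."""
    return np.ascontiguousarray(np.transpose(X, (0, 1, 3, 2)), dtype=dtype)


def _conv_forward(x, W, b, stride):
    """im2col convolution; returns activations and the patch matrix.

    The patch matrix (rows = output positions, cols = fh*fw*C receptive
    field) is materialized once and reused by the parameter-gradient GEMM.
    """
    sh, sw = stride
    fh, fw, _, k = W.shape
    p6 = sliding_window_view(x, (fh, fw), axis=(1, 2))[:, ::sh, ::sw]
    B, Ho, Wo = p6.shape[:3]
    patches = np.ascontiguousarray(p6.transpose(0, 1, 2, 4, 5, 3)).reshape(B * Ho * Wo, -1)
    y = (patches @ W.reshape(-1, k)).reshape(B, Ho, Wo, k) + b
    return y, patches


def _conv_backward_params(patches, dy, w_shape):
    k = dy.shape[-1]
    dym = dy.reshape(-1, k)
    return (patches.T @ dym).reshape(w_shape), dym.sum(axis=0)


def _conv_backward_input(x_shape, W, dy, stride):
    sh, sw = stride
    fh, fw = W.shape[:2]
    B, Ho, Wo, _ = dy.shape
    dx = np.zeros(x_shape, dtype=dy.dtype)
    for i in range(fh):
        for j in range(fw):
            # W[i, j]: (C, K); dy: (B, Ho, Wo, K) -> (B, Ho, Wo, C)
            contrib = np.tensordot(dy, W[i, j], axes=([3], [1]))
            dx[:, i : i + Ho * sh : sh, j : j + Wo * sw : sw, :] += contrib
    return dx


class Network:
    """Trainable handle for a validated :class:`~fnirs_transfer.model.CnnSpec`."""

    def __init__(self, spec, rng_seed: int = 0, dtype=np.float32):
        from .model import validate_spec  # local import to avoid a cycle

        self.spec = spec
        self.rng_seed = int(rng_seed)
        self.dtype = np.dtype(dtype)
        report = validate_spec(spec)
        self._shapes = {r["name"]: r["output_shape"] for r in report.rows}
        self.n_params = report.total_params_standard

        convs = [l for l in spec.layers if l.kind == "conv"]
        pool = next(l for l in spec.layers if l.kind == "maxpool")
        dense = next(l for l in spec.layers if l.kind == "dense")
        out = spec.layers[-1]
        self._conv_strides = [tuple(l.stride or (1, 1)) for l in convs]
        self._pool_size = tuple(pool.size)

        ch, depth, samples = spec.input_shape
        rng = np.random.default_rng(self.rng_seed)
        self.params: dict[str, dict[str, np.ndarray]] = {}
        d = depth
        for name, l in zip(("conv1", "conv2"), convs):
            fan_in = l.size[0] * l.size[1] * d
            self.params[name] = {
                "W": rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(*l.size, d, l.filters)).astype(self.dtype),
                "b": np.zeros(l.filters, dtype=self.dtype),
            }
            d = l.filters
        flat = int(np.prod(self._shapes["maxpool"]))
        self.params["dense"] = {
            "W": rng.normal(0.0, np.sqrt(2.0 / flat), size=(flat, dense.units)).astype(self.dtype),
            "b": np.zeros(dense.units, dtype=self.dtype),
        }
        self.params["output"] = {
            "W": rng.normal(0.0, np.sqrt(1.0 / dense.units), size=(dense.units, spec.n_classes)).astype(self.dtype),
            "b": np.zeros(spec.n_classes, dtype=self.dtype),
        }
        self.trainable: dict[str, bool] = {g: True for g in GROUPS}

    # -- forward -----------------------------------------------------------
    def _forward(self, x, want_cache: bool = False):
        cache = {}
        a = x
        for name, stride in zip(("conv1", "conv2"), self._conv_strides):
            z, patches = _conv_forward(a, self.params[name]["W"], self.params[name]["b"], stride)
            a = np.maximum(z, 0.0)
            if want_cache:
                cache[name] = {"patches": patches, "pre": z}
            if name == "conv1":
                cache["conv1_out_shape"] = a.shape
        ph, pw = self._pool_size
        B, H, W, C = a.shape
        ar = a.reshape(B, H // ph, ph, W // pw, pw, C)
        ar = ar.transpose(0, 1, 3, 5, 2, 4).reshape(B, H // ph, W // pw, C, ph * pw)
        pool_idx = np.argmax(ar, axis=-1)
        pooled = np.take_along_axis(ar, pool_idx[..., None], axis=-1)[..., 0]
        flat = pooled.reshape(B, -1)
        h = flat @ self.params["dense"]["W"] + self.params["dense"]["b"]
        hr = np.maximum(h, 0.0)
        logits = hr @ self.params["output"]["W"] + self.params["output"]["b"]
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        if want_cache:
            cache.update(
                pool_in_shape=a.shape, pool_idx=pool_idx, flat=flat, dense_pre=h, dense_act=hr
            )
            return probs, cache
        return probs

    def predict_proba(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities for epoched examples (B, ch, chromo, samples)."""
        x = examples_to_input(np.asarray(X), dtype=self.dtype)
        return np.concatenate(
            [self._forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class indices; ties break to the lowest class index."""
        return np.argmax(self.predict_proba(X), axis=1)

    # -- backward ----------------------------------------------------------
    def _backward(self, x, y_onehot, cache, probs):
        B = x.shape[0]
        grads = {}
        dlogits = (probs - y_onehot) / B
        grads["output"] = {
            "W": cache["dense_act"].T @ dlogits,
            "b": dlogits.sum(axis=0),
        }
        dh = (dlogits @ self.params["output"]["W"].T) * (cache["dense_pre"] > 0)
        grads["dense"] = {"W": cache["flat"].T @ dh, "b": dh.sum(axis=0)}
        dflat = dh @ self.params["dense"]["W"].T
        # un-pool
        Bp, Ho, Wo, C = cache["pool_idx"].shape
        ph, pw = self._pool_size
        dpool = dflat.reshape(Bp, Ho, Wo, C)
        dun = np.zeros((Bp, Ho, Wo, C, ph * pw))
        np.put_along_axis(dun, cache["pool_idx"][..., None], dpool[..., None], axis=-1)
        H, W = cache["pool_in_shape"][1:3]
        da = (
            dun.reshape(Bp, Ho, Wo, C, ph, pw)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(Bp, H, W, C)
        )
        dz2 = da * (cache["conv2"]["pre"] > 0)
        w2 = self.params["conv2"]["W"]
        dW2, db2 = _conv_backward_params(cache["conv2"]["patches"], dz2, w2.shape)
        grads["conv2"] = {"W": dW2, "b": db2}
        da = _conv_backward_input(
            cache["conv1_out_shape"], w2, dz2, self._conv_strides[1]
        )
        dz1 = da * (cache["conv1"]["pre"] > 0)
        dW1, db1 = _conv_backward_params(
            cache["conv1"]["patches"], dz1, self.params["conv1"]["W"].shape
        )
        grads["conv1"] = {"W": dW1, "b": db1}
        return grads

    # -- training ----------------------------------------------------------
    def train(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        milestones: tuple = (),
        on_milestone=None,
    ) -> list[float]:
        """Mini-batch Adam on softmax cross-entropy; returns per-epoch loss.

        Frozen parameter groups receive no updates.  ``epochs == 0`` is a
        no-op that leaves every parameter untouched.  When ``milestones``
        and ``on_milestone`` are given, ``on_milestone(completed_epochs)``
        is called after each listed epoch count — optimizer state carries
        straight through, so the run is one continuous trajectory observed
        at several budgets.
        """
        if epochs < 0:
            raise ValidationError("epochs must be >= 0")
        if epochs == 0:
            return []
        if not any(self.trainable.values()):
            raise TrainingError("no trainable parameters: every group is frozen")
        y = np.asarray(y, dtype=int)
        if y.min() < 0 or y.max() >= self.spec.n_classes:
            raise ValidationError("labels must lie in [0, n_classes)")
        x_all = examples_to_input(np.asarray(X), dtype=self.dtype)
        onehot = np.eye(self.spec.n_classes, dtype=self.dtype)[y]
        rng = np.random.default_rng(seed)
        m = {g: {k: np.zeros_like(v) for k, v in p.items()} for g, p in self.params.items()}
        v = {g: {k: np.zeros_like(vv) for k, vv in p.items()} for g, p in self.params.items()}
        t = 0
        log: list[float] = []
        n = len(x_all)
        marks = set(milestones)
        for epoch_i in range(epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x_all[idx], onehot[idx]
                probs, cache = self._forward(xb, want_cache=True)
                loss = -np.mean(np.log(np.sum(probs * yb, axis=1) + 1e-12))
                losses.append(loss)
                grads = self._backward(xb, yb, cache, probs)
                t += 1
                for g in GROUPS:
                    if not self.trainable[g]:
                        continue
                    for k in self.params[g]:
                        m[g][k] = beta1 * m[g][k] + (1 - beta1) * grads[g][k]
                        v[g][k] = beta2 * v[g][k] + (1 - beta2) * grads[g][k] ** 2
                        mhat = m[g][k] / (1 - beta1**t)
                        vhat = v[g][k] / (1 - beta2**t)
                        self.params[g][k] -= lr * mhat / (np.sqrt(vhat) + eps)
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise TrainingError(
                    f"training diverged (loss={epoch_loss}) with seed={seed}, lr={lr}, "
                    f"batch_size={batch_size}, epochs={epochs}"
                )
            log.append(epoch_loss)
            if on_milestone is not None and (epoch_i + 1) in marks:
                on_milestone(epoch_i + 1)
        return log

    # -- parameter access --------------------------------------------------
    def get_params(self) -> dict:
        return {g: {k: v.copy() for k, v in p.items()} for g, p in self.params.items()}

    def set_params(self, params: dict) -> None:
        for g, p in params.items():
            if g not in self.params:
                raise ValidationError(f"unknown parameter group {g!r}")
            for k, arr in p.items():
                if self.params[g][k].shape != arr.shape:
                    raise ValidationError(
                        f"shape mismatch for {g}.{k}: {arr.shape} vs {self.params[g][k].shape}"
                    )
                self.params[g][k] = np.array(arr, dtype=self.dtype)

    def param_hashes(self) -> dict[str, str]:
        """Stable per-group content hash, for freeze verification."""
        out = {}
        for g, p in self.params.items():
            h = hashlib.sha256()
            for k in sorted(p):
                h.update(np.ascontiguousarray(p[k]).tobytes())
            out[g] = h.hexdigest()
        return out

    def count_params(self) -> int:
        return int(sum(arr.size for p in self.params.values() for arr in p.values()))
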