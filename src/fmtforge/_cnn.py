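"""A small convolutional network over taxonomy images, in pure numpy.

Two valid-padding convolution layers (ReLU), a 1x2 max-pool, then a dense
head that also receives the sample covariates. Trained with Adam on
mini-batches, early-stopped on a recipient-grouped validation split.
Deterministic for a fixed seed. Sized for hundreds of samples on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np


@dataclasses.dataclass
class CNNConfig:
    channels: tuple[int, int] = (8, 16)
    kernel: tuple[int, int] = (2, 3)
    pool_width: int = 2
    hidden: int = 32
    dropout: float = 0.2
    lr: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 150
    patience: int = 20
    val_fraction: float = 0.15
    weight_decay: float = 1e-5
    min_width: int = 8  # images narrower than this are zero-padded


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H-kh+1, W-kw+1, C*kh*kw) patch matrix."""
    n, c, h, w = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, c, oh, ow, kh, kw), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh, ow, c * kh * kw)


def _col2im(dpatches: np.ndarray, x_shape, kh: int, kw: int) -> np.ndarray:
    n, c, h, w = x_shape
    oh, ow = h - kh + 1, w - kw + 1
    dp = dpatches.reshape(n, oh, ow, c, kh, kw)
    dx = np.zeros(x_shape)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + oh, j : j + ow] += dp[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dx


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.lr = lr
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


class ConvImageNet:
    """Convolutional regressor/classifier over (levels x leaves) images."""

    def __init__(self, task_type: str = "regression", config: CNNConfig | None = None, seed: int = 0):
        if task_type not in ("regression", "binary"):
            raise ValueError(f"unknown task_type {task_type!r}")
        self.task_type = task_type
        self.config = config or CNNConfig()
        self.seed = int(seed)
        self.params: dict[str, np.ndarray] | None = None
        self._y_loc = 0.0  # target centring (regression)
        self._y_scale = 1.0
        self._x_loc: np.ndarray | float = 0.0  # per-pixel input standardization
        self._x_scale: np.ndarray | float = 1.0
        self._c_loc: np.ndarray | float = 0.0
        self._c_scale: np.ndarray | float = 1.0

    # -- shapes -------------------------------------------------------------
    def _pad(self, images: np.ndarray) -> np.ndarray:
        w = images.shape[2]
        if w >= self.config.min_width:
            return images
        out = np.zeros((images.shape[0], images.shape[1], self.config.min_width))
        out[:, :, :w] = images
        return out

    def _feature_dim(self, h: int, w: int) -> int:
        kh, kw = self.config.kernel
        c1, c2 = self.config.channels
        h2, w2 = h - 2 * (kh - 1), w - 2 * (kw - 1)
        return c2 * h2 * (w2 // self.config.pool_width)

    def _init_params(self, h: int, w: int, n_cov: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        kh, kw = self.config.kernel
        c1, c2 = self.config.channels
        flat = self._feature_dim(h, w) + n_cov

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        return {
            "W1": he((c1, 1 * kh * kw), 1 * kh * kw),
            "b1": np.zeros(c1),
            "W2": he((c2, c1 * kh * kw), c1 * kh * kw),
            "b2": np.zeros(c2),
            "W3": he((flat, self.config.hidden), flat),
            "b3": np.zeros(self.config.hidden),
            "W4": he((self.config.hidden, 1), self.config.hidden),
            "b4": np.zeros(1),
        }

    # -- forward / backward -------------------------------------------------
    def _forward(self, images: np.ndarray, cov: np.ndarray, drop_rng: np.random.Generator | None):
        p = self.params
        cfg = self.config
        kh, kw = cfg.kernel
        x = images[:, None, :, :]  # (N,1,H,W)
        cols1 = _im2col(x, kh, kw)
        z1 = cols1 @ p["W1"].T + p["b1"]  # (N,oh,ow,c1)
        a1 = np.maximum(z1, 0.0)
        a1n = a1.transpose(0, 3, 1, 2)  # (N,c1,oh,ow)
        cols2 = _im2col(a1n, kh, kw)
        z2 = cols2 @ p["W2"].T + p["b2"]
        a2 = np.maximum(z2, 0.0)  # (N,oh2,ow2,c2)
        # 1 x pool_width max pool over width
        n, oh2, ow2, c2 = a2.shape
        pw = cfg.pool_width
        wp = (ow2 // pw) * pw
        blocks = a2[:, :, :wp, :].reshape(n, oh2, wp // pw, pw, c2)
        pooled = blocks.max(axis=3)
        argmax = blocks.argmax(axis=3)
        flat = pooled.reshape(n, -1)
        feats = np.concatenate([flat, cov], axis=1)
        z3 = feats @ p["W3"] + p["b3"]
        a3 = np.maximum(z3, 0.0)
        if drop_rng is not None and cfg.dropout > 0:
            mask = (drop_rng.random(a3.shape) >= cfg.dropout) / (1 - cfg.dropout)
            a3d = a3 * mask
        else:
            mask = None
            a3d = a3
        out = (a3d @ p["W4"] + p["b4"]).ravel()
        cache = (x, cols1, z1, a1n, cols2, z2, a2, argmax, flat, feats, z3, a3, mask, a3d)
        return out, cache

    def _backward(self, dout: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        cfg = self.config
        kh, kw = cfg.kernel
        (x, cols1, z1, a1n, cols2, z2, a2, argmax, flat, feats, z3, a3, mask, a3d) = cache
        n = dout.shape[0]
        g: dict[str, np.ndarray] = {}
        dout = dout[:, None]
        g["W4"] = a3d.T @ dout / n
        g["b4"] = dout.mean(axis=0)
        da3 = dout @ p["W4"].T
        if mask is not None:
            da3 = da3 * mask
        dz3 = da3 * (z3 > 0)
        g["W3"] = feats.T @ dz3 / n
        g["b3"] = dz3.mean(axis=0)
        dfeats = dz3 @ p["W3"].T
        dflat = dfeats[:, : flat.shape[1]]
        # unpool
        nb, oh2, ow2, c2 = a2.shape
        pw = cfg.pool_width
        nblocks = ow2 // pw
        dpooled = dflat.reshape(nb, oh2, nblocks, c2)
        dblocks = np.zeros((nb, oh2, nblocks, pw, c2))
        np.put_along_axis(dblocks, argmax[:, :, :, None, :], dpooled[:, :, :, None, :], axis=3)
        da2 = np.zeros_like(a2)
        da2[:, :, : nblocks * pw, :] = dblocks.reshape(nb, oh2, nblocks * pw, c2)
        dz2 = da2 * (z2 > 0)
        g["W2"] = np.tensordot(dz2, cols2, axes=([0, 1, 2], [0, 1, 2])) / n
        g["b2"] = dz2.mean(axis=(0, 1, 2)) * (dz2.shape[1] * dz2.shape[2])
        dcols2 = dz2 @ p["W2"]
        da1n = _col2im(dcols2, a1n.shape, kh, kw)
        da1 = da1n.transpose(0, 2, 3, 1)
        dz1 = da1 * (z1 > 0)
        g["W1"] = np.tensordot(dz1, cols1, axes=([0, 1, 2], [0, 1, 2])) / n
        g["b1"] = dz1.mean(axis=(0, 1, 2)) * (dz1.shape[1] * dz1.shape[2])
        if cfg.weight_decay:
            for k in ("W1", "W2", "W3", "W4"):
                g[k] = g[k] + cfg.weight_decay * p[k]
        return g

    def _loss_grad(self, pred: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        if self.task_type == "regression":
            diff = pred - y
            return float(np.mean(diff**2)), 2.0 * diff
        prob = 1.0 / (1.0 + np.exp(-pred))
        eps = 1e-12
        loss = float(-np.mean(y * np.log(prob + eps) + (1 - y) * np.log(1 - prob + eps)))
        return loss, prob - y

    # -- public API ---------------------------------------------------------
    def fit(
        self,
        images: np.ndarray,
        covariates: np.ndarray,
        y: np.ndarray,
        groups: np.ndarray | None = None,
    ) -> "ConvImageNet":
        cfg = self.config
        rng = np.random.default_rng(self.seed)
        images = self._pad(np.asarray(images, dtype=float))
        cov = np.asarray(covariates, dtype=float)
        y = np.asarray(y, dtype=float)
        n = images.shape[0]
        # standardize inputs; statistics frozen into the model
        self._x_loc = images.mean(axis=0)
        self._x_scale = np.where(images.std(axis=0) > 1e-12, images.std(axis=0), 1.0)
        images = (images - self._x_loc) / self._x_scale
        if cov.size:
            self._c_loc = cov.mean(axis=0)
            self._c_scale = np.where(cov.std(axis=0) > 1e-12, cov.std(axis=0), 1.0)
            cov = (cov - self._c_loc) / self._c_scale
        if self.task_type == "regression":
            self._y_loc = float(y.mean())
            self._y_scale = float(y.std()) or 1.0
        yt = (y - self._y_loc) / self._y_scale if self.task_type == "regression" else y

        # grouped validation split for early stopping
        if groups is None:
            groups = np.arange(n)
        uniq = np.array(sorted(set(groups)), dtype=object)
        perm = rng.permutation(len(uniq))
        n_val_groups = max(1, int(round(cfg.val_fraction * len(uniq))))
        val_groups = set(uniq[perm[:n_val_groups]])
        val_mask = np.array([g in val_groups for g in groups])
        if val_mask.all() or not val_mask.any():
            val_mask = np.zeros(n, dtype=bool)
            val_mask[rng.permutation(n)[: max(1, n // 7)]] = True
        tr_idx = np.flatnonzero(~val_mask)
        va_idx = np.flatnonzero(val_mask)

        self.params = self._init_params(images.shape[1], images.shape[2], cov.shape[1], rng)
        opt = _Adam(self.params, cfg.lr)
        best_loss = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stall = 0
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(tr_idx)
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                pred, cache = self._forward(images[batch], cov[batch], drop_rng=rng)
                _, dout = self._loss_grad(pred, yt[batch])
                grads = self._backward(dout, cache)
                opt.step(self.params, grads)
            val_pred, _ = self._forward(images[va_idx], cov[va_idx], drop_rng=None)
            val_loss, _ = self._loss_grad(val_pred, yt[va_idx])
            if val_loss < best_loss - 1e-6:
                best_loss = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
        self.params = best_params
        return self

    def predict(self, images: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        images = self._pad(np.asarray(images, dtype=float))
        images = (images - self._x_loc) / self._x_scale
        cov = np.asarray(covariates, dtype=float)
        if cov.size:
            cov = (cov - self._c_loc) / self._c_scale
        out, _ = self._forward(images, cov, drop_rng=None)
        if self.task_type == "regression":
            return out * self._y_scale + self._y_loc
        return 1.0 / (1.0 + np.exp(-out))
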