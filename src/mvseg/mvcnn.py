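"""The multi-view pyramid CNN and its soft-dice loss.

Six independent branches — one per (view, scale) combination: axial/coronal/
sagittal at scale 0 and scale 1 — each process a 32x32x3 patch through a
convolutional block (3x3 kernels, batch normalization, ReLU), 2x2 max pooling,
25% dropout, and a dense layer.  The branch outputs are concatenated and fused
by two dense layers, the last one a 2-way softmax over (non-tumor, tumor).

The network is implemented directly on NumPy arrays with explicit forward and
backward passes (float32 throughout, He-style initialization, batch statistics
during training and running averages at inference).  This keeps training and
inference fully deterministic under a fixed seed and free of framework
dependencies.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

N_BRANCHES = 6  # 3 views x 2 scales
_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9
SOFTDICE_EPS = 1e-7


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The layer recipe (3x3 conv + BN + ReLU, 2x2 max pool, 25% dropout, dense
    branch output, two dense head layers, softmax over 2 classes) is fixed;
    layer widths are configurable because no canonical values exist for them.
    The defaults are sized for single-CPU experiments on phantom cohorts.
    """

    conv_filters: int = 8
    dense_units_branch: int = 32
    dense_units_head: int = 64
    dropout_rate: float = 0.25
    kernel: tuple[int, int] = (3, 3)
    pool: tuple[int, int] = (2, 2)
    n_classes: int = 2
    n_views: int = 3
    n_scales: int = 2
    n_channels: int = 3
    patch: int = 32

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("conv_filters", "dense_units_branch", "dense_units_head",
                     "n_classes", "n_views", "n_scales", "n_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.kernel != (3, 3) or self.pool != (2, 2):
            raise ValueError("only 3x3 kernels with 2x2 pooling are supported")

    @property
    def flat_branch(self) -> int:
        side = self.patch // self.pool[0]
        return side * side * self.conv_filters

    def parameter_count(self) -> int:
        """Total trainable parameter count (excludes BN running buffers)."""
        k = self.kernel[0] * self.kernel[1]
        per_branch = (
            k * self.n_channels * self.conv_filters        # conv weights (no bias: BN follows)
            + 2 * self.conv_filters                        # BN gamma, beta
            + self.flat_branch * self.dense_units_branch   # branch dense W
            + self.dense_units_branch                      # branch dense b
        )
        n_branches = self.n_views * self.n_scales
        head = (
            n_branches * self.dense_units_branch * self.dense_units_head
            + self.dense_units_head
            + self.dense_units_head * self.n_classes
            + self.n_classes
        )
        return n_branches * per_branch + head


def _conv2d_im2col(x: np.ndarray) -> np.ndarray:
    """im2col matrix (B*H*W, 9*Cin) matching :func:`_conv2d_same` ordering."""
    B, H, W, Cin = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    return win.transpose(0, 1, 2, 4, 5, 3).reshape(B * H * W, 9 * Cin)


class MVCNN:
    """Multi-view CNN with explicit parameters and gradients.

    Use :func:`build_model` to construct a freshly initialized instance.
    Parameters live in ``self.params`` (dict of float32 arrays); batch-norm
    running statistics in ``self.buffers``.
    """

    def __init__(self, cfg: ModelConfig, params: dict, buffers: dict, seed: int = 0):
        self.cfg = cfg
        self.params = params
        self.buffers = buffers
        self._dropout_rng = np.random.default_rng(seed)

    # -- construction -------------------------------------------------------

    @classmethod
    def build(cls, cfg: ModelConfig, seed: int = 0) -> "MVCNN":
        rng = np.random.default_rng(seed)
        params: dict[str, np.ndarray] = {}
        buffers: dict[str, np.ndarray] = {}
        F = cfg.conv_filters
        for b in range(cfg.n_views * cfg.n_scales):
            fan_in = 9 * cfg.n_channels
            params[f"b{b}.conv_w"] = (
                rng.standard_normal((3, 3, cfg.n_channels, F)) * np.sqrt(2.0 / fan_in)
            ).astype(np.float32)
            params[f"b{b}.bn_gamma"] = np.ones(F, dtype=np.float32)
            params[f"b{b}.bn_beta"] = np.zeros(F, dtype=np.float32)
            buffers[f"b{b}.bn_mean"] = np.zeros(F, dtype=np.float32)
            buffers[f"b{b}.bn_var"] = np.ones(F, dtype=np.float32)
            params[f"b{b}.dense_w"] = (
                rng.standard_normal((cfg.flat_branch, cfg.dense_units_branch))
                * np.sqrt(2.0 / cfg.flat_branch)
            ).astype(np.float32)
            params[f"b{b}.dense_b"] = np.zeros(cfg.dense_units_branch, dtype=np.float32)
        concat = cfg.n_views * cfg.n_scales * cfg.dense_units_branch
        params["head1_w"] = (
            rng.standard_normal((concat, cfg.dense_units_head)) * np.sqrt(2.0 / concat)
        ).astype(np.float32)
        params["head1_b"] = np.zeros(cfg.dense_units_head, dtype=np.float32)
        params["head2_w"] = (
            rng.standard_normal((cfg.dense_units_head, cfg.n_classes))
            * np.sqrt(2.0 / cfg.dense_units_head)
        ).astype(np.float32)
        params["head2_b"] = np.zeros(cfg.n_classes, dtype=np.float32)
        return cls(cfg, params, buffers, seed=seed)

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    # -- forward ------------------------------------------------------------

    def forward(
        self, batch: np.ndarray, training: bool = False, cache: Optional[dict] = None
    ) -> np.ndarray:
        """Class probabilities for a batch.

        ``batch`` is (B, 6, 32, 32, 3): the stacked PatchSet views.  Returns
        (B, 2) softmax probabilities (non-tumor, tumor).  Dropout and batch
        statistics are active only when ``training``; inference is
        deterministic.
        """
        x = np.asarray(batch)
        if x.dtype != np.float64:  # float64 kept for numerical gradient checks
            x = x.astype(np.float32)
        if x.ndim != 5 or x.shape[1:] != (N_BRANCHES, self.cfg.patch, self.cfg.patch,
                                          self.cfg.n_channels):
            raise ValueError(f"batch must be (B, 6, 32, 32, 3), got {x.shape}")
        B = x.shape[0]
        feats = []
        for b in range(N_BRANCHES):
            pooled, bcache = self._branch_forward(x[:, b], b, training)
            if training and self.cfg.dropout_rate > 0:
                keep = 1.0 - self.cfg.dropout_rate
                mask = (self._dropout_rng.random(pooled.shape, dtype=np.float32)
                        < keep).astype(pooled.dtype)
                mask /= keep
                dropped = pooled * mask
            else:
                mask = None
                dropped = pooled
            flat = dropped.reshape(B, -1)
            dense = flat @ self.params[f"b{b}.dense_w"] + self.params[f"b{b}.dense_b"]
            feat = np.maximum(dense, 0.0)
            feats.append(feat)
            if cache is not None:
                bcache.update(mask=mask, flat=flat, dense=dense)
                cache[f"b{b}"] = bcache
        concat = np.concatenate(feats, axis=1)
        h1 = concat @ self.params["head1_w"] + self.params["head1_b"]
        a1 = np.maximum(h1, 0.0)
        logits = a1 @ self.params["head2_w"] + self.params["head2_b"]
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
        if cache is not None:
            cache.update(concat=concat, h1=h1, a1=a1, probs=probs)
        return probs

    def _branch_forward(self, xb: np.ndarray, b: int, training: bool):
        """One conv branch: conv -> BN -> ReLU -> 2x2 max pool.

        Uses fused numba kernels on float32 input; float64 input follows an
        equivalent plain-NumPy reference path (used by numerical gradient
        checks and as a cross-check of the kernels).
        """
        from mvseg import _kernels

        F = self.cfg.conv_filters
        B = xb.shape[0]
        fast = xb.dtype == np.float32
        w = self.params[f"b{b}.conv_w"]
        if fast:
            cols = _kernels.im2col_3x3(np.ascontiguousarray(xb))
        else:
            cols = _conv2d_im2col(xb)
        conv = (cols @ w.reshape(-1, F)).reshape(B, 32, 32, F)
        if training:
            if fast:
                mean, var = _kernels.batch_mean_var(conv)
            else:
                mean = conv.mean(axis=(0, 1, 2))
                var = np.square(conv - mean).mean(axis=(0, 1, 2))
            self.buffers[f"b{b}.bn_mean"] = (
                _BN_MOMENTUM * self.buffers[f"b{b}.bn_mean"] + (1 - _BN_MOMENTUM) * mean
            ).astype(np.float32)
            self.buffers[f"b{b}.bn_var"] = (
                _BN_MOMENTUM * self.buffers[f"b{b}.bn_var"] + (1 - _BN_MOMENTUM) * var
            ).astype(np.float32)
        else:
            mean = self.buffers[f"b{b}.bn_mean"].astype(conv.dtype)
            var = self.buffers[f"b{b}.bn_var"].astype(conv.dtype)
        inv_std = (1.0 / np.sqrt(var + _BN_EPS)).astype(conv.dtype)
        scale = (self.params[f"b{b}.bn_gamma"] * inv_std).astype(conv.dtype)
        bias = (self.params[f"b{b}.bn_beta"] - mean * scale).astype(conv.dtype)
        if fast:
            pooled, argmax = _kernels.bn_relu_pool_forward(conv, scale, bias)
        else:
            bn = conv * scale + bias
            relu = np.maximum(bn, 0.0)
            blocks = np.ascontiguousarray(
                relu.reshape(B, 16, 2, 16, 2, F).transpose(0, 1, 3, 2, 4, 5)
            ).reshape(B, 16, 16, 4, F)
            argmax = blocks.argmax(axis=3).astype(np.uint8)
            pooled = np.take_along_axis(
                blocks, argmax[:, :, :, None, :].astype(np.intp), axis=3
            )[:, :, :, 0, :]
        bcache = dict(cols=cols, conv=conv, mean=mean, inv_std=inv_std, argmax=argmax,
                      fast=fast)
        return pooled, bcache

    # -- backward -----------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of a scalar loss given d(loss)/d(logits)."""
        grads: dict[str, np.ndarray] = {}
        a1 = cache["a1"]
        grads["head2_w"] = a1.T @ dlogits
        grads["head2_b"] = dlogits.sum(axis=0)
        da1 = dlogits @ self.params["head2_w"].T
        dh1 = da1 * (cache["h1"] > 0)
        grads["head1_w"] = cache["concat"].T @ dh1
        grads["head1_b"] = dh1.sum(axis=0)
        dconcat = dh1 @ self.params["head1_w"].T

        from mvseg import _kernels

        D = self.cfg.dense_units_branch
        F = self.cfg.conv_filters
        for b in range(N_BRANCHES):
            c = cache[f"b{b}"]
            dfeat = dconcat[:, b * D:(b + 1) * D] * (c["dense"] > 0)
            grads[f"b{b}.dense_w"] = c["flat"].T @ dfeat
            grads[f"b{b}.dense_b"] = dfeat.sum(axis=0)
            dflat = dfeat @ self.params[f"b{b}.dense_w"].T
            Bc = dflat.shape[0]
            dpooled = dflat.reshape(Bc, 16, 16, F)
            if c["mask"] is not None:
                dpooled = dpooled * c["mask"]
            gamma = self.params[f"b{b}.bn_gamma"]
            beta = self.params[f"b{b}.bn_beta"]
            if c["fast"]:
                dconv, dgamma, dbeta = _kernels.bn_relu_pool_backward(
                    c["conv"], c["mean"], c["inv_std"],
                    gamma.astype(np.float32), beta.astype(np.float32),
                    np.ascontiguousarray(dpooled, dtype=np.float32), c["argmax"],
                )
            else:
                dconv, dgamma, dbeta = self._pool_bn_backward_ref(c, gamma, beta, dpooled)
            grads[f"b{b}.bn_gamma"] = dgamma
            grads[f"b{b}.bn_beta"] = dbeta
            # conv backward (dW only: the patch inputs need no gradient)
            grads[f"b{b}.conv_w"] = (c["cols"].T @ dconv.reshape(-1, F)).reshape(
                3, 3, self.cfg.n_channels, F
            )
        for k, v in grads.items():
            grads[k] = v.astype(np.float32)
        return grads

    def _pool_bn_backward_ref(self, c, gamma, beta, dpooled):
        """NumPy reference backward through BN + ReLU + max pool."""
        F = self.cfg.conv_filters
        Bc = dpooled.shape[0]
        dblocks = np.zeros((Bc, 16, 16, 4, F), dtype=dpooled.dtype)
        np.put_along_axis(dblocks, c["argmax"][:, :, :, None, :].astype(np.intp),
                          dpooled[:, :, :, None, :], axis=3)
        drelu = np.ascontiguousarray(
            dblocks.reshape(Bc, 16, 16, 2, 2, F).transpose(0, 1, 3, 2, 4, 5)
        ).reshape(Bc, 32, 32, F)
        xhat = (c["conv"] - c["mean"]) * c["inv_std"]
        bn = xhat * gamma + beta
        dbn = drelu * (bn > 0)
        dgamma = (dbn * xhat).sum(axis=(0, 1, 2))
        dbeta = dbn.sum(axis=(0, 1, 2))
        dxhat = dbn * gamma
        dconv = (
            dxhat
            - dxhat.mean(axis=(0, 1, 2))
            - xhat * (dxhat * xhat).mean(axis=(0, 1, 2))
        ) * c["inv_std"]
        return dconv, dgamma, dbeta

    def train_step_grads(
        self, batch: np.ndarray, labels: np.ndarray, eps: float = SOFTDICE_EPS
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Soft-dice loss and parameter gradients for one training batch."""
        cache: dict = {}
        probs = self.forward(batch, training=True, cache=cache)
        p = probs[:, 1]
        g = np.asarray(labels, dtype=np.float64)
        loss, dldp = _softdice_with_grad(p.astype(np.float64), g, eps)
        # through the 2-way softmax: dp/dz1 = p(1-p), dp/dz0 = -p(1-p)
        dz1 = dldp * p * (1.0 - p)
        dlogits = np.stack([-dz1, dz1], axis=1).astype(np.float32)
        grads = self.backward(cache, dlogits)
        return float(loss), grads

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint with the config embedded as JSON."""
        path = Path(path)
        with zipfile.ZipFile(path, "w") as zf:
            cfg = asdict(self.cfg)
            cfg["kernel"] = list(cfg["kernel"])
            cfg["pool"] = list(cfg["pool"])
            zf.writestr("config.json", json.dumps(cfg))
            buf = io.BytesIO()
            np.savez(buf, **self.params, **{f"buffer__{k}": v for k, v in self.buffers.items()})
            zf.writestr("arrays.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "MVCNN":
        with zipfile.ZipFile(Path(path)) as zf:
            cfg_d = json.loads(zf.read("config.json"))
            cfg_d["kernel"] = tuple(cfg_d["kernel"])
            cfg_d["pool"] = tuple(cfg_d["pool"])
            cfg = ModelConfig(**cfg_d)
            with np.load(io.BytesIO(zf.read("arrays.npz"))) as arrs:
                params = {k: arrs[k] for k in arrs.files if not k.startswith("buffer__")}
                buffers = {
                    k[len("buffer__"):]: arrs[k] for k in arrs.files if k.startswith("buffer__")
                }
        return cls(cfg, params, buffers)


def build_model(cfg: ModelConfig, seed: int = 0) -> MVCNN:
    """Freshly initialized MV-CNN; identical seeds give identical parameters."""
    return MVCNN.build(cfg, seed)


def _softdice_with_grad(
    p: np.ndarray, g: np.ndarray, eps: float
) -> tuple[float, np.ndarray]:
    num = 2.0 * float(p @ g) + eps
    den = float(p.sum() + g.sum()) + eps
    loss = 1.0 - num / den
    # d/dp_i [num/den] = (2 g_i den - num) / den^2
    dldp = -(2.0 * g * den - num) / den**2
    return loss, dldp


def softdice_loss(
    pred_tumor_probs: np.ndarray, labels: np.ndarray, epsilon: float = SOFTDICE_EPS
) -> float:
    """Batch soft-dice loss: ``1 - (2 Σ p·g + ε) / (Σ p + Σ g + ε)``.

    Sums run over the whole batch, matching a Dice overlap computed on the
    batch as one set of voxels.  Bounded in [0, 1] for probabilities in [0, 1].
    """
    p = np.asarray(pred_tumor_probs, dtype=np.float64)
    g = np.asarray(labels, dtype=np.float64)
    if p.shape != g.shape or p.ndim != 1:
        raise ValueError("pred probs and labels must be equal-length vectors")
    if p.size < 1:
        raise ValueError("batch must be non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    loss, _ = _softdice_with_grad(p, g, epsilon)
    return float(loss)
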