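"""Numba kernels for the convolutional branch hot path.

The branch tensors (batch x 32 x 32 x filters, float32) are memory-bound in
pure NumPy because every elementwise step is a full pass over tens of
megabytes.  These kernels fuse im2col, batch-norm + ReLU + 2x2 max-pool, and
the corresponding backward pass into single sweeps.  They are exact
re-expressions of the layer math, not approximations.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def im2col_3x3(x: np.ndarray) -> np.ndarray:
    """im2col for a 'same' 3x3 convolution.

    x: (B, H, W, C) float32 -> (B*H*W, 9*C) with column order (ky, kx, c),
    zero padding outside the window.
    """
    B, H, W, C = x.shape
    cols = np.zeros((B * H * W, 9 * C), dtype=np.float32)
    for b in range(B):
        base_b = b * H * W
        for i in range(H):
            for j in range(W):
                n = base_b + i * W + j
                for ky in range(3):
                    ii = i + ky - 1
                    if ii < 0 or ii >= H:
                        continue
                    for kx in range(3):
                        jj = j + kx - 1
                        if jj < 0 or jj >= W:
                            continue
                        off = (ky * 3 + kx) * C
                        for c in range(C):
                            cols[n, off + c] = x[b, ii, jj, c]
    return cols


@njit(cache=True, fastmath=False)
def bn_relu_pool_forward(conv, scale, bias):
    """Fused (x*scale + bias) -> ReLU -> 2x2 max pool with argmax.

    conv: (B, H, W, F); returns pooled (B, H/2, W/2, F) and the block-local
    argmax in {0..3} (uint8) for the backward scatter.
    """
    B, H, W, F = conv.shape
    Ho, Wo = H // 2, W // 2
    pooled = np.empty((B, Ho, Wo, F), dtype=np.float32)
    amax = np.zeros((B, Ho, Wo, F), dtype=np.uint8)
    for b in range(B):
        for oi in range(Ho):
            for oj in range(Wo):
                for f in range(F):
                    best = np.float32(0.0)
                    arg = np.uint8(0)
                    k = 0
                    for di in range(2):
                        for dj in range(2):
                            v = conv[b, 2 * oi + di, 2 * oj + dj, f] * scale[f] + bias[f]
                            if v < 0.0:
                                v = np.float32(0.0)
                            if k == 0 or v > best:
                                best = v
                                arg = np.uint8(k)
                            k += 1
                    pooled[b, oi, oj, f] = best
                    amax[b, oi, oj, f] = arg
    return pooled, amax


@njit(cache=True, fastmath=False)
def bn_relu_pool_backward(conv, mean, inv_std, gamma, beta, dpooled, amax):
    """Backward through BN (batch statistics) + ReLU + 2x2 max pool.

    Returns (dconv, dgamma, dbeta).  Two sweeps: the first scatters the pooled
    gradient to the argmax sites (gated by the ReLU), accumulating the batch
    sums the BN backward needs; the second applies the mean corrections.
    """
    B, H, W, F = conv.shape
    Ho, Wo = H // 2, W // 2
    n = B * H * W
    dxhat = np.zeros((B, H, W, F), dtype=np.float32)
    dgamma = np.zeros(F, dtype=np.float64)
    dbeta = np.zeros(F, dtype=np.float64)
    s1 = np.zeros(F, dtype=np.float64)   # sum dxhat
    s2 = np.zeros(F, dtype=np.float64)   # sum dxhat * xhat
    for b in range(B):
        for oi in range(Ho):
            for oj in range(Wo):
                for f in range(F):
                    g = dpooled[b, oi, oj, f]
                    if g == 0.0:
                        continue
                    k = amax[b, oi, oj, f]
                    i = 2 * oi + (k // 2)
                    j = 2 * oj + (k % 2)
                    xh = (conv[b, i, j, f] - mean[f]) * inv_std[f]
                    if xh * gamma[f] + beta[f] <= 0.0:
                        continue  # ReLU gate (output was clamped to zero)
                    dgamma[f] += g * xh
                    dbeta[f] += g
                    dx = g * gamma[f]
                    dxhat[b, i, j, f] = dx
                    s1[f] += dx
                    s2[f] += dx * xh
    m1 = (s1 / n).astype(np.float32)
    m2 = (s2 / n).astype(np.float32)
    dconv = np.empty((B, H, W, F), dtype=np.float32)
    for b in range(B):
        for i in range(H):
            for j in range(W):
                for f in range(F):
                    xh = (conv[b, i, j, f] - mean[f]) * inv_std[f]
                    dconv[b, i, j, f] = (dxhat[b, i, j, f] - m1[f] - xh * m2[f]) * inv_std[f]
    return dconv, dgamma.astype(np.float32), dbeta.astype(np.float32)


@njit(cache=True, fastmath=False)
def batch_mean_var(conv):
    """Per-channel mean and (biased) variance over (B, H, W) in one sweep."""
    B, H, W, F = conv.shape
    s = np.zeros(F, dtype=np.float64)
    sq = np.zeros(F, dtype=np.float64)
    for b in range(B):
        for i in range(H):
            for j in range(W):
                for f in range(F):
                    v = conv[b, i, j, f]
                    s[f] += v
                    sq[f] += v * v
    n = B * H * W
    mean = (s / n).astype(np.float32)
    var = (sq / n - (s / n) ** 2).astype(np.float32)
    return mean, var


@njit(cache=True, fastmath=False)
def extract_patches(stack: np.ndarray, idx: np.ndarray, pad: int) -> np.ndarray:
    """Gather the six tri-planar patches for a batch of voxels.

    stack: zero-padded (X+2p, Y+2p, Z+2p, C) float32; idx: (B, 3) unpadded
    voxel indices.  Output (B, 6, 32, 32, C): scale-0 axial/coronal/sagittal
    then scale-1 views with the 2x2 mean pooling fused into the gather.
    """
    B = idx.shape[0]
    C = stack.shape[3]
    out = np.empty((B, 6, 32, 32, C), dtype=np.float32)
    for b in range(B):
        ci = idx[b, 0] + pad
        cj = idx[b, 1] + pad
        ck = idx[b, 2] + pad
        for r in range(32):
            for c in range(32):
                i0 = ci - 16 + r          # row along i (axial, coronal)
                j0 = cj - 16 + c          # column along j (axial)
                jr0 = cj - 16 + r         # row along j (sagittal)
                k0 = ck - 16 + c          # column along k (coronal, sagittal)
                for ch in range(C):
                    out[b, 0, r, c, ch] = stack[i0, j0, ck, ch]    # axial (i,j)
                    out[b, 1, r, c, ch] = stack[i0, cj, k0, ch]    # coronal (i,k)
                    out[b, 2, r, c, ch] = stack[ci, jr0, k0, ch]   # sagittal (j,k)
                i1 = ci - 32 + 2 * r
                j1 = cj - 32 + 2 * c
                jr1 = cj - 32 + 2 * r
                k1 = ck - 32 + 2 * c
                for ch in range(C):
                    out[b, 3, r, c, ch] = 0.25 * (
                        stack[i1, j1, ck, ch] + stack[i1, j1 + 1, ck, ch]
                        + stack[i1 + 1, j1, ck, ch] + stack[i1 + 1, j1 + 1, ck, ch])
                    out[b, 4, r, c, ch] = 0.25 * (
                        stack[i1, cj, k1, ch] + stack[i1, cj, k1 + 1, ch]
                        + stack[i1 + 1, cj, k1, ch] + stack[i1 + 1, cj, k1 + 1, ch])
                    out[b, 5, r, c, ch] = 0.25 * (
                        stack[ci, jr1, k1, ch] + stack[ci, jr1, k1 + 1, ch]
                        + stack[ci, jr1 + 1, k1, ch] + stack[ci, jr1 + 1, k1 + 1, ch])
    return out
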