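"""Class-rebalanced voxel sampling and tri-planar two-scale patch extraction.

Roughly 2% of in-mask voxels are tumor, so training draws a fixed-size sample
of 50% of all tumor voxels and 1% of all healthy (in-body, non-tumor) voxels.
Around each selected voxel six 2D patches are cut: axial, coronal and sagittal
windows at scale 0 (32x32) and scale 1 (64x64, mean-pooled down to 32x32),
each with three channels in fixed order (T1, T1gad, STIR).  Volumes are
variance-normalized per sequence over the body mask (z-score clipped to
[-4, 4]) and zero-padded by 32 voxels so border patches stay full-sized.

Window convention: the selected voxel sits at in-window index 16 (scale 0
spans [c-16, c+15]) and index 32 at scale 1 (spans [c-32, c+31]).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from mvseg.volume_io import LabelMask, MultiSequenceCase, Sequence, Volume

PAD = 32  # zero border added around the full image in all three dimensions
PATCH = 32
CHANNEL_ORDER = (Sequence.T1, Sequence.T1GAD, Sequence.STIR)
CLIP_SD = 4.0


@dataclass(frozen=True)
class VoxelSample:
    """One training voxel in unpadded standard-space coordinates."""

    case_id: str
    index: tuple[int, int, int]
    label: int  # 0 = healthy, 1 = tumor


@dataclass
class PatchSet:
    """The six 32x32x3 network inputs around one voxel.

    ``scale0``/``scale1`` are (3 views, 32, 32, 3 channels) arrays with view
    order (axial, coronal, sagittal) and channel order (T1, T1gad, STIR).
    """

    scale0: np.ndarray
    scale1: np.ndarray

    def __post_init__(self) -> None:
        for name in ("scale0", "scale1"):
            arr = np.asarray(getattr(self, name), dtype=np.float32)
            if arr.shape != (3, PATCH, PATCH, 3):
                raise ValueError(f"{name} must be (3, 32, 32, 3), got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)

    def stacked(self) -> np.ndarray:
        """(6, 32, 32, 3) array: scale-0 views then scale-1 views."""
        return np.concatenate([self.scale0, self.scale1], axis=0)


def sample_voxels(
    reference: LabelMask,
    body_mask: LabelMask,
    tumor_frac: float = 0.5,
    healthy_frac: float = 0.01,
    seed: int = 0,
    case_id: str = "",
) -> list[VoxelSample]:
    """Draw the training voxels for one case.

    A fixed-size sample without replacement: ``round(tumor_frac * N_tumor)``
    voxels from the tumor mask and ``round(healthy_frac * N_healthy)`` from
    body-mask voxels that are not tumor.  Deterministic under ``seed``.
    """
    if not (0 < tumor_frac <= 1 and 0 < healthy_frac <= 1):
        raise ValueError("fractions must be in (0, 1]")
    if not reference.same_grid(body_mask):
        raise ValueError("reference and body mask must share a grid")
    tumor = reference.data == 1
    if np.any(tumor & (body_mask.data == 0)):
        raise ValueError("body mask must contain all tumor voxels")
    healthy = (body_mask.data == 1) & ~tumor

    n_tumor = int(tumor.sum())
    n_healthy = int(healthy.sum())
    if n_tumor == 0:
        raise ValueError("empty tumor mask")
    k_tumor = int(round(tumor_frac * n_tumor))
    k_healthy = int(round(healthy_frac * n_healthy))
    if k_healthy == 0:
        raise ValueError(f"healthy sample count is 0 (N_healthy={n_healthy})")

    rng = np.random.default_rng(seed)
    samples: list[VoxelSample] = []
    for mask, k, label in ((tumor, k_tumor, 1), (healthy, k_healthy, 0)):
        idx = np.argwhere(mask)
        chosen = idx[rng.choice(len(idx), size=k, replace=False)]
        samples.extend(
            VoxelSample(case_id, (int(i), int(j), int(l)), label) for i, j, l in chosen
        )
    return samples


def normalize_channels(
    volumes: dict[Sequence, Optional[Volume]], body_mask: LabelMask
) -> dict[Sequence, Optional[Volume]]:
    """Variance-normalize each sequence over the body mask.

    Every voxel becomes ``(value - mu) / sigma`` clipped to [-4, 4], with mu
    and sigma computed over body-mask voxels of that sequence only.  Constant
    images map to all zeros; absent sequences stay absent (their channel is
    zero-filled at patch extraction).
    """
    out: dict[Sequence, Optional[Volume]] = {}
    inside = body_mask.data == 1
    if not inside.any():
        raise ValueError("body mask is empty")
    for seq, v in volumes.items():
        if v is None:
            out[seq] = None
            continue
        if v.shape != body_mask.shape:
            raise ValueError(f"{seq}: volume grid does not match body mask")
        vals = v.data[inside].astype(np.float64)
        mu = float(vals.mean())
        sigma = float(vals.std())
        if sigma == 0.0:
            data = np.zeros(v.shape, dtype=np.float32)
        else:
            data = np.clip((v.data - mu) / sigma, -CLIP_SD, CLIP_SD).astype(np.float32)
        out[seq] = Volume(data, v.affine.copy(), seq)
    return out


def stack_channels(volumes: dict[Sequence, Optional[Volume]], pad: int = PAD) -> np.ndarray:
    """Zero-padded (X+2p, Y+2p, Z+2p, 3) channel stack in fixed channel order.

    Absent sequences become all-zero channels.
    """
    shapes = [v.shape for v in volumes.values() if v is not None]
    if not shapes:
        raise ValueError("no sequences available")
    shape = shapes[0]
    chans = []
    for seq in CHANNEL_ORDER:
        v = volumes.get(seq)
        if v is None:
            chans.append(np.zeros(shape, dtype=np.float32))
        else:
            if v.shape != shape:
                raise ValueError("all sequences must share a grid")
            chans.append(v.data.astype(np.float32))
    stack = np.stack(chans, axis=-1)
    return np.pad(stack, ((pad, pad), (pad, pad), (pad, pad), (0, 0)))


def extract_batch(stack: np.ndarray, indices: np.ndarray, pad: int = PAD) -> np.ndarray:
    """Vectorized patch extraction for a batch of voxels.

    ``stack`` is the padded channel stack from :func:`stack_channels`;
    ``indices`` is (B, 3) unpadded voxel coordinates.  Returns
    (B, 6, 32, 32, 3): three scale-0 views then three scale-1 views
    (each already pooled to 32x32).
    """
    idx = np.asarray(indices, dtype=np.intp)
    if idx.ndim != 2 or idx.shape[1] != 3:
        raise ValueError("indices must be (B, 3)")
    unpadded = np.asarray(stack.shape[:3]) - 2 * pad
    if np.any(idx < 0) or np.any(idx >= unpadded):
        raise ValueError("voxel index outside the unpadded grid")
    if stack.dtype == np.float32 and stack.flags.c_contiguous:
        from mvseg import _kernels

        return _kernels.extract_patches(stack, idx, pad)
    ci, cj, ck = (idx + pad).T
    B = len(idx)
    out = np.empty((B, 6, PATCH, PATCH, 3), dtype=np.float32)
    for s, half in enumerate((PATCH // 2, PATCH)):  # scale 0: +/-16, scale 1: +/-32
        off = np.arange(-half, half)
        ri = ci[:, None] + off  # (B, W)
        rj = cj[:, None] + off
        rk = ck[:, None] + off
        # axial: in-plane (i, j) at slice k
        ax = stack[ri[:, :, None], rj[:, None, :], ck[:, None, None], :]
        # coronal: (i, k) plane at row j
        co = stack[ri[:, :, None], cj[:, None, None], rk[:, None, :], :]
        # sagittal: (j, k) plane at column i
        sa = stack[ci[:, None, None], rj[:, :, None], rk[:, None, :], :]
        views = (ax, co, sa)
        for v, patch in enumerate(views):
            if s == 0:
                out[:, v] = patch
            else:
                out[:, 3 + v] = downsample_scale1(patch)
    return out


def extract_patchset(
    volumes: dict[Sequence, Optional[Volume]] | np.ndarray,
    index: tuple[int, int, int],
    pad: int = PAD,
) -> PatchSet:
    """Extract the six patches around one voxel (unpadded coordinates).

    ``volumes`` may be the normalized per-sequence dict or a precomputed
    padded stack from :func:`stack_channels`.
    """
    stack = volumes if isinstance(volumes, np.ndarray) else stack_channels(volumes, pad)
    batch = extract_batch(stack, np.asarray(index, dtype=np.intp)[None, :], pad)
    return PatchSet(scale0=batch[0, :3], scale1=batch[0, 3:])


def downsample_scale1(patch: np.ndarray) -> np.ndarray:
    """2x2 mean pooling over the leading two spatial axes of (..., H, W, C).

    Exactly mean-preserving; requires even spatial dimensions.
    """
    arr = np.asarray(patch)
    *lead, h, w, c = arr.shape
    if h % 2 or w % 2:
        raise ValueError("spatial dimensions must be even for 2x2 pooling")
    pooled = arr.reshape(*lead, h // 2, 2, w // 2, 2, c).mean(axis=(-2, -4))
    return pooled


def prepare_case_stack(case: MultiSequenceCase, body_mask: LabelMask) -> np.ndarray:
    """Normalize a standard-space case and return its padded channel stack."""
    normed = normalize_channels(case.sequences(), body_mask)
    return stack_channels(normed)


def samples_to_frame(samples: list[VoxelSample]):
    """Serialize samples as a DataFrame (case_id, i, j, k, label)."""
    import pandas as pd

    return pd.DataFrame(
        [(s.case_id, *s.index, s.label) for s in samples],
        columns=["case_id", "i", "j", "k", "label"],
    )
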