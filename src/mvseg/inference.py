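"""Masked full-volume segmentation and predicted-volume computation."""

from __future__ import annotations

import numpy as np

from mvseg.mvcnn import MVCNN
from mvseg.patch_sampling import extract_batch, prepare_case_stack
from mvseg.volume_io import LabelMask, MultiSequenceCase


def segment_volume(
    model: MVCNN,
    case: MultiSequenceCase,
    mask: LabelMask,
    batch_size: int = 512,
) -> LabelMask:
    """Classify every in-mask voxel of a standard-space case.

    The case is variance-normalized and padded, a PatchSet extracted around
    every voxel with ``mask == 1``, and the network applied in inference mode.
    A voxel is labelled tumor iff its tumor-class probability is strictly
    above 0.5 (ties go to non-tumor); voxels outside the mask stay 0.  The
    result never extends outside the mask, and batching is unobservable: any
    batch size yields the same segmentation.
    """
    if case.t1.shape != mask.shape:
        raise ValueError("mask grid does not match the case grid")
    out = np.zeros(mask.shape, dtype=np.uint8)
    indices = np.argwhere(mask.data == 1)
    if len(indices) == 0:
        return LabelMask(out, mask.affine.copy())
    stack = prepare_case_stack(case, mask)
    for start in range(0, len(indices), batch_size):
        chunk = indices[start:start + batch_size]
        probs = model.forward(extract_batch(stack, chunk), training=False)
        tumor = probs[:, 1] > 0.5
        out[chunk[tumor, 0], chunk[tumor, 1], chunk[tumor, 2]] = 1
    return LabelMask(out, mask.affine.copy())


def predicted_volume_cm3(m: LabelMask) -> float:
    """Mask volume in cm^3: voxel count times voxel volume.

    On the 1-mm isotropic standard grid each voxel is 1 mm^3, so 1000 voxels
    equal 1 cm^3.
    """
    if not isinstance(m, LabelMask):
        raise TypeError("predicted_volume_cm3 expects a binary LabelMask")
    voxel_mm3 = float(np.prod(m.spacing))
    return m.n_voxels * voxel_mm3 / 1000.0
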