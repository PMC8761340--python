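"""Synthetic multi-sequence head-and-neck phantoms with known ground truth.

Each phantom is a smoothed ellipsoidal "neck" with low-frequency internal
texture (zero outside the body, exercising the non-zero template averaging), a
smooth blob tumor of controllable volume placed at a site-dependent position,
and the sequence-contrast pattern the segmentation network must exploit: the
tumor is iso-intense on T1, strongly hyperintense on STIR, and enhancing on
contrast-enhanced T1.  Non-T1 sequences can be perturbed by known rigid
transforms (simulating inter-sequence motion), the whole subject can be posed
away from the template frame, Gaussian noise is added inside the body, and the
contrast channel is occasionally dropped.

The phantoms are deliberately simple: the point is mechanism recovery with an
exactly known reference, not anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from mvseg.standard_space import AffineTransform, Interp, resample
from mvseg.volume_io import LabelMask, Location, MultiSequenceCase, Sequence, Volume

_LOCATION_OFFSETS = {
    # tumor center offset as a fraction of the body semi-axes
    Location.ORAL_CAVITY: (0.45, 0.0, 0.25),
    Location.OROPHARYNX: (0.0, 0.2, 0.0),
    Location.HYPOPHARYNX: (-0.2, -0.1, -0.35),
}

# per-stratum target tumor volumes (cm^3), matching the V1-V4 boundaries
VOLUME_STRATA = {
    "V1": (1.5, 3.0),
    "V2": (3.5, 6.5),
    "V3": (8.0, 14.0),
    "V4": (16.0, 22.0),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one synthetic case.

    The default 64-voxel grid at 2 mm keeps experiments desk-sized while
    preserving the anatomy's proportions: the body spans ~12 cm and holds
    roughly 550 cm^3, so a 2-20 cm^3 tumor occupies the ~2% of in-mask voxels
    a real cohort shows.  That prevalence matters: the 50%/1% class
    rebalancing yields a roughly balanced training set only when tumors are a
    small fraction of the body.  The full template grid (224 x 192 x 117 at
    1 mm) is just a configuration choice.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: float = 2.0
    tumor_volume_cm3: float = 10.0
    location: Location = Location.OROPHARYNX
    background_scale: float = 6.0   # smoothing sigma (voxels) of the body texture
    noise_sd: float = 2.0           # intensity units, body intensities are O(100)
    misalign_mm: float = 2.0        # inter-sequence rigid perturbation magnitude
    misalign_deg: float = 2.0
    subject_misalign_mm: float = 0.0  # whole-subject pose away from template frame
    subject_misalign_deg: float = 0.0
    t1gad_missing_probability: float = 0.03
    body_axes_frac: tuple[float, float, float] = (0.80, 0.74, 0.86)
    tumor_roughness: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if self.tumor_volume_cm3 <= 0:
            raise ValueError("target tumor volume must be positive")


@dataclass
class PhantomTruth:
    """Everything the generator knows that the pipeline must recover."""

    std_mask: LabelMask                      # ground-truth tumor mask, template frame
    t1_to_std: AffineTransform               # true subject pose (native T1 -> template)
    stir_to_t1: AffineTransform              # true realigning transforms
    t1gad_to_t1: Optional[AffineTransform]
    body_mask_std: LabelMask                 # body support in the template frame


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _random_rigid(
    rng: np.random.Generator, mm: float, deg: float, center: np.ndarray
) -> AffineTransform:
    if mm == 0 and deg == 0:
        return AffineTransform.identity()
    t = rng.uniform(-mm, mm, size=3)
    r = rng.uniform(-deg, deg, size=3)
    return AffineTransform.from_rigid(t, r, center_mm=center)


def _blob_mask(
    rng: np.random.Generator,
    shape: tuple[int, int, int],
    center: np.ndarray,
    target_voxels: int,
    roughness: float,
    allowed: np.ndarray,
) -> np.ndarray:
    """Smooth blob of (nearly) exactly ``target_voxels`` voxels inside ``allowed``.

    A perturbed radial field is thresholded at the quantile that yields the
    target count, then restricted to its largest 6-connected component.
    """
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r0 = (3 * target_voxels / (4 * np.pi)) ** (1 / 3)
    d = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center))) / r0
    pert = _smooth_field(rng, shape, sigma=max(2.0, r0 / 2))
    fieldv = d + roughness * pert
    vals = fieldv[allowed]
    if target_voxels > vals.size:
        raise ValueError("tumor cannot fit inside the body")
    thr = np.partition(vals, target_voxels - 1)[target_voxels - 1]
    mask = (fieldv <= thr) & allowed
    lab, n = ndimage.label(mask)  # default structure = 6-connectivity
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    if abs(int(mask.sum()) - target_voxels) > 0.05 * target_voxels:
        raise ValueError("tumor cannot fit inside the body at the target volume")
    return mask


def generate_case(cfg: PhantomConfig) -> tuple[MultiSequenceCase, PhantomTruth]:
    """Generate one phantom case (native space) plus its ground truth.

    Deterministic under ``cfg.seed``.  The returned true transforms are the
    realigning transforms a perfect registration would recover: applying them
    through :func:`mvseg.standard_space.resample` brings each perturbed
    sequence back onto the T1 grid (and the T1 into the template frame).
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(int(n) for n in cfg.shape)
    affine = np.diag([cfg.spacing_mm] * 3 + [1.0])
    center = (np.asarray(shape) - 1) / 2.0

    # body: ellipsoid with jittered semi-axes, zero outside
    semi = np.asarray(cfg.body_axes_frac) * np.asarray(shape) / 2.0
    semi = semi * rng.uniform(0.93, 1.03, size=3)
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    ell = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    body = ell <= 1.0

    texture = _smooth_field(rng, shape, cfg.background_scale)
    # radial shading gives registration a global intensity gradient to lock onto
    shading = np.cos(np.sqrt(ell) * np.pi / 2.0)

    # asymmetric internal structures (spine-like rod, airway-like tube, an
    # oblique muscle-like blob): without them the ellipsoid is nearly
    # rotationally symmetric and rigid registration cannot pin down rotation
    def _tube(offset_frac: tuple[float, float], radius_frac: float) -> np.ndarray:
        ox, oy = (center[0] + offset_frac[0] * semi[0],
                  center[1] + offset_frac[1] * semi[1])
        r = radius_frac * min(semi[0], semi[1])
        return ((grids[0] - ox) ** 2 + (grids[1] - oy) ** 2) <= r**2

    spine = _tube((-0.50, 0.0), 0.14) & body
    airway = _tube((0.38, 0.05), 0.11) & body
    mx = center + np.asarray([0.15, 0.45, 0.20]) * semi
    muscle = (sum(((g - m) / (0.22 * s)) ** 2
                  for g, m, s in zip(grids, mx, semi)) <= 1.0) & body

    # tumor blob at the site-dependent position, eroded-body interior only
    offs = np.asarray(_LOCATION_OFFSETS[cfg.location])
    tumor_center = center + offs * semi * rng.uniform(0.8, 1.1)
    target = int(round(cfg.tumor_volume_cm3 * 1000.0 / cfg.spacing_mm**3))
    interior = ell <= 0.75
    tumor = _blob_mask(rng, shape, tumor_center, target, cfg.tumor_roughness, interior)

    def compose_image(base: float, tex_amp: float, shade_amp: float, tumor_delta: float):
        img = np.where(body, base + tex_amp * texture + shade_amp * shading, 0.0)
        img = np.where(spine, img + 0.6 * base, img)
        img = np.where(airway, 0.1 * base, img)
        img = np.where(muscle, img + 0.35 * base, img)
        img = img + tumor_delta * tumor
        return np.clip(img, 0.5, None) * body + 0.0

    t1_img = compose_image(100.0, 12.0, 30.0, 5.0)      # tumor nearly iso-intense
    stir_img = compose_image(70.0, 8.0, 20.0, 60.0)     # tumor hyperintense
    gad_img = compose_image(90.0, 12.0, 25.0, 50.0)     # tumor enhancing

    grid = (shape, affine)
    center_mm = affine[:3, :3] @ center + affine[:3, 3]

    # whole-subject pose: native T1 frame vs template frame
    pose_to_std = _random_rigid(
        rng, cfg.subject_misalign_mm, cfg.subject_misalign_deg, center_mm
    )
    # inter-sequence motion: realigning transforms seq -> T1
    stir_to_t1 = _random_rigid(rng, cfg.misalign_mm, cfg.misalign_deg, center_mm)
    t1gad_to_t1 = _random_rigid(rng, cfg.misalign_mm, cfg.misalign_deg, center_mm)
    t1gad_missing = rng.random() < cfg.t1gad_missing_probability

    def as_native(img: np.ndarray, seq: Sequence, realign: AffineTransform) -> Volume:
        v = Volume(img, affine.copy(), seq)
        # the acquired image is the standard-frame object moved by the inverse
        # of (pose ∘ realign); identity transforms skip the resampling entirely
        total = pose_to_std.matrix @ realign.matrix
        if np.allclose(total, np.eye(4), atol=1e-12):
            return v
        t = AffineTransform(total).inverse()
        return resample(v, t, grid, Interp.LINEAR)

    t1_native = as_native(t1_img, Sequence.T1, AffineTransform.identity())
    stir_native = as_native(stir_img, Sequence.STIR, stir_to_t1)
    gad_native = None if t1gad_missing else as_native(gad_img, Sequence.T1GAD, t1gad_to_t1)

    std_mask = LabelMask(tumor.astype(np.uint8), affine.copy())
    if np.allclose(pose_to_std.matrix, np.eye(4), atol=1e-12):
        ref_native = std_mask.with_data(std_mask.data.copy())
    else:
        ref_native = resample(std_mask, pose_to_std.inverse(), grid, Interp.NEAREST)

    def add_noise(v: Optional[Volume]) -> Optional[Volume]:
        if v is None or cfg.noise_sd == 0:
            return v
        noise = rng.normal(0.0, cfg.noise_sd, size=v.shape)
        data = np.clip(v.data + noise * (v.data != 0), 0.0, None)
        return v.with_data(data)

    vol = cfg.tumor_volume_cm3
    t_stage = "T2" if vol <= 7 else ("T3" if vol <= 15 else "T4")
    n_stage = ("N0", "N1", "N2")[int(rng.integers(3))]
    case = MultiSequenceCase(
        case_id=f"phantom-{cfg.seed:08d}",
        t1=add_noise(t1_native),
        stir=add_noise(stir_native),
        t1gad=add_noise(gad_native),
        reference=ref_native,
        location=cfg.location,
        t_stage=t_stage,
        n_stage=n_stage,
    )
    truth = PhantomTruth(
        std_mask=std_mask,
        t1_to_std=pose_to_std,
        stir_to_t1=stir_to_t1,
        t1gad_to_t1=None if t1gad_missing else t1gad_to_t1,
        body_mask_std=LabelMask(body.astype(np.uint8), affine.copy()),
    )
    return case, truth


def generate_cohort(
    n: int,
    seed: int = 0,
    volume_distribution: Optional[dict[str, float]] = None,
    base_config: Optional[PhantomConfig] = None,
) -> tuple[list[tuple[MultiSequenceCase, PhantomTruth]], pd.DataFrame]:
    """Generate ``n`` phantoms stratified over the V1-V4 volume groups.

    ``volume_distribution`` gives per-stratum weights (default: equal).
    Returns the cases with their truths plus a manifest DataFrame
    (case_id, location, volume group, target volume, T1gad presence).
    Deterministic under ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if base_config is None:
        base_config = PhantomConfig()
    dist = volume_distribution or {s: 1.0 for s in VOLUME_STRATA}
    strata = sorted(dist)
    weights = np.asarray([dist[s] for s in strata], dtype=float)
    weights = weights / weights.sum()
    # largest-remainder allocation of n cases over strata
    raw = weights * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1

    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)
    locations = list(_LOCATION_OFFSETS)

    cases: list[tuple[MultiSequenceCase, PhantomTruth]] = []
    rows = []
    i = 0
    for stratum, count in zip(strata, counts):
        lo, hi = VOLUME_STRATA[stratum]
        for _ in range(count):
            vol = float(rng.uniform(lo, hi))
            loc = locations[i % len(locations)]
            cfg = replace(
                base_config,
                tumor_volume_cm3=vol,
                location=loc,
                seed=int(child_seeds[i]),
            )
            case, truth = generate_case(cfg)
            case.case_id = f"case-{seed}-{i:03d}"
            cases.append((case, truth))
            rows.append(
                dict(
                    case_id=case.case_id,
                    location=loc.value,
                    volume_group=stratum,
                    target_volume_cm3=vol,
                    t_stage=case.t_stage,
                    n_stage=case.n_stage,
                    has_t1gad=case.has_t1gad,
                )
            )
            i += 1
    manifest = pd.DataFrame(rows)
    return cases, manifest
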