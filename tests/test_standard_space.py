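"""Template construction, transform algebra, resampling and registration."""

import numpy as np
import pytest
import scipy.linalg

from mvseg.evaluation import dsc
from mvseg.phantom import PhantomConfig, generate_case
from mvseg.standard_space import (
    AffineTransform,
    CaseTransforms,
    Dof,
    Interp,
    build_template,
    case_to_standard,
    compose,
    mask_to_native,
    register_affine,
    resample,
    rigid_component,
)
from mvseg.volume_io import LabelMask, Sequence, Volume


def _vol(data, affine=None, seq=Sequence.T1):
    return Volume(np.asarray(data, dtype=float), np.eye(4) if affine is None else affine, seq)


def transform_error(rec: AffineTransform, true: AffineTransform, center_mm):
    """(translation error at the center, rotation angle error in degrees)."""
    d = rec.matrix @ np.linalg.inv(true.matrix)
    ang = np.rad2deg(np.arccos(np.clip((np.trace(d[:3, :3]) - 1) / 2, -1, 1)))
    disp = np.linalg.norm(AffineTransform(d).apply(center_mm) - np.asarray(center_mm))
    return disp, ang


class TestBuildTemplate:
    def test_nonzero_average_at_a_voxel(self):
        vols = [_vol(np.full((2, 2, 2), v)) for v in (0, 0, 0, 5, 7)]
        tpl = build_template(vols, threshold=0.30)
        # occupancy 2/5 = 0.4 >= 0.3; mean over the non-zero contributors
        assert tpl.occupancy_mask.data[0, 0, 0] == 1
        assert tpl.template.data[0, 0, 0] == pytest.approx(6.0)

    def test_voxel_below_occupancy_threshold_masked_out(self):
        vols = [_vol(np.full((2, 2, 2), 4.0)) for _ in range(2)]
        vols += [_vol(np.zeros((2, 2, 2))) for _ in range(8)]
        tpl = build_template(vols, threshold=0.30)
        assert tpl.occupancy_mask.n_voxels == 0
        assert np.all(tpl.template.data == 0)

    def test_identical_volumes_reproduce_themselves(self, rng):
        data = rng.random((4, 4, 4)) + 0.5
        tpl = build_template([_vol(data) for _ in range(4)], threshold=0.30)
        assert np.allclose(tpl.template.data, data)
        assert tpl.occupancy_mask.n_voxels == 64

    def test_order_invariance(self, rng):
        vols = [_vol(rng.random((4, 4, 4)) * (rng.random((4, 4, 4)) < 0.7)) for _ in range(6)]
        a = build_template(vols, 0.3)
        b = build_template(vols[::-1], 0.3)
        assert np.allclose(a.template.data, b.template.data)
        assert np.array_equal(a.occupancy_mask.data, b.occupancy_mask.data)

    def test_mask_shrinks_with_threshold(self, rng):
        vols = [_vol(rng.random((5, 5, 5)) * (rng.random((5, 5, 5)) < 0.6)) for _ in range(8)]
        sizes = [build_template(vols, t).occupancy_mask.n_voxels
                 for t in (0.1, 0.3, 0.5, 0.8, 1.0)]
        assert sizes == sorted(sizes, reverse=True)

    @pytest.mark.parametrize("n", [0, 1])
    def test_too_small_stack_rejected(self, n, rng):
        vols = [_vol(rng.random((3, 3, 3)))] * n
        with pytest.raises(ValueError):
            build_template(vols, 0.3)

    def test_mismatched_grids_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            build_template([_vol(rng.random((3, 3, 3))), _vol(rng.random((4, 4, 4)))], 0.3)


class TestTransformAlgebra:
    def test_compose_identity_law(self, rng):
        a = AffineTransform.from_rigid(rng.normal(size=3), rng.normal(size=3))
        assert np.allclose(compose(AffineTransform.identity(), a).matrix, a.matrix)

    def test_compose_inverse_law(self, rng):
        a = AffineTransform.from_rigid(rng.normal(size=3), rng.normal(size=3))
        assert np.allclose(compose(a, a.inverse()).matrix, np.eye(4), atol=1e-10)

    def test_compose_matches_sequential_point_mapping(self, rng):
        a = AffineTransform(np.vstack([np.column_stack([rng.normal(size=(3, 3)) + 2 * np.eye(3),
                                                        rng.normal(size=3)]), [0, 0, 0, 1]]))
        b = AffineTransform.from_rigid(rng.normal(size=3), rng.normal(size=3) * 10)
        pts = rng.normal(scale=50, size=(100, 3))
        err = np.abs(compose(a, b).apply(pts) - a.apply(b.apply(pts))).max()
        assert err < 1e-9

    def test_compose_associative(self, rng):
        ts = [AffineTransform.from_rigid(rng.normal(size=3), rng.normal(size=3) * 5)
              for _ in range(3)]
        left = compose(compose(ts[0], ts[1]), ts[2])
        right = compose(ts[0], compose(ts[1], ts[2]))
        assert np.allclose(left.matrix, right.matrix, atol=1e-12)

    def test_bottom_row_enforced(self):
        m = np.eye(4)
        m[3, 0] = 1.0
        with pytest.raises(ValueError):
            AffineTransform(m)


class TestRigidComponent:
    def test_idempotent_on_rigid_input(self, rng):
        a = AffineTransform.from_rigid((3, -2, 1), (10, -20, 5))
        out = rigid_component(a)
        assert np.allclose(out.matrix, a.matrix, atol=1e-10)

    def test_pure_scaling_gives_identity_rotation(self):
        m = np.diag([2.0, 2.0, 2.0, 1.0])
        m[:3, 3] = (1, 2, 3)
        out = rigid_component(AffineTransform(m))
        assert np.allclose(out.matrix[:3, :3], np.eye(3), atol=1e-12)
        assert np.allclose(out.translation, (1, 2, 3))

    def test_recovers_rotation_from_rotation_times_scaling(self, rng):
        R = AffineTransform.from_rigid((0, 0, 0), (25, -40, 65)).matrix[:3, :3]
        m = np.eye(4)
        m[:3, :3] = R @ np.diag([1.7, 0.6, 1.1])
        out = rigid_component(AffineTransform(m))
        assert np.allclose(out.matrix[:3, :3], R, atol=1e-10)

    def test_matches_polar_decomposition_oracle(self, rng):
        for _ in range(20):
            A = rng.normal(size=(3, 3)) + 2.5 * np.eye(3)
            if np.linalg.det(A) <= 0:
                continue
            m = np.eye(4)
            m[:3, :3] = A
            ours = rigid_component(AffineTransform(m)).matrix[:3, :3]
            oracle, _ = scipy.linalg.polar(A)  # independent orthogonal-factor computation
            assert np.allclose(ours, oracle, atol=1e-10)

    def test_reflection_rejected(self):
        m = np.diag([-1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            rigid_component(AffineTransform(m))


class TestResample:
    def test_identity_same_grid_is_identity(self, rng):
        v = _vol(rng.random((10, 11, 12)))
        out = resample(v, AffineTransform.identity(), v, Interp.LINEAR)
        assert np.allclose(out.data, v.data, atol=1e-5)

    def test_integer_translation_nearest_is_exact_shift(self, rng):
        data = np.zeros((10, 10, 10))
        data[3:6, 3:6, 3:6] = rng.random((3, 3, 3)) + 1
        v = _vol(data)
        t = AffineTransform.from_rigid((2, 1, -1))
        out = resample(v, t, v, Interp.NEAREST)
        assert np.allclose(out.data[5:8, 4:7, 2:5], data[3:6, 3:6, 3:6])

    def test_mask_stays_binary_under_nearest(self, rng):
        m = LabelMask((rng.random((9, 9, 9)) < 0.4).astype(np.uint8))
        out = resample(m, AffineTransform.from_rigid((0.4, -0.7, 1.2), (3, 1, -2)), m,
                       Interp.NEAREST)
        assert isinstance(out, LabelMask)
        assert set(np.unique(out.data)) <= {0, 1}

    def test_mask_with_linear_interp_rejected(self):
        m = LabelMask(np.ones((4, 4, 4), dtype=np.uint8))
        with pytest.raises(ValueError, match="NEAREST"):
            resample(m, AffineTransform.identity(), m, Interp.LINEAR)


@pytest.fixture(scope="module")
def phantom_t1():
    cfg = PhantomConfig(seed=21, misalign_mm=0, misalign_deg=0, noise_sd=2.0)
    case, _ = generate_case(cfg)
    return case.t1


class TestRegistration:
    @staticmethod
    def _center(v):
        return v.affine[:3, :3] @ ((np.asarray(v.shape) - 1) / 2) + v.affine[:3, 3]

    def test_self_registration_is_identity(self, phantom_t1):
        rec = register_affine(phantom_t1, phantom_t1, dof=Dof.RIGID)
        disp, ang = transform_error(rec, AffineTransform.identity(), self._center(phantom_t1))
        assert disp < 0.1 and ang < 0.1

    def test_known_translation_recovered(self, phantom_t1):
        true = AffineTransform.from_rigid((4, -3, 2))
        moved = resample(phantom_t1, true.inverse(), phantom_t1, Interp.LINEAR)
        rec = register_affine(moved, phantom_t1, dof=Dof.RIGID)
        assert np.abs(rec.translation - (4, -3, 2)).max() < 0.5

    def test_known_rotation_translation_recovered(self, phantom_t1):
        c = self._center(phantom_t1)
        true = AffineTransform.from_rigid((6, -8, 3), (0, 0, 5), center_mm=c)
        moved = resample(phantom_t1, true.inverse(), phantom_t1, Interp.LINEAR)
        rec = register_affine(moved, phantom_t1, dof=Dof.RIGID)
        disp, ang = transform_error(rec, true, c)
        assert disp < 0.5 and ang < 0.5

    def test_constant_volume_rejected(self):
        v = _vol(np.ones((8, 8, 8)))
        with pytest.raises(ValueError, match="constant"):
            register_affine(v, v)


class TestCaseToStandard:
    def test_full_case_round_trip(self, misaligned_phantom):
        """A case with inter-sequence motion and a subject pose lands on the
        template-frame ground truth after the two-step pipeline."""
        case, truth = misaligned_phantom
        # template sharing the subject's anatomy (its aligned twin, re-noised),
        # so the true pose is exactly identifiable
        twin, _ = generate_case(PhantomConfig(
            tumor_volume_cm3=10.0, misalign_mm=0, misalign_deg=0, noise_sd=2.0,
            t1gad_missing_probability=0.0, seed=5,
        ))
        nz = np.random.default_rng(0).normal(0, 2.0, twin.t1.shape)
        renoised = twin.t1.with_data(np.clip(twin.t1.data + nz * (twin.t1.data != 0), 0.5, None)
                                     * (twin.t1.data != 0))
        from mvseg.standard_space import build_template

        tpl = build_template([twin.t1, renoised], 0.30)
        std_case, ct = case_to_standard(case, tpl)
        c = tpl.template.affine[:3, :3] @ ((np.asarray(tpl.template.shape) - 1) / 2)
        disp, ang = transform_error(ct.t1_to_std, truth.t1_to_std, c)
        assert disp < 0.5 and ang < 0.5
        disp_s, ang_s = transform_error(ct.stir_to_t1, truth.stir_to_t1, c)
        assert disp_s < 0.5 and ang_s < 0.5
        overlap = dsc(std_case.reference, truth.std_mask)
        assert overlap > 0.95

    def test_absent_t1gad_stays_absent(self, small_phantom):
        case, truth = small_phantom
        case_no_gad = type(case)(
            case_id=case.case_id, t1=case.t1, stir=case.stir, t1gad=None,
            reference=case.reference, location=case.location,
        )
        stack = [generate_case(PhantomConfig(
            shape=(48, 48, 48), tumor_volume_cm3=3.0, misalign_mm=0, misalign_deg=0,
            noise_sd=2.0, seed=s))[0].t1 for s in (41, 42)]
        from mvseg.standard_space import build_template

        tpl = build_template(stack, 0.30)
        std_case, ct = case_to_standard(case_no_gad, tpl)
        assert std_case.t1gad is None
        assert ct.t1gad_to_t1 is None


class TestMaskToNative:
    def test_integer_translation_round_trip_exact(self, rng):
        m = LabelMask((rng.random((12, 12, 12)) < 0.2).astype(np.uint8))
        t = AffineTransform.from_rigid((3, -2, 1))
        ct = CaseTransforms(t1_to_std=t, stir_to_t1=AffineTransform.identity())
        std = resample(m, t, m, Interp.NEAREST)
        back = mask_to_native(std, ct, m)
        inner = tuple(slice(4, 8) for _ in range(3))
        assert np.array_equal(back.data[inner], m.data[inner])

    def test_general_rigid_round_trip_dsc(self):
        cfg = PhantomConfig(seed=51, tumor_volume_cm3=10.0, spacing_mm=1.0,
                            misalign_mm=0, misalign_deg=0, noise_sd=0.0)
        _, truth = generate_case(cfg)
        m = truth.std_mask
        c = m.affine[:3, :3] @ ((np.asarray(m.shape) - 1) / 2)
        t = AffineTransform.from_rigid((4.3, -2.7, 3.1), (4, -3, 6), center_mm=c)
        ct = CaseTransforms(t1_to_std=t, stir_to_t1=AffineTransform.identity())
        std = resample(m, t, m, Interp.NEAREST)
        back = mask_to_native(std, ct, m)
        assert dsc(back, m) > 0.9

    def test_empty_mask_stays_empty(self):
        m = LabelMask(np.zeros((8, 8, 8), dtype=np.uint8))
        ct = CaseTransforms(t1_to_std=AffineTransform.from_rigid((1.5, 0, 0), (2, 0, 0)),
                            stir_to_t1=AffineTransform.identity())
        assert mask_to_native(m, ct, m).n_voxels == 0
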