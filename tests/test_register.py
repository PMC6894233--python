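"""Registration: initialization, MI metric, refinement, re-slicing."""

import numpy as np
import pytest

from erosiotrack import (
    PhantomSpec,
    RigidTransform,
    Volume3D,
    initialize_transform,
    make_followup,
    make_phantom,
    mutual_information,
    register_rigid,
    resample_to_baseline,
)
from erosiotrack.register import EmptyOverlapError, InitializationError

SP = 0.082


def _shifted(vol: Volume3D, shift) -> Volume3D:
    """Content moved by +shift voxels (background-padded integer roll)."""
    out = np.full_like(vol.data, vol.data.min())
    src = [slice(max(0, -s), vol.data.shape[i] - max(0, s)) for i, s in enumerate(shift)]
    dst = [slice(max(0, s), vol.data.shape[i] - max(0, -s)) for i, s in enumerate(shift)]
    out[tuple(dst)] = vol.data[tuple(src)]
    return vol.with_data(out, frame="followup")


class TestInitialize:
    def test_recovers_pure_translation_within_one_voxel(self, small_phantom):
        vol, _ = small_phantom
        moving = _shifted(vol, (3, -2, 5))
        T = initialize_transform(vol, moving)
        # content moved by +d: moving coords map to fixed coords via -d
        expected = np.array([-3, 2, -5]) * SP
        assert np.all(np.abs(T.translation_mm - expected) <= SP)
        assert T.rotation_angle_deg() < 2.0

    def test_identity_for_identical_volumes(self, small_phantom):
        vol, _ = small_phantom
        T = initialize_transform(vol, vol.with_data(vol.data, frame="followup"))
        assert T.rotation_angle_deg() < 0.5
        assert np.linalg.norm(T.translation_mm) < SP

    def test_recovers_axial_rotation_within_two_degrees(self, small_phantom):
        from scipy.ndimage import rotate

        vol, _ = small_phantom
        rotated = rotate(
            vol.data, angle=10.0, axes=(1, 2), reshape=False, order=1,
            mode="constant", cval=float(vol.data.min()),
        )
        moving = vol.with_data(rotated, frame="followup")
        T = initialize_transform(vol, moving)
        true = RigidTransform.from_euler(
            (np.deg2rad(-10.0), 0, 0), center_mm=vol.center_mm()
        )
        err = T.compose(true.inverse()).rotation_angle_deg()
        assert err < 2.0

    def test_empty_foreground_raises(self):
        flat = Volume3D(np.zeros((16, 16, 16)))
        with pytest.raises(InitializationError):
            initialize_transform(flat, flat)


class TestMutualInformation:
    def test_self_similarity_equals_marginal_entropy_and_is_local_max(
        self, small_phantom
    ):
        vol, _ = small_phantom
        mi0 = mutual_information(vol, vol, stride=2)
        # joint histogram is diagonal at identity: MI = marginal entropy
        hist, _ = np.histogram(vol.data[::2, ::2, ::2], bins=32)
        p = hist / hist.sum()
        entropy = -(p[p > 0] * np.log(p[p > 0])).sum()
        assert mi0 == pytest.approx(entropy, rel=1e-3)
        for d in ((0.3, 0, 0), (0, 0.3, 0), (0, 0, 0.3)):
            T = RigidTransform.from_euler((0, 0, 0), d)
            assert mutual_information(vol, vol, T, stride=2) < mi0

    def test_independent_noise_has_near_zero_mi(self):
        rng = np.random.default_rng(0)
        a = Volume3D(rng.normal(size=(40, 40, 40)))
        b = Volume3D(rng.normal(size=(40, 40, 40)))
        # 8 bins on 64k samples: bias ~ (bins-1)^2/(2n) stays below 0.05 nats
        assert mutual_information(a, b, bins=8) < 0.05

    def test_invariant_under_bin_preserving_monotone_relabeling(self, small_phantom):
        vol, _ = small_phantom
        # affine maps preserve bin assignment under min/max normalization
        relabeled = vol.with_data(vol.data * 3.0 + 100.0)
        mi_a = mutual_information(vol, vol, stride=2)
        mi_b = mutual_information(vol, relabeled, stride=2)
        assert mi_a == pytest.approx(mi_b, rel=1e-6)

    def test_empty_overlap_raises(self, small_phantom):
        vol, _ = small_phantom
        far = RigidTransform.from_euler((0, 0, 0), (1000.0, 0, 0))
        with pytest.raises(EmptyOverlapError):
            mutual_information(vol, vol, far)


class TestRegisterRigid:
    def test_identity_pair_stays_identity(self, small_phantom):
        vol, _ = small_phantom
        res = register_rigid(vol, vol.with_data(vol.data, frame="followup"))
        assert res.transform.rotation_angle_deg() < 0.2
        assert np.linalg.norm(res.transform.translation_mm) < 0.5 * SP
        assert res.mutual_information >= res.initial_mutual_information

    def test_noisy_pair_recovers_known_motion(self):
        spec = PhantomSpec(
            grid_shape=(64, 56, 104), followup_slices=96, noise_sd=40.0, seed=3
        )
        base, _ = make_phantom(spec)
        motion = RigidTransform.from_euler(
            np.deg2rad([5.0, 0, 0]), (0.5, -0.3, 0.8), center_mm=base.center_mm()
        )
        fu, _, _ = make_followup(spec, [], motion, {}, noise_sd=40.0)
        res = register_rigid(base, fu)
        rot_err = res.transform.compose(motion.inverse()).rotation_angle_deg()
        center_err = np.linalg.norm(
            res.transform.apply(base.center_mm()) - motion.apply(base.center_mm())
        )
        assert rot_err <= 0.5
        assert center_err <= 0.5 * SP

    def test_mi_never_decreases_from_far_init(self, small_phantom, lesioned_pair):
        base = lesioned_pair["baseline"]
        fu = lesioned_pair["followup"]
        bad_init = RigidTransform.from_euler(
            (np.deg2rad(20.0), 0, 0), (0, 0, 0), center_mm=base.center_mm()
        )
        res = register_rigid(base, fu, init=bad_init)
        assert res.mutual_information >= res.initial_mutual_information

    def test_agrees_with_simpleitk_oracle(self, lesioned_pair):
        """Independent cross-check: SimpleITK's MI registration finds the
        same motion on the same pair (within half a voxel / half a degree)."""
        import SimpleITK as sitk

        base, fu = lesioned_pair["baseline"], lesioned_pair["followup"]
        ours = register_rigid(base, fu).transform

        f_img = sitk.GetImageFromArray(base.data)
        f_img.SetSpacing((SP,) * 3)
        m_img = sitk.GetImageFromArray(fu.data)
        m_img.SetSpacing((SP,) * 3)
        reg = sitk.ImageRegistrationMethod()
        reg.SetMetricAsMattesMutualInformation(32)
        reg.SetOptimizerAsRegularStepGradientDescent(1.0, 1e-4, 200)
        reg.SetOptimizerScalesFromPhysicalShift()
        reg.SetInterpolator(sitk.sitkLinear)
        init = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.MOMENTS,
        )
        reg.SetInitialTransform(init, inPlace=False)
        tf = reg.Execute(f_img, m_img)
        tf = sitk.Euler3DTransform(sitk.CompositeTransform(tf).GetNthTransform(0))
        # sitk maps fixed physical (x,y,z) -> moving; ours maps moving->fixed
        R_sitk = np.array(tf.GetMatrix()).reshape(3, 3)[::-1, ::-1]
        sitk_T = RigidTransform(
            rotation=R_sitk.T,
            translation_mm=-R_sitk.T @ (
                np.array(tf.GetTranslation())[::-1]
                + np.array(tf.GetCenter())[::-1]
                - R_sitk @ np.array(tf.GetCenter())[::-1]
            ),
        )
        diff = ours.compose(sitk_T.inverse())
        assert diff.rotation_angle_deg() < 0.5
        center = base.center_mm()
        assert np.linalg.norm(ours.apply(center) - sitk_T.apply(center)) < 0.5 * SP


class TestResample:
    def test_identity_on_own_grid_is_exact(self, small_phantom):
        vol, _ = small_phantom
        out, valid = resample_to_baseline(vol, RigidTransform.identity(), vol)
        assert valid.all()
        assert np.allclose(out.data, vol.data, atol=1e-5)

    def test_integer_translation_matches_index_shift(self, small_phantom):
        vol, _ = small_phantom
        shift = (4, -3, 6)
        moving = _shifted(vol, shift)
        T = RigidTransform.from_euler((0, 0, 0), tuple(-np.array(shift) * SP))
        out, valid = resample_to_baseline(moving, T, vol)
        assert np.allclose(out.data[valid], vol.data[valid], atol=1e-4)
        assert valid.mean() > 0.8

    def test_constant_volume_stays_constant_on_valid_voxels(self):
        const = Volume3D(np.full((30, 30, 30), 7.0))
        T = RigidTransform.from_euler((0.2, -0.1, 0.15), (0.4, -0.2, 0.3))
        out, valid = resample_to_baseline(const, T, const)
        assert np.allclose(out.data[valid], 7.0, atol=1e-5)

    def test_round_trip_within_interpolation_blur(self, small_phantom, small_spec):
        vol, _ = small_phantom
        T = RigidTransform.from_euler(
            np.deg2rad([4.0, -3.0, 2.0]), (0.3, -0.2, 0.5),
            center_mm=vol.center_mm(),
        )
        fwd, v1 = resample_to_baseline(vol, T.inverse(), vol)
        back, v2 = resample_to_baseline(fwd, T, vol)
        both = v1 & v2
        mae = np.abs(back.data[both] - vol.data[both]).mean()
        assert mae <= 0.02 * small_spec.intensity_bone
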