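import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ivmproc import (
    LandmarkSet,
    PhantomSpec,
    RigidTransform3D,
    SessionTransform,
    align_replicates_translation,
    fit_rigid,
    landmark_residuals,
    make_phantom,
    make_serial_pair,
    make_validation_replicates,
    register_serial,
    resample_volume,
)
from ivmproc.core_io import Stack5D
from ivmproc.register3d import DegenerateLandmarksError


def _random_rigid(rng):
    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return RigidTransform3D(R=R, t=t)


class TestFitRigid:
    def test_identical_point_sets_give_identity(self):
        pts = np.array([[0.0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]])
        xform, report = fit_rigid(LandmarkSet(moving=pts, reference=pts))
        assert np.allclose(xform.R, np.eye(3), atol=1e-12)
        assert np.allclose(xform.t, 0.0, atol=1e-12)
        assert report["rms_um"] < 1e-12

    def test_quarter_turn_about_z(self):
        moving = np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]])
        reference = np.array([[0.0, 1, 0], [-1, 0, 0], [0, 0, 1], [0, 0, 0]])
        xform, _ = fit_rigid(LandmarkSet(moving=moving, reference=reference))
        assert np.allclose(xform.R, [[0, -1, 0], [1, 0, 0], [0, 0, 1]], atol=1e-12)
        assert np.allclose(xform.t, 0.0, atol=1e-12)

    def test_exact_recovery_over_random_transforms(self):
        # noiseless correspondences from 100 random rigid motions
        rng = np.random.default_rng(77)
        for _ in range(100):
            true = _random_rigid(rng)
            n = rng.integers(4, 21)
            moving = rng.uniform(0, 100, (n, 3))
            fitted, _ = fit_rigid(LandmarkSet(moving=moving, reference=true.apply(moving)))
            assert np.linalg.norm(fitted.R - true.R) < 1e-6
            assert np.abs(fitted.t - true.t).max() < 1e-6

    def test_noisy_landmarks_recover_rotation_within_one_degree(self):
        rng = np.random.default_rng(15)
        true = _random_rigid(rng)
        moving = rng.uniform(0, 100, (15, 3))
        reference = true.apply(moving) + rng.normal(0, 0.5, (15, 3))
        fitted, report = fit_rigid(LandmarkSet(moving=moving, reference=reference))
        delta = Rotation.from_matrix(fitted.R @ true.R.T).magnitude()
        assert np.degrees(delta) < 1.0
        # objective value matches a brute-force numerical minimization
        from scipy.optimize import minimize

        def objective(params):
            R = Rotation.from_rotvec(params[:3]).as_matrix()
            return np.sum((moving @ R.T + params[3:] - reference) ** 2)

        x0 = np.concatenate([Rotation.from_matrix(fitted.R).as_rotvec(), fitted.t])
        best = minimize(objective, x0, method="Nelder-Mead", options={"xatol": 1e-12, "fatol": 1e-12})
        ours = np.sum((fitted.apply(moving) - reference) ** 2)
        assert ours <= best.fun + 1e-9

    def test_swap_gives_inverse_transform(self):
        rng = np.random.default_rng(31)
        true = _random_rigid(rng)
        moving = rng.uniform(0, 50, (12, 3))
        lm = LandmarkSet(moving=moving, reference=true.apply(moving))
        fwd, _ = fit_rigid(lm)
        bwd, _ = fit_rigid(LandmarkSet(moving=lm.reference, reference=lm.moving))
        assert np.allclose(bwd.R, fwd.R.T, atol=1e-9)
        assert np.allclose(bwd.t, -fwd.R.T @ fwd.t, atol=1e-9)

    def test_rotation_is_always_proper(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            moving = rng.uniform(0, 10, (6, 3))
            reference = rng.uniform(0, 10, (6, 3))  # arbitrary, even reflective-looking
            xform, _ = fit_rigid(LandmarkSet(moving=moving, reference=reference))
            assert np.allclose(xform.R.T @ xform.R, np.eye(3), atol=1e-10)
            assert np.linalg.det(xform.R) == pytest.approx(1.0, abs=1e-10)

    def test_degenerate_configurations_rejected(self):
        two = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateLandmarksError, match=">= 3"):
            fit_rigid(LandmarkSet(moving=two, reference=two))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateLandmarksError, match="collinear"):
            fit_rigid(LandmarkSet(moving=line, reference=line))


class TestLandmarkResiduals:
    def test_exact_correspondence_zero(self):
        rng = np.random.default_rng(8)
        true = _random_rigid(rng)
        moving = rng.uniform(0, 30, (6, 3))
        res, rms = landmark_residuals(
            LandmarkSet(moving=moving, reference=true.apply(moving)), true
        )
        assert np.allclose(res, 0.0, atol=1e-10) and rms < 1e-10

    def test_single_offset_pair_under_identity(self):
        lm = LandmarkSet(
            moving=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [3, 2, 2]]),
            reference=np.array([[0.0, 0, 2.0], [1, 0, 0], [0, 1, 0], [3, 2, 2]]),
        )
        res, rms = landmark_residuals(lm, RigidTransform3D.identity())
        assert res[0] == pytest.approx(2.0)
        assert rms == pytest.approx(np.sqrt(np.mean(res**2)))


class TestLandmarkCSV:
    def test_bigwarp_dialect_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        lm = LandmarkSet(
            moving=rng.uniform(0, 100, (5, 3)),
            reference=rng.uniform(0, 100, (5, 3)),
            active=np.array([True, True, False, True, True]),
        )
        lm.to_csv(tmp_path / "lm.csv")
        back = LandmarkSet.from_csv(tmp_path / "lm.csv")
        assert np.allclose(back.moving, lm.moving)
        assert np.allclose(back.reference, lm.reference)
        assert np.array_equal(back.active, lm.active)
        assert back.names == lm.names


class TestResampleVolume:
    def test_identity_is_exact_copy(self, small_phantom):
        out = resample_volume(small_phantom, RigidTransform3D.identity())
        assert np.allclose(out.data, small_phantom.data)

    def test_integer_voxel_translation_is_exact(self):
        rng = np.random.default_rng(4)
        s = Stack5D(rng.integers(0, 500, (1, 6, 1, 16, 16)), voxel_size=(2.0, 0.5, 0.5))
        # translate by exactly (2 vox z, 3 vox y, -1 vox x) in physical units
        xform = RigidTransform3D(R=np.eye(3), t=np.array([-1 * 0.5, 3 * 0.5, 2 * 2.0]))
        out = resample_volume(s, xform)
        assert np.array_equal(out.data[0, 2:, 0, 3:, :15], s.data[0, :4, 0, :13, 1:])

    def test_all_outside_gives_zero_volume(self, small_phantom):
        xform = RigidTransform3D(R=np.eye(3), t=np.array([1e6, 1e6, 1e6]))
        assert np.all(resample_volume(small_phantom, xform).data == 0)

    def test_mean_intensity_preserved_for_inbounds_motion(self, small_spec):
        ref, mov, lms, true_x = make_serial_pair(
            small_spec, SessionTransform(rot_z_deg=5.0, translation_um=(2.0, 1.0, 0.0))
        )
        aligned = resample_volume(mov, true_x)
        inner = (0, slice(2, -2), slice(None), slice(12, -12), slice(12, -12))
        assert np.mean(aligned.data[inner]) == pytest.approx(np.mean(ref.data[inner]), rel=0.02)


class TestRegisterSerial:
    def test_phantom_pair_realigns_above_095_correlation(self, small_spec):
        xf = SessionTransform(rot_z_deg=10.0, translation_um=(3.0, -2.0, 1.0))
        ref, mov, lms, _ = make_serial_pair(small_spec, xf, n_landmarks=15)
        before = np.corrcoef(mov.data.ravel(), ref.data.ravel())[0, 1]
        aligned, report = register_serial(mov, ref, lms)
        inner = (0, slice(1, -1), slice(None), slice(8, -8), slice(8, -8))
        after = np.corrcoef(aligned.data[inner].ravel(), ref.data[inner].ravel())[0, 1]
        assert report["rms_um"] < 1e-6
        assert after > 0.95 and after > before

    def test_two_landmarks_degenerate(self, small_phantom):
        lm = LandmarkSet(moving=np.zeros((2, 3)), reference=np.zeros((2, 3)))
        with pytest.raises(DegenerateLandmarksError):
            register_serial(small_phantom, small_phantom, lm)


class TestAlignReplicates:
    def test_identical_replicates_zero_offsets(self, small_phantom):
        from ivmproc import corrupt, PoissonGaussianModel

        rep = corrupt(small_phantom, PoissonGaussianModel(4.0, 10.0), seed=1)
        aligned, offsets = align_replicates_translation([rep, rep, rep])
        assert np.allclose(offsets, 0.0, atol=0.05)
        assert all(np.array_equal(a.data, rep.data) for a in aligned)

    def test_known_integer_offset_recovered(self, small_phantom):
        from scipy import ndimage as ndi

        shifted_data = np.empty_like(small_phantom.data)
        for c in range(small_phantom.n_c):
            shifted_data[0, :, c] = ndi.shift(
                small_phantom.data[0, :, c].astype(float), (2, -1, 3), order=0, mode="nearest"
            )
        shifted = small_phantom.with_data(shifted_data)
        _, offsets = align_replicates_translation([small_phantom, shifted])
        assert np.abs(offsets[1] - np.array([2, -1, 3])).max() < 0.5

    def test_generator_jitter_recovered(self, default_noise):
        spec = PhantomSpec(
            shape=(1, 10, 2, 64, 64), n_filaments=4, n_tubes=1, n_puncta=4, n_fibrils=4, seed=6
        )
        reps, _, offsets_vox = make_validation_replicates(
            spec, n=4, model=default_noise, jitter_um=1.5, seed=6
        )
        _, est = align_replicates_translation(reps)
        true_rel = offsets_vox - offsets_vox[0]
        assert np.abs(est[1:] - true_rel[1:]).max() < 0.5

    def test_geometry_mismatch_rejected(self, small_phantom):
        other = Stack5D(np.zeros((1, 2, 1, 8, 8), dtype=np.uint16))
        with pytest.raises(ValueError, match="shape"):
            align_replicates_translation([small_phantom, other])
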