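import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from ivmproc import (
    PhantomSpec,
    PoissonGaussianModel,
    VSTConfig,
    build_estimation_tile,
    chunk_plan,
    collaborative_filter,
    corrupt,
    denoise_vst,
    estimate_noise_sigma,
    gat_forward,
    gat_inverse,
    make_phantom,
    median3d,
    rescale_unit,
    unrescale_unit,
)
from ivmproc.core_io import Stack5D
from ivmproc.denoise import estimation_slice_indices


class TestNoiseSigmaEstimation:
    def test_flat_image_with_known_gaussian_noise(self):
        rng = np.random.default_rng(0)
        img = 200.0 + rng.normal(0, 10.0, (512, 512))
        assert 9.0 <= estimate_noise_sigma(img) <= 11.0

    def test_structure_rejected_on_noise_free_edge(self):
        # a step edge has sparse diagonal wavelet energy: the MAD ignores it
        img = np.zeros((256, 256))
        img[:, 128:] = 1000.0
        assert estimate_noise_sigma(img) < 1.0

    def test_constant_image_returns_zero(self):
        assert estimate_noise_sigma(np.full((64, 64), 7.0)) == 0.0

    def test_matches_wavelet_mad_reference(self):
        # independent cross-check against the scikit-image estimator, which
        # implements the same robust wavelet-domain principle
        from skimage.restoration import estimate_sigma as skimage_sigma

        rng = np.random.default_rng(3)
        base = ndimage.gaussian_filter(rng.random((256, 256)), 4) * 500
        img = base + rng.normal(0, 5.0, base.shape)
        ours = estimate_noise_sigma(img)
        ref = float(skimage_sigma(img))
        assert ours == pytest.approx(ref, rel=0.15)
        assert ours == pytest.approx(5.0, rel=0.10)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="16x16"):
            estimate_noise_sigma(np.zeros((8, 8)))


class TestEstimationTile:
    def test_slice_selection_45_of_10(self):
        # 45 slices, up to 10: round(linspace(0, 44, 10))
        idx = estimation_slice_indices(45, 10)
        assert idx.tolist() == [0, 5, 10, 15, 20, 24, 29, 34, 39, 44]

    def test_fewer_slices_than_max_gives_grid_with_empty_cell(self):
        rng = np.random.default_rng(1)
        stack = Stack5D(rng.integers(0, 100, (1, 8, 1, 16, 16)))
        tile = build_estimation_tile(stack, max_slices=10)
        # 8 slices arranged in a 3-column grid: 3 rows, one empty cell
        assert tile.shape == (3 * 16, 3 * 16)
        assert np.array_equal(tile[:16, :16], stack.data[0, 0, 0])
        assert np.all(tile[32:, 32:] == 0)  # zero-padded ninth cell

    def test_single_slice_passthrough(self):
        rng = np.random.default_rng(2)
        stack = Stack5D(rng.integers(0, 100, (1, 1, 1, 16, 16)))
        assert np.array_equal(build_estimation_tile(stack, 10), stack.data[0, 0, 0])


class TestGAT:
    def test_forward_closed_form_at_zero(self):
        m = PoissonGaussianModel(alpha=1.0, sigma=0.0, mu=0.0)
        assert gat_forward(np.array(0.0), m) == pytest.approx(2 * np.sqrt(3 / 8), abs=1e-9)

    def test_nonpositive_radicand_clamped(self):
        m = PoissonGaussianModel(alpha=1.0, sigma=0.0, mu=10.0)
        assert gat_forward(np.array(5.0), m) == 0.0

    def test_variance_stabilized_to_unity(self):
        # Poisson-Gaussian draws at photon means 20..2000 all map to ~unit variance
        rng = np.random.default_rng(17)
        m = PoissonGaussianModel(alpha=1.0, sigma=2.0, mu=0.0)
        for y in np.geomspace(20, 2000, 6):
            z = rng.poisson(y, 10_000) + rng.normal(0, 2.0, 10_000)
            v = np.var(gat_forward(z, m), ddof=1)
            assert 0.9 <= v <= 1.1

    def test_algebraic_inverse_is_exact_on_range(self):
        for m in (
            PoissonGaussianModel(1.0, 0.0, 0.0),
            PoissonGaussianModel(2.5, 6.0, 0.0),
            PoissonGaussianModel(4.0, 10.0, 1.0),
        ):
            z = np.array([0.0, 1.0, 10.0, 1000.0])
            back = gat_inverse(gat_forward(z, m), m, "algebraic")
            assert np.abs(back - z).max() < 1e-9

    def test_unbiased_inverse_recovers_poisson_mean(self):
        # the exact unbiased inverse acts on E[f(z)] (a denoised value) and
        # undoes the small-count bias the algebraic inverse leaves behind
        rng = np.random.default_rng(23)
        m = PoissonGaussianModel(alpha=1.0, sigma=0.0, mu=0.0)
        z = rng.poisson(20, 100_000).astype(float)
        mean_stab = float(np.mean(gat_forward(z, m)))
        est = float(gat_inverse(np.array(mean_stab), m, "exact_unbiased"))
        assert est == pytest.approx(20.0, rel=0.01)
        # contrast: algebraic inverse of the mean is visibly biased at y=1
        z1 = rng.poisson(1, 100_000).astype(float)
        alg = float(gat_inverse(np.array(np.mean(gat_forward(z1, m))), m, "algebraic"))
        unb = float(gat_inverse(np.array(np.mean(gat_forward(z1, m))), m, "exact_unbiased"))
        assert abs(alg - 1.0) > 0.1
        assert abs(unb - 1.0) < 0.05

    def test_below_minimum_clamps_to_zero(self):
        m = PoissonGaussianModel(alpha=1.0, sigma=0.0, mu=0.0)
        assert gat_inverse(np.array(0.0), m, "exact_unbiased") == 0.0
        assert gat_inverse(np.array(0.5), m, "algebraic") == 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            gat_inverse(np.ones(3), PoissonGaussianModel(), "bogus")


class TestRescaleUnit:
    def test_linear_map_and_exact_inverse(self):
        x = np.array([2.0, 3.0, 6.0])
        scaled, rec = rescale_unit(x)
        assert np.allclose(scaled, (x - 2) / 4)
        assert np.abs(unrescale_unit(scaled, rec) - x).max() < 1e-12

    def test_constant_input_degenerate(self):
        scaled, rec = rescale_unit(np.full(5, 3.3))
        assert rec.degenerate and np.all(scaled == 0)
        assert np.allclose(unrescale_unit(scaled, rec), 3.3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rescale_unit(np.array([1.0, np.inf]))


def _brute_force_median(vol, r):
    out = np.empty_like(vol, dtype=np.float64)
    nz, ny, nx = vol.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                block = vol[
                    max(z - r, 0) : z + r + 1,
                    max(y - r, 0) : y + r + 1,
                    max(x - r, 0) : x + r + 1,
                ]
                out[z, y, x] = np.median(block)
    return out


class TestMedian3D:
    def test_constant_stack_unchanged(self):
        s = Stack5D(np.full((1, 6, 1, 10, 10), 42, dtype=np.uint16))
        assert np.array_equal(median3d(s, 2).data, s.data)

    def test_impulse_removed(self):
        data = np.full((1, 9, 1, 16, 16), 50, dtype=np.uint16)
        data[0, 4, 0, 8, 8] = 60000
        out = median3d(Stack5D(data), radius=2)
        assert out.data[0, 4, 0, 8, 8] == 50

    @pytest.mark.parametrize("radius", [1, 2])
    def test_matches_brute_force_oracle(self, radius):
        # float stack so truncated-window half-integer medians compare exactly
        rng = np.random.default_rng(radius)
        vol = rng.integers(0, 1000, (8, 16, 16)).astype(np.float32)
        s = Stack5D(vol[None, :, None], bit_depth=32, is_float=True)
        out = median3d(s, radius)
        expected = _brute_force_median(vol.astype(np.float64), radius)
        assert np.array_equal(out.data[0, :, 0].astype(np.float64), expected)

    @pytest.mark.parametrize("radius", [1, 2])
    def test_integer_stack_matches_rounded_oracle(self, radius):
        rng = np.random.default_rng(10 + radius)
        vol = rng.integers(0, 1000, (6, 12, 12)).astype(np.uint16)
        out = median3d(Stack5D(vol[None, :, None]), radius)
        expected = np.floor(_brute_force_median(vol.astype(np.float64), radius) + 0.5)
        assert np.array_equal(out.data[0, :, 0].astype(np.float64), expected)

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            median3d(Stack5D(np.zeros((1, 1, 1, 4, 4), dtype=np.uint16)), 0)


class TestChunkPlan:
    def test_reference_layout_25_10_5(self):
        plan = chunk_plan(25, 10, 5)
        assert [(a, b) for a, b, _, _ in plan] == [(0, 10), (5, 15), (10, 20), (15, 25)]

    def test_keep_ranges_partition_reference_case(self):
        plan = chunk_plan(25, 10, 5)
        owned = sorted(f for _, _, ka, kb in plan for f in range(ka, kb))
        assert owned == list(range(25))
        for a, b, ka, kb in plan:
            assert a <= ka < kb <= b

    def test_short_stack_single_chunk(self):
        assert chunk_plan(7, 10, 5) == [(0, 7, 0, 7)]

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(n=st.integers(1, 200), length=st.integers(1, 40), overlap=st.integers(0, 39))
    def test_partition_property(self, n, length, overlap):
        if overlap >= length:
            overlap = length - 1
        plan = chunk_plan(n, length, overlap)
        owned = sorted(f for _, _, ka, kb in plan for f in range(ka, kb))
        assert owned == list(range(n))
        for a, b, ka, kb in plan:
            assert 0 <= a < b <= n and a <= ka < kb <= b
            assert b - a <= length


class TestCollaborativeFilter:
    def test_noise_free_piecewise_constant_preserved(self):
        img = np.zeros((64, 64))
        img[20:40, 10:50] = 0.8
        out = collaborative_filter(img, noise_std=0.01)
        assert np.abs(out - img).mean() < 0.01

    def test_noise_reduced_at_least_threefold(self):
        rng = np.random.default_rng(5)
        sig = 0.1
        img = 0.5 + rng.normal(0, sig, (96, 96))
        out = collaborative_filter(np.clip(img, 0, 1), noise_std=sig)
        assert np.std(img - 0.5) / np.std(out - 0.5) >= 3.0

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        img = np.clip(0.5 + rng.normal(0, 0.1, (48, 48)), 0, 1)
        a = collaborative_filter(img, 0.1)
        b = collaborative_filter(img, 0.1)
        assert np.array_equal(a, b)

    def test_3d_volume_smoothing(self):
        rng = np.random.default_rng(7)
        vol = np.clip(0.5 + rng.normal(0, 0.1, (10, 32, 32)), 0, 1)
        out = collaborative_filter(vol, 0.1)
        assert out.shape == vol.shape
        assert np.std(out - 0.5) < np.std(vol - 0.5) / 3


class TestDenoiseVST:
    def test_defaults_match_published_parameters(self):
        cfg = VSTConfig()
        assert cfg.chunk_length == 10
        assert cfg.chunk_overlap == 5
        assert cfg.tile_max_slices == 10

    def test_identity_backend_round_trips_within_one_adu(self, default_noise):
        spec = PhantomSpec(
            shape=(1, 8, 2, 48, 48), n_filaments=4, n_tubes=1, n_puncta=4, n_fibrils=4, seed=4
        )
        noisy = corrupt(make_phantom(spec), default_noise, seed=4)
        for mode in ("algebraic", "exact_unbiased"):
            out, _ = denoise_vst(
                noisy,
                VSTConfig(filter_backend="identity", inverse_mode=mode),
                model=PoissonGaussianModel(alpha=default_noise.alpha),
            )
            assert np.abs(out.data.astype(int) - noisy.data.astype(int)).max() <= 1

    def test_denoising_improves_psnr_and_preserves_geometry(self, default_noise):
        from ivmproc.metrics_bench import image_metrics

        spec = PhantomSpec(
            shape=(1, 8, 3, 64, 64), n_filaments=4, n_tubes=1, n_puncta=4, n_fibrils=4, seed=8
        )
        clean = make_phantom(spec)
        gt = np.asarray(clean.data, dtype=np.float64)
        noisy = corrupt(clean, default_noise, seed=8)
        out, report = denoise_vst(noisy, model=PoissonGaussianModel(alpha=default_noise.alpha), mode="3d")
        assert out.shape == noisy.shape
        assert out.voxel_size == noisy.voxel_size
        assert out.channel_names == noisy.channel_names
        assert out.bit_depth == noisy.bit_depth
        assert set(report["sigma_per_channel"]) == set(noisy.channel_names)
        for c in range(3):
            psnr_noisy = image_metrics(gt[0, :, c], noisy.data[0, :, c].astype(float))[0]
            psnr_denoised = image_metrics(gt[0, :, c], out.data[0, :, c].astype(float))[0]
            assert psnr_denoised > psnr_noisy

    def test_float_input_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="integer"):
            denoise_vst(small_phantom)
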