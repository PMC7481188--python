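"""Inverse methods: Wiener deconvolution, f-k migration, Light-Cone
Transform, Richardson-Lucy Poisson compensation, and display helpers."""

import numpy as np
import pytest
from scipy.fft import fftn
from scipy.signal import find_peaks

from cdtomo import (
    C0,
    DiffusionKernel,
    MeasurementVolume,
    ReconstructionVolume,
    ScanGrid,
    WienerConfig,
    add_poisson_noise,
    depth_falloff_compensation,
    fk_migration,
    freespace_transient_confocal,
    lct_transform,
    max_intensity_projection,
    point_scene,
    poisson_iterative_reconstruct,
    prototype_grid,
    reconstruct,
    simulate_confocal,
    wiener_deconvolve,
)
from cdtomo.forward import convolve_kernel
from cdtomo.scenes import SceneFixtureSpec, make_fixture

DT = 0.032


def delta_kernel(pitch, dt, nxy=1, nt=2):
    v = np.zeros((nxy, nxy, nt))
    v[nxy // 2, nxy // 2, 0] = 1.0
    return DiffusionKernel(values=v, dx=pitch, dy=pitch, dt=dt, two_way=True)


@pytest.fixture(scope="module")
def blurred_point(proto_slab, proto_grid, proto_kernels):
    """Noiseless synthetic: point at 40 cm standoff convolved with phi_bar."""
    scene = point_scene(0.0, 0.0, proto_slab.z_d + 40.0,
                        reflectance_model="retroreflective")
    free = freespace_transient_confocal(scene, proto_grid, DT, 160,
                                        exit_plane_z=proto_slab.z_d)
    _, two = proto_kernels
    blur = np.maximum(convolve_kernel(free.data, two), 0.0)
    m = MeasurementVolume(data=blur, dt=DT, grid=proto_grid)
    return scene, free, m


class TestWienerDeconvolve:
    def test_delta_kernel_identity_at_large_alpha(self, blurred_point):
        _, free, _ = blurred_point
        dk = delta_kernel(free.grid.pitch, DT)
        out = wiener_deconvolve(free, dk, WienerConfig(alpha=1e14))
        np.testing.assert_allclose(out.data, free.data, rtol=1e-6,
                                   atol=1e-10 * free.data.max())

    def test_round_trip_recovers_on_conditioned_frequencies(self, proto_slab,
                                                            proto_grid,
                                                            proto_kernels):
        # noiseless tau = phi_bar * I with a large alpha recovers I on every
        # frequency carrying usable kernel power; I is supported away from
        # the window edges so the recorded volume holds the full (linear)
        # convolution
        one, _ = proto_kernels
        from cdtomo import two_way_kernel
        two = two_way_kernel(DiffusionKernel(values=one.values[12:21, 12:21, :48],
                                             dx=one.dx, dy=one.dy, dt=one.dt))
        rng = np.random.default_rng(1)
        free = np.zeros((32, 32, 160))
        free[10:22, 10:22, 40:60] = rng.random((12, 12, 20))
        # mild smoothing keeps I essentially in-band, so the non-negativity
        # clamp on the deconvolved output does not fold out-of-band ringing
        # back into the compared spectrum
        from scipy.ndimage import gaussian_filter
        free = gaussian_filter(free, sigma=(1.0, 1.0, 2.0), mode="constant")
        m = MeasurementVolume(
            data=np.maximum(convolve_kernel(free, two), 0.0), dt=DT,
            grid=proto_grid)
        dec = wiener_deconvolve(m, two, WienerConfig(alpha=1e12))
        shape = (64, 64, 320)
        kpad = np.zeros(shape)
        kpad[:9, :9, :48] = two.values
        kpad = np.roll(kpad, (-4, -4), axis=(0, 1))
        spec = np.abs(fftn(kpad))
        # keep frequencies with kernel power above 1e-6 of peak power;
        # below that the relative-alpha = 1e12 filter itself attenuates by
        # an O(1) factor, so recovery there is not meaningful
        mask = spec**2 > 1e-6 * (spec**2).max()
        F_dec = fftn(dec.data, s=shape)
        F_free = fftn(free, s=shape)
        rel = (np.linalg.norm((F_dec - F_free)[mask])
               / np.linalg.norm(F_free[mask]))
        assert rel < 1e-3

    def test_restores_time_of_flight(self, blurred_point, proto_kernels):
        # the kernel's bulk delay is part of its spectrum: deconvolution
        # moves the peak back to the free-space arrival bin
        scene, free, m = blurred_point
        _, two = proto_kernels
        dec = wiener_deconvolve(m, two, WienerConfig(alpha=1e6))
        assert (dec.data[16, 16].argmax()
                == pytest.approx(free.data[16, 16].argmax(), abs=1))

    def test_linearity(self, blurred_point, proto_kernels):
        _, _, m = blurred_point
        _, two = proto_kernels
        cfg = WienerConfig(alpha=100.0)
        w1 = wiener_deconvolve(m, two, cfg).data
        m2 = MeasurementVolume(data=3.0 * m.data, dt=m.dt, grid=m.grid)
        w2 = wiener_deconvolve(m2, two, cfg).data
        np.testing.assert_allclose(w2, 3.0 * w1, rtol=1e-9, atol=1e-9 * w1.max())

    def test_zero_kernel_and_bad_alpha_rejected(self, blurred_point):
        _, _, m = blurred_point
        zk = DiffusionKernel(values=np.zeros((1, 1, 4)), dx=m.grid.pitch,
                             dy=m.grid.pitch, dt=DT, two_way=True)
        with pytest.raises(ValueError, match="zero"):
            wiener_deconvolve(m, zk)
        with pytest.raises(ValueError, match="alpha"):
            WienerConfig(alpha=-1.0)
        with pytest.raises(ValueError, match="pad_factor"):
            WienerConfig(pad_factor=3)


class TestFkMigration:
    def test_zero_in_zero_out(self, proto_grid):
        m = MeasurementVolume(data=np.zeros((32, 32, 64)), dt=DT, grid=proto_grid)
        vol = fk_migration(m)
        assert not vol.albedo.any()

    def test_point_target_localization_no_diffusion(self, proto_slab, proto_grid):
        scene = point_scene(0.0, 0.0, proto_slab.z_d + 50.0,
                            reflectance_model="retroreflective")
        free = freespace_transient_confocal(scene, proto_grid, DT, 160,
                                            exit_plane_z=proto_slab.z_d)
        vol = fk_migration(free, C0, z0=proto_slab.z_d)
        x, y, z = vol.argmax_position()
        assert abs(x) <= proto_grid.pitch and abs(y) <= proto_grid.pitch
        assert abs(z - (proto_slab.z_d + 50.0)) <= vol.voxel_size[2]

    def test_two_targets_axially_9cm_apart_resolved(self, proto_slab, proto_grid,
                                                    sharp_irf):
        spec = SceneFixtureSpec(kind="two_points", standoffs=(40.0, 49.0),
                                z_d=proto_slab.z_d,
                                reflectance_model="retroreflective")
        scene = make_fixture(spec)
        m = simulate_confocal(scene, proto_slab, proto_grid, sharp_irf, DT, 160)
        vol = reconstruct(m, proto_slab, WienerConfig(alpha=1e6), method="fk")
        prof = vol.albedo.max(axis=(0, 1))
        zs = vol.zs
        sel = zs < 65.0  # exclude window-edge artifacts
        peaks, _ = find_peaks(prof[sel], height=0.4 * prof[sel].max(),
                              distance=int(4.0 / vol.voxel_size[2]))
        assert len(peaks) == 2
        np.testing.assert_allclose(np.sort(zs[sel][peaks]),
                                   [42.54, 51.54], atol=2.5)


class TestLct:
    def test_zero_in_zero_out(self, proto_grid):
        m = MeasurementVolume(data=np.zeros((32, 32, 64)), dt=DT, grid=proto_grid)
        vol = lct_transform(m)
        assert not vol.albedo.any()

    def test_cross_method_consistency_point_target(self, proto_slab, proto_grid):
        scene = point_scene(0.0, 0.0, proto_slab.z_d + 50.0,
                            reflectance_model="retroreflective")
        free = freespace_transient_confocal(scene, proto_grid, DT, 160,
                                            exit_plane_z=proto_slab.z_d)
        pf = fk_migration(free, C0, z0=proto_slab.z_d).argmax_position()
        pl = lct_transform(free, C0, z0=proto_slab.z_d).argmax_position()
        assert abs(pf[0] - pl[0]) <= proto_grid.pitch
        assert abs(pf[1] - pl[1]) <= proto_grid.pitch
        assert abs(pf[2] - pl[2]) <= C0 * DT / 2

    def test_planar_target_depth_profile(self, proto_slab, proto_grid, sharp_irf):
        # plane small enough that every return (corner scan points included)
        # lands inside the recorded window
        spec = SceneFixtureSpec(kind="plane", standoffs=(40.0,),
                                z_d=proto_slab.z_d, voxel_pitch=4.0,
                                reflectance_model="retroreflective",
                                lateral_extent=12.0)
        scene = make_fixture(spec)
        m = simulate_confocal(scene, proto_slab, proto_grid, sharp_irf, DT, 160)
        vol = reconstruct(m, proto_slab, WienerConfig(alpha=1e5), method="lct")
        prof = vol.albedo.max(axis=(0, 1))
        z_peak = vol.zs[prof.argmax()]
        assert z_peak == pytest.approx(proto_slab.z_d + 40.0, abs=3.0)


class TestReconstruct:
    def test_point_targets_at_three_depths(self, proto_slab, proto_grid, sharp_irf):
        # three targets at the depths used for the cone scene: 45, 65, 78 cm
        dt, nt = 0.044, 160
        spec = SceneFixtureSpec(kind="point", standoffs=(45.0,), z_d=proto_slab.z_d,
                                reflectance_model="retroreflective")
        data = None
        for s in (45.0, 65.0, 78.0):
            scene = point_scene(0.0, 0.0, proto_slab.z_d + s,
                                reflectance_model="retroreflective")
            m = simulate_confocal(scene, proto_slab, proto_grid, sharp_irf, dt, nt)
            data = m.data if data is None else data + m.data
        m = MeasurementVolume(data=data, dt=dt, grid=proto_grid)
        vol = reconstruct(m, proto_slab, WienerConfig(alpha=1e6), method="fk")
        vol = depth_falloff_compensation(vol, 2.0)
        prof = vol.albedo.max(axis=(0, 1))
        zs = vol.zs
        sel = zs < 90.0
        peaks, _ = find_peaks(prof[sel], height=0.3 * prof[sel].max(),
                              distance=int(8.0 / vol.voxel_size[2]))
        z_peaks = np.sort(zs[sel][peaks])
        # each recovered depth within the axial resolution bound (~9 cm)
        for truth in (47.54, 67.54, 80.54):
            assert np.min(np.abs(z_peaks - truth)) < 9.0

    def test_homogeneity(self, proto_slab, small_grid, sharp_irf):
        scene = point_scene(0.0, 0.0, proto_slab.z_d + 30.0,
                            reflectance_model="retroreflective")
        m = simulate_confocal(scene, proto_slab, small_grid, sharp_irf, 0.05, 96)
        cfg = WienerConfig(alpha=1e5)  # relative alpha: scale-invariant
        v1 = reconstruct(m, proto_slab, cfg, method="fk")
        m2 = MeasurementVolume(data=1e3 * m.data, dt=m.dt, grid=m.grid)
        v2 = reconstruct(m2, proto_slab, cfg, method="fk")
        np.testing.assert_allclose(v2.albedo, 1e3 * v1.albedo, rtol=1e-7,
                                   atol=1e-7 * v2.albedo.max())

    def test_letter_fixture_iou(self, proto_slab, proto_grid, sharp_irf):
        # resolution-limited overlap between a thresholded slice and the mask
        spec = SceneFixtureSpec(kind="letter_mask", letter="S", standoffs=(50.0,),
                                z_d=proto_slab.z_d, voxel_pitch=2.0,
                                reflectance_model="retroreflective",
                                lateral_extent=44.0)
        scene = make_fixture(spec)
        m = simulate_confocal(scene, proto_slab, proto_grid, sharp_irf, 0.04, 160)
        vol = reconstruct(m, proto_slab, WienerConfig(alpha=1e5), method="fk")
        img = max_intensity_projection(vol, axis="z", gamma=1.0)
        rec = img > 0.5
        # rasterize ground truth onto the scan grid
        pos, _ = scene.point_cloud()
        truth = np.zeros_like(rec)
        ix = np.round(pos[:, 0] / proto_grid.pitch + (proto_grid.nx - 1) / 2).astype(int)
        iy = np.round(pos[:, 1] / proto_grid.pitch + (proto_grid.ny - 1) / 2).astype(int)
        truth[ix.clip(0, 31), iy.clip(0, 31)] = True
        iou = (rec & truth).sum() / (rec | truth).sum()
        assert iou > 0.3

    def test_unknown_method_rejected(self, proto_slab, small_grid):
        m = MeasurementVolume(data=np.zeros((8, 8, 16)), dt=DT, grid=small_grid)
        with pytest.raises(ValueError, match="method"):
            reconstruct(m, proto_slab, method="radon")


class TestPoissonIterative:
    @pytest.fixture(scope="class")
    def counts_and_truth(self, proto_slab, irf):
        grid = ScanGrid(nx=16, ny=16, pitch=70 / 31)
        scene = point_scene(0.0, 0.0, proto_slab.z_d + 40.0,
                            reflectance_model="retroreflective")
        free = freespace_transient_confocal(scene, grid, DT, 160,
                                            exit_plane_z=proto_slab.z_d)
        m = simulate_confocal(scene, proto_slab, grid, irf, DT, 160)
        counts = add_poisson_noise(m, 1e6, 0.0, seed=7)
        from cdtomo import sampled_kernel, two_way_kernel
        two = two_way_kernel(sampled_kernel(proto_slab, grid.pitch, grid.pitch,
                                            DT, 16, 16, 160))
        return counts, free, two

    def test_likelihood_non_decreasing(self, counts_and_truth):
        counts, _, two = counts_and_truth
        est = poisson_iterative_reconstruct(counts, two, iterations=50)
        trace = np.asarray(est.meta["loglik_trace"])
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_estimate_closer_to_truth_than_raw(self, counts_and_truth):
        counts, free, two = counts_and_truth
        est = poisson_iterative_reconstruct(counts, two, iterations=50)
        scale = counts.meta["noise_scale"] * two.values.sum()
        target = free.data * scale
        err_rl = np.linalg.norm(est.data - target)
        err_raw = np.linalg.norm(counts.data - target)
        assert err_rl < err_raw

    def test_delta_kernel_fixed_point(self, counts_and_truth):
        counts, _, _ = counts_and_truth
        dk = delta_kernel(counts.grid.pitch, DT, nxy=1, nt=3)
        est = poisson_iterative_reconstruct(counts, dk, iterations=1)
        np.testing.assert_allclose(est.data, counts.data, rtol=1e-9, atol=1e-9)

    def test_requires_counts(self, counts_and_truth, proto_kernels):
        _, free, two = counts_and_truth
        with pytest.raises(ValueError, match="count"):
            poisson_iterative_reconstruct(free, two)


class TestDisplayHelpers:
    @pytest.fixture()
    def volume(self):
        rng = np.random.default_rng(3)
        return ReconstructionVolume(albedo=rng.random((6, 5, 8)),
                                    voxel_size=(2.0, 2.0, 1.0), z0=10.0)

    def test_falloff_exponent_zero_identity(self, volume):
        out = depth_falloff_compensation(volume, 0.0)
        np.testing.assert_array_equal(out.albedo, volume.albedo)

    def test_falloff_scales_slices_as_power(self):
        vol = ReconstructionVolume(albedo=np.ones((2, 2, 6)),
                                   voxel_size=(1.0, 1.0, 2.0), z0=10.0)
        out = depth_falloff_compensation(vol, 4.0)
        means = out.albedo.mean(axis=(0, 1))
        np.testing.assert_allclose(means, (vol.zs / vol.zs[0]) ** 4, rtol=1e-12)

    def test_falloff_equalizes_isotropic_targets(self):
        # two equal-albedo point returns with 1/z^4 falloff at 45 and 78 cm
        albedo = np.zeros((3, 3, 40))
        zs = 45.0 + np.arange(40) * 1.0
        k45, k78 = 0, 33
        albedo[1, 1, k45] = 45.0**-4
        albedo[1, 1, k78] = 78.0**-4
        vol = ReconstructionVolume(albedo=albedo, voxel_size=(1, 1, 1.0), z0=45.0)
        out = depth_falloff_compensation(vol, 4.0)
        p45, p78 = out.albedo[1, 1, k45], out.albedo[1, 1, k78]
        assert p78 == pytest.approx(p45, rel=0.2)

    def test_mip_basics(self, volume):
        img = max_intensity_projection(volume, axis="z", gamma=1.0)
        assert img.shape == (6, 5)
        np.testing.assert_allclose(img, volume.albedo.max(axis=2)
                                   / volume.albedo.max())
        const = ReconstructionVolume(albedo=np.full((4, 4, 4), 2.5),
                                     voxel_size=(1, 1, 1))
        np.testing.assert_array_equal(
            max_intensity_projection(const, "x", 1 / 3), np.ones((4, 4)))

    def test_single_bright_voxel_projects_once(self):
        a = np.zeros((5, 6, 7))
        a[2, 3, 4] = 1.0
        vol = ReconstructionVolume(albedo=a, voxel_size=(1, 1, 1))
        img = max_intensity_projection(vol, axis="z")
        assert img[2, 3] == 1.0 and img.sum() == 1.0

    def test_mip_argument_validation(self, volume):
        with pytest.raises(ValueError):
            max_intensity_projection(volume, axis="w")
        with pytest.raises(ValueError):
            max_intensity_projection(volume, gamma=0.0)
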