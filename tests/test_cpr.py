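"""Contact-point deconvolution, helical reconstruction, density maps."""

import numpy as np
import pytest

from afmhelix import cpr, synthetic as syn
from conftest import registered_rmsd, run_filament_pipeline


def _hemisphere(step=0.125, n=241, r_s=3.0):
    x = (np.arange(n) - n // 2) * step
    X, Y = np.meshgrid(x, x)
    rho = np.hypot(X, Y)
    return np.where(rho <= r_s,
                    np.sqrt(np.clip(r_s ** 2 - rho ** 2, 0, None)), 0.0)


class TestDeconvolve:
    def test_hemisphere_contacts_lie_on_sphere(self):
        step, n, r_s = 0.125, 241, 3.0
        surf = _hemisphere(step, n, r_s)
        tip = syn.TipModel(5.5)
        dil = syn.dilate_height_map(surf, step, tip)
        cloud = cpr.deconvolve(dil, tip, pixel_size=step, threshold=0.05,
                               oversample=2)
        c = (n // 2) * step
        d = np.sqrt((cloud.points[:, 0] - c) ** 2 +
                    (cloud.points[:, 1] - c) ** 2 + cloud.points[:, 2] ** 2)
        assert np.sqrt(np.mean((d - r_s) ** 2)) < 0.1

    def test_zero_radius_tip_is_identity(self):
        rng = np.random.default_rng(0)
        raster = np.abs(rng.normal(2.0, 0.5, (30, 20)))
        cloud = cpr.deconvolve(raster, 0.0, pixel_size=2.0, threshold=0.5)
        rows, cols = cloud.pixel_index.T
        assert np.allclose(cloud.points[:, 0], cols * 2.0)
        assert np.allclose(cloud.points[:, 1], rows * 2.0)
        assert np.allclose(cloud.points[:, 2], raster[rows, cols])

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            cpr.deconvolve(np.ones((5, 5)), -1.0, pixel_size=1.0)

    def test_cylinder_width_collapse(self):
        # dilation widens a cylinder's apparent footprint; the recovered
        # contact points collapse back to within the true diameter
        ph = syn.make_phantom(syn.PhantomParams(
            cross_section=("circle", 3.0), symmetry=1, pitch_360=200.0,
            handedness=-1, length=740.0))
        img = syn.simulate_scan(ph, syn.TipModel(5.5),
                                syn.ScanGrid(nx=200, ny=48, noise_sd=0.0),
                                seed=0)
        raster = img.heights[24 - 10:24 + 11, :].T
        apparent = np.ptp(np.nonzero(raster.max(axis=0) > 0.05)[0]) * \
            img.pixel_size
        cloud = cpr.deconvolve(raster, syn.TipModel(5.5),
                               pixel_size=img.pixel_size, threshold=0.05)
        spread = np.ptp(cloud.points[:, 0])
        assert apparent > 10.0          # dilation really widened it
        # the occluded flanks below the equator leave a genuine
        # certified-envelope ambiguity of order one pixel per side
        assert spread <= 6.0 + 2 * img.pixel_size

    def test_never_increases_apparent_height(self):
        ph = syn.make_phantom(syn.PhantomParams(
            cross_section=("ellipse", 4.0, 2.0), symmetry=2,
            pitch_360=200.0, handedness=-1, length=500.0))
        img = syn.simulate_scan(ph, syn.TipModel(2.0),
                                syn.ScanGrid(nx=260, ny=48, noise_sd=0.0),
                                seed=0)
        raster = img.heights[24 - 10:24 + 11, :].T
        cloud = cpr.deconvolve(raster, syn.TipModel(2.0),
                               pixel_size=img.pixel_size, threshold=0.3)
        # bounded by the image maximum up to the sub-pixel interpolation
        # tolerance of the upsampled eroded surface
        assert cloud.points[:, 2].max() <= raster.max() + 0.01
        assert cloud.points[:, 2].max() == pytest.approx(raster.max(),
                                                         abs=0.05)


class TestReconstruct:
    def test_circle_zero_tip(self):
        ph = syn.make_phantom(syn.PhantomParams(
            cross_section=("circle", 3.0), symmetry=1, pitch_360=200.0,
            handedness=-1, length=740.0))
        img = syn.simulate_scan(ph, syn.TipModel(0.05),
                                syn.ScanGrid(nx=400, ny=48, noise_sd=0.0),
                                seed=0)
        raster = img.heights[24 - 10:24 + 11, :].T
        cloud = cpr.deconvolve(raster, 0.0, pixel_size=img.pixel_size,
                               threshold=0.3)
        cfg = cpr.ReconstructionConfig(
            symmetry=1, periodicity_px=200 / img.pixel_size, handedness=-1)
        env = cpr.reconstruct(cloud, cfg)
        assert np.all(np.abs(env.r - 3.0) < 0.05)

    def test_ellipse_c2_accuracy(self):
        _, _, _, _, _, env = run_filament_pipeline(
            ("ellipse", 4.0, 2.0), 2, 200.0, -1, noise=0.0)
        truth = cpr.accessible_envelope(
            syn.ellipse_cross_section(4.0, 2.0), 2.0)
        assert registered_rmsd(env.r, truth) < 0.2

    def test_envelope_symmetry_invariance(self):
        _, _, _, _, _, env = run_filament_pipeline(
            ("lobed", 2.0, 3.5), 3, 240.0, -1, noise=0.255, seed=5)
        assert np.allclose(env.r, np.roll(env.r, 120), atol=1e-6)

    def test_wrong_handedness_smears(self):
        # unwinding with the opposite handedness doubles the twist
        # instead of undoing it: the pooled azimuthal scatter must be
        # strictly larger than with the correct handedness
        ph, img, tr_, est, hnd, env = run_filament_pipeline(
            ("ellipse", 4.0, 2.0), 2, 200.0, -1, noise=0.0)
        cloud = cpr.deconvolve(tr_, syn.TipModel(2.0), threshold=0.5)

        def scatter(handedness):
            cfg = cpr.ReconstructionConfig(
                symmetry=2, periodicity_px=est.cod / img.pixel_size,
                handedness=handedness)
            envh = cpr.reconstruct(cloud, cfg)
            u = cpr.unwind_cloud(cloud, cfg,
                                 axis=envh.metadata["axis"])
            r = np.hypot(u[:, 0], u[:, 1])
            bins = np.floor(u[:, 2]).astype(int) % 360
            tot = 0.0
            for b in range(360):
                sel = bins == b
                if sel.sum() > 1:
                    tot += r[sel].var() * sel.sum()
            return tot / len(r)

        assert scatter(+1) > 2 * scatter(-1)

    def test_degenerate_cloud_rejected(self):
        pts = np.column_stack([np.full(100, 5.0), np.arange(100.0),
                               np.full(100, 2.0)])
        cloud = cpr.ContactPointCloud(points=pts,
                                      pixel_index=np.zeros((100, 2), int),
                                      pixel_size=1.0)
        cfg = cpr.ReconstructionConfig(symmetry=1, periodicity_px=50.0,
                                       handedness=-1)
        with pytest.raises(ValueError):
            cpr.reconstruct(cloud, cfg)


class TestRoundTrip:
    @pytest.mark.parametrize("cs,sym,pitch", [
        (("circle", 3.0), 1, 200.0),
        (("ellipse", 4.0, 2.0), 2, 200.0),
        (("ellipse", 4.0, 2.0), 2, 120.0),
        (("lobed", 2.0, 3.5), 3, 240.0),
        (("lobed", 2.0, 3.5), 1, 150.0),
    ])
    def test_envelope_recovery(self, cs, sym, pitch):
        # phantom -> scan -> deconvolve -> reconstruct recovers the
        # tip-accessible cross-section within max(0.2 nm, 2% of r)
        ph, _, _, _, _, env = run_filament_pipeline(
            cs, sym, pitch, -1, noise=0.255, seed=sym * 17 + int(pitch))
        truth = cpr.accessible_envelope(ph.cross_section, 2.0)
        tol = max(0.2, 0.02 * truth.mean())
        assert registered_rmsd(env.r, truth) < tol

    def test_error_grows_with_tip_radius(self):
        # versus the raw cross-section, information loss (hence envelope
        # error) grows with tip size: larger tips bridge more concavity
        errs = []
        for tip_r in (0.5, 2.0, 5.5):
            ph, _, _, _, _, env = run_filament_pipeline(
                ("lobed", 1.5, 3.5), 2, 200.0, -1, tip_radius=tip_r,
                noise=0.0, seed=3)
            errs.append(registered_rmsd(env.r, ph.cross_section))
        assert errs[0] < errs[1] < errs[2]


class TestSymmetryEstimation:
    def test_c2_ellipse(self):
        ph, img, tr_, est, hnd, _ = run_filament_pipeline(
            ("ellipse", 4.0, 2.0), 2, 200.0, -1, noise=0.0)
        cloud = cpr.deconvolve(tr_, syn.TipModel(2.0), threshold=0.5)
        best, scores, low_conf = cpr.estimate_symmetry(
            tr_, cloud, est.cod / img.pixel_size, hnd, syn.TipModel(2.0))
        assert best == 2 and not low_conf

    def test_c3_lobed(self):
        ph, img, tr_, est, hnd, _ = run_filament_pipeline(
            ("lobed", 2.0, 3.5), 3, 240.0, -1, noise=0.255, seed=4)
        cloud = cpr.deconvolve(tr_, syn.TipModel(2.0))
        best, scores, low_conf = cpr.estimate_symmetry(
            tr_, cloud, est.cod / img.pixel_size, hnd, syn.TipModel(2.0))
        assert best == 3

    def test_circle_low_confidence(self):
        ph, img, tr_, est, hnd, _ = run_filament_pipeline(
            ("circle", 3.0), 1, 200.0, -1, noise=0.0)
        cloud = cpr.deconvolve(tr_, syn.TipModel(2.0), threshold=0.5)
        best, scores, low_conf = cpr.estimate_symmetry(
            tr_, cloud, 100 / img.pixel_size, -1, syn.TipModel(2.0))
        assert low_conf and best == 1


class TestDensityMap:
    def test_single_point_peak(self):
        pts = np.tile([[1.0, 2.0]], (10, 1)) + \
            np.random.default_rng(0).normal(0, 1e-9, (10, 2))
        dmap = cpr.density_map(pts, bandwidth=1.0)
        assert dmap.grid.max() == pytest.approx(1 / (2 * np.pi), rel=1e-3)

    def test_two_far_points_half_peaks(self):
        pts = np.array([[0.0, 0.0]] * 5 + [[30.0, 0.0]] * 5)
        dmap = cpr.density_map(pts, bandwidth=1.0)
        assert dmap.grid.max() == pytest.approx(1 / (4 * np.pi), rel=1e-3)

    def test_ring_has_ridge_at_radius(self):
        th = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = 3.0 * np.column_stack([np.cos(th), np.sin(th)])
        dmap = cpr.density_map(pts, bandwidth=0.3)
        iy, ix = np.unravel_index(np.argmax(dmap.grid), dmap.grid.shape)
        x = dmap.extent[0] + ix * dmap.step
        z = dmap.extent[2] + iy * dmap.step
        assert np.hypot(x, z) == pytest.approx(3.0, abs=0.15)

    def test_normalization(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(0, 2.0, (500, 2))
        dmap = cpr.density_map(pts)
        assert dmap.integral() == pytest.approx(1.0, abs=1e-3)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            cpr.density_map(np.zeros((5, 2)))


class TestAccessibleEnvelope:
    def test_convex_sections_unchanged(self):
        circ = np.full(360, 3.0)
        assert np.abs(cpr.accessible_envelope(circ, 2.0) - 3.0).max() < 0.08
        ell = syn.ellipse_cross_section(4.0, 2.0)
        assert np.abs(cpr.accessible_envelope(ell, 2.0) - ell).max() < 0.1

    def test_shapely_closing_oracle(self):
        # independent oracle: polygon buffer out/in by the tip radius
        import shapely.geometry as geom

        sec = syn.protofilament_cross_section(2.5, 2.0, 2)
        th = np.deg2rad(np.arange(360.0))
        poly = geom.Polygon(np.column_stack([sec * np.sin(th),
                                             sec * np.cos(th)]))
        closed = poly.buffer(5.5, quad_segs=64).buffer(-5.5, quad_segs=64)
        oracle = np.empty(360)
        for i, t in enumerate(th):
            ray = geom.LineString([(0, 0), (50 * np.sin(t),
                                            50 * np.cos(t))])
            inter = ray.intersection(closed)
            oracle[i] = inter.length
        ours = cpr.accessible_envelope(sec, 5.5)
        assert np.sqrt(np.mean((ours - oracle) ** 2)) < 0.1
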