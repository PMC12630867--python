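"""Reference map ingestion, helical extension, envelopes, matching."""

import numpy as np
import pytest

from afmhelix import cpr, cryoem, pipeline, population, synthetic as syn
from afmhelix import trace as tr
from conftest import registered_rmsd


def _cylinder_map(path, radius_A=30.0, vox=2.0, n=64):
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n].astype(float)
    c = (n - 1) / 2
    rr = np.hypot((xx - c) * vox, (yy - c) * vox)
    dens = (rr <= radius_A).astype(float)
    cryoem.write_map(path, dens, vox)
    return dens


def _twisted_ellipse_map(path, twist=-2.0, rise=4.8, a=40.0, b=20.0,
                         vox=2.0, n=80, nz=40):
    zz, yy, xx = np.mgrid[0:nz, 0:n, 0:n].astype(float)
    c = (n - 1) / 2
    X, Y, Z = (xx - c) * vox, (yy - c) * vox, zz * vox
    ang = np.deg2rad(twist) * Z / rise
    Xr = X * np.cos(ang) + Y * np.sin(ang)
    Yr = -X * np.sin(ang) + Y * np.cos(ang)
    dens = ((Xr / a) ** 2 + (Yr / b) ** 2 <= 1.0).astype(float)
    cryoem.write_map(path, dens, vox)
    return dens


class TestMapIO:
    def test_round_trip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        dens = rng.random((24, 20, 28)).astype(np.float32)
        p = tmp_path / "m.mrc"
        cryoem.write_map(p, dens, 1.5)
        import gemmi

        m = gemmi.read_ccp4_map(str(p))
        assert np.array_equal(np.array(m.grid), dens)

    def test_cylinder_loads_with_radius(self, tmp_path):
        p = tmp_path / "cyl.mrc"
        _cylinder_map(p)
        ref = cryoem.load_map(p, contour_level=0.5, twist=-1.2, rise=4.8,
                              accession="SYN-CYL")
        assert ref.voxel_size == pytest.approx(2.0)
        surf = cryoem.align_extend(ref, target_length=80.0)
        r = np.hypot(surf[:, 0], surf[:, 1])
        assert r.min() > 2.8 and r.max() < 3.2    # 30 A +- voxel

    def test_contour_above_max_raises(self, tmp_path):
        p = tmp_path / "cyl.mrc"
        _cylinder_map(p)
        with pytest.raises(ValueError):
            cryoem.load_map(p, contour_level=2.0, twist=-1.2, rise=4.8)

    def test_denoising_drops_stray_blobs(self, tmp_path):
        dens = np.zeros((40, 40, 40))
        dens[5:35, 18:24, 18:24] = 1.0      # main rod along z
        dens[2, 2, 2] = 1.0                 # single stray voxel
        p = tmp_path / "noisy.mrc"
        cryoem.write_map(p, dens, 2.0)
        ref = cryoem.load_map(p, contour_level=0.5, twist=-1.0, rise=4.8)
        assert ref.voxels[2, 2, 2] == 0.0
        assert ref.voxels[20, 20, 20] == 1.0


class TestAlignExtend:
    def test_cylinder_stays_cylinder(self, tmp_path):
        p = tmp_path / "cyl.mrc"
        _cylinder_map(p)
        ref = cryoem.load_map(p, contour_level=0.5, twist=-1.2, rise=4.8)
        surf = cryoem.align_extend(ref, target_length=150.0)
        r = np.hypot(surf[:, 0], surf[:, 1])
        assert np.ptp(surf[:, 2]) >= 149.0
        assert r.std() < 0.12

    def test_screw_extension_completes_half_turn(self, tmp_path):
        # twist -1.2 deg / rise 4.8 A: 180 degrees over (180/1.2)*4.8 =
        # 720 A of length; the unwound extended surface collapses to a
        # single consistent cross-section
        p = tmp_path / "ell.mrc"
        _twisted_ellipse_map(p, twist=-1.2, rise=4.8)
        ref = cryoem.load_map(p, contour_level=0.5, twist=-1.2, rise=4.8,
                              symmetry=2)
        surf = cryoem.align_extend(ref, target_length=160.0)
        assert np.ptp(surf[:, 2]) >= 144.0    # length covered (nm)
        env = cryoem.reference_envelope(surf, 0.0, twist=-1.2, rise=4.8,
                                        symmetry=2)
        truth = syn.ellipse_cross_section(4.0, 2.0)
        assert registered_rmsd(env.r, truth) < 0.25


class TestReferenceEnvelope:
    def test_cylinder_any_tip(self, tmp_path):
        p = tmp_path / "cyl.mrc"
        _cylinder_map(p)
        ref = cryoem.load_map(p, contour_level=0.5, twist=-1.2, rise=4.8)
        env = cryoem.reference_envelope(ref, syn.TipModel(5.5))
        assert np.all(np.abs(env.r - 3.0) < 0.15)
        assert env.dpf == pytest.approx(-1 / ((360 / 1.2) * 0.48), rel=1e-6)

    def test_zero_tip_equals_iso_profile(self, tmp_path):
        p = tmp_path / "ell.mrc"
        _twisted_ellipse_map(p)
        ref = cryoem.load_map(p, contour_level=0.5, twist=-2.0, rise=4.8,
                              symmetry=2)
        env = cryoem.reference_envelope(ref, 0.0)
        truth = syn.ellipse_cross_section(4.0, 2.0)
        assert registered_rmsd(env.r, truth) < 0.25

    def test_groove_narrower_than_tip_is_bridged(self):
        # deep two-lobe groove: absent from the accessible profile; the
        # shapely rolling-disk closing is the independent oracle
        import shapely.geometry as geom

        sec = syn.protofilament_cross_section(2.2, 2.0, 2)
        th = np.deg2rad(np.arange(360.0))
        ours = cpr.accessible_envelope(sec, 5.5)
        groove = slice(80, 100)
        assert ours[groove].min() > sec[groove].min() + 0.3
        poly = geom.Polygon(np.column_stack([sec * np.sin(th),
                                             sec * np.cos(th)]))
        closed = poly.buffer(5.5, quad_segs=64).buffer(-5.5, quad_segs=64)
        for i in (85, 90, 95):
            ray = geom.LineString([(0, 0), (40 * np.sin(th[i]),
                                            40 * np.cos(th[i]))])
            assert abs(ray.intersection(closed).length - ours[i]) < 0.1


class TestSimulatedReferenceImages:
    def test_cylinder_uniform_ribbon(self, tmp_path):
        p = tmp_path / "cyl.mrc"
        _cylinder_map(p)
        ref = cryoem.load_map(p, contour_level=0.5, twist=0.0, rise=4.8)
        surf = cryoem.align_extend(ref, target_length=400.0)
        img = cryoem.simulate_reference_image(
            surf, syn.TipModel(5.5),
            syn.ScanGrid(nx=220, ny=40, noise_sd=0.0), seed=0)
        prof = img.heights[20, 20:-20]
        assert prof.std() < 0.08
        assert img.heights.max() == pytest.approx(6.0, abs=0.15)

    def test_twisted_map_crossover_repeat_and_dpf(self, tmp_path):
        # dpf from (twist, rise, symmetry) must agree with the FFT of
        # the simulated image within one refined frequency bin
        p = tmp_path / "ell.mrc"
        _twisted_ellipse_map(p)
        ref = cryoem.load_map(p, contour_level=0.5, twist=-2.0, rise=4.8,
                              symmetry=2)
        surf = cryoem.align_extend(ref, target_length=800.0)
        img = cryoem.simulate_reference_image(
            surf, syn.TipModel(5.5),
            syn.ScanGrid(nx=400, ny=48, noise_sd=0.0), seed=0)
        est = tr.estimate_periodicity(img.heights[24, :], img.pixel_size,
                                      0.05)
        expected_cod = (360.0 / 2.0) * 0.48 / 2
        n = img.heights.shape[1]
        bin_width = expected_cod ** 2 / (n * img.pixel_size)
        assert est.determinate
        assert est.cod == pytest.approx(expected_cod, abs=bin_width)
        assert abs(ref.dpf) == pytest.approx(1 / est.cod, abs=0.001)


class TestCrossModality:
    def test_map_envelope_matches_afm_reconstruction(self, tmp_path):
        # the same filament seen through both routes — iso-surface
        # closing of the map vs CPR on its simulated AFM image — must
        # give the same envelope within max(0.3 nm, 3%)
        p = tmp_path / "ell.mrc"
        _twisted_ellipse_map(p)
        ref = cryoem.load_map(p, contour_level=0.5, twist=-2.0, rise=4.8,
                              symmetry=2)
        env_map = cryoem.reference_envelope(ref, syn.TipModel(5.5))
        surf = cryoem.align_extend(ref, target_length=800.0)
        img = cryoem.simulate_reference_image(
            surf, syn.TipModel(5.5),
            syn.ScanGrid(nx=400, ny=52, noise_sd=0.0), seed=0)
        img.metadata["background_sd"] = 0.05
        t = tr.trace_filament(img, (200, 26), threshold=0.5)
        cod = env_map.periodicity
        cl = tr.smooth_centerline(t.centerline, 1.3 * cod / img.pixel_size)
        t = tr.straighten(img, cl, 16.0, t)
        hnd, _ = tr.determine_handedness(t.straightened,
                                         cod / img.pixel_size)
        assert hnd == ref.hnd
        cloud = cpr.deconvolve(t, syn.TipModel(5.5), threshold=0.5)
        cfg = cpr.ReconstructionConfig(symmetry=2,
                                       periodicity_px=cod / img.pixel_size,
                                       handedness=hnd)
        env_afm = cpr.reconstruct(cloud, cfg)
        tol = max(0.3, 0.03 * env_map.r.mean())
        assert registered_rmsd(env_afm.r, env_map.r) < tol


class TestMatching:
    def test_planted_copy_ranks_first(self, study_matrix):
        refs = pipeline.reference_envelopes(5.5)
        envs = [cryoem.ReferenceEnvelope(r=refs[3].r.copy(),
                                         pitch_360=refs[3].pitch_360,
                                         handedness=refs[3].handedness,
                                         symmetry=refs[3].symmetry,
                                         filament_id="copy")] + \
            [pipeline.analytic_envelope(p, 5.5, filament_id=f"bg{i}")
             for i, p in enumerate(pipeline.sample_population_params(
                 "tris_ph7.4", 10, seed=5))]
        table, _ = cryoem.match(envs, refs, study_matrix.sigma_cs,
                                study_matrix.sigma_dpf)
        first = table.iloc[0]
        assert first["filament_id"] == "copy"
        assert first["d_xi"] == pytest.approx(0.0, abs=1e-9)
        # ranking equals a brute-force sort of the distance table
        assert (table["d_xi"].to_numpy() ==
                np.sort(table["d_xi"].to_numpy())).all()
        # rank list invariant to reference ordering
        table_r, _ = cryoem.match(envs, refs[::-1], study_matrix.sigma_cs,
                                  study_matrix.sigma_dpf)
        a = table[["filament_id", "accession"]].to_numpy().tolist()
        b = table_r[["filament_id", "accession"]].to_numpy().tolist()
        assert a == b

    def test_null_threshold_zero(self, study_matrix, reference_set,
                                 null_envelope_set):
        _, nulls = null_envelope_set
        frac, count, total = cryoem.null_match_rate(
            nulls[:200], reference_set, study_matrix.sigma_cs,
            study_matrix.sigma_dpf, threshold=0.0)
        assert count == 0 and frac == 0.0

    def test_planted_positives_counted(self, study_matrix, reference_set):
        planted = [cryoem.ReferenceEnvelope(
            r=r.r.copy(), pitch_360=r.pitch_360, handedness=r.handedness,
            symmetry=r.symmetry, filament_id=f"p{i}")
            for i, r in enumerate(reference_set[:5])]
        frac, count, total = cryoem.null_match_rate(
            planted, reference_set, study_matrix.sigma_cs,
            study_matrix.sigma_dpf)
        assert count >= 5
        assert total == 5 * len(reference_set)
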