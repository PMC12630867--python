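"""Shared fixtures: phantom scans and the population-scale study objects.

Everything is generated programmatically; expensive objects (the
400-filament study population, the 4000-spec null set, reference
envelopes) are session-scoped so the acceptance and property tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from afmhelix import cpr, pipeline, population, synthetic, trace


def run_filament_pipeline(cs, sym, pitch, hnd, tip_radius=2.0, noise=0.0,
                          seed=0, length=740.0, nx=400, ny=48,
                          symmetry_known=True):
    """Full phantom -> scan -> trace -> deconvolve -> reconstruct chain.

    Returns (phantom, image, trace, periodicity, measured handedness,
    envelope).  With ``symmetry_known`` the generator's symmetry is used
    for reconstruction; otherwise it is estimated by back-simulation.
    """
    ph = synthetic.make_phantom(synthetic.PhantomParams(
        cross_section=cs, symmetry=sym, pitch_360=float(pitch),
        handedness=hnd, length=length))
    grid = synthetic.ScanGrid(nx=nx, ny=ny, noise_sd=noise)
    tip = synthetic.TipModel(tip_radius)
    img = synthetic.simulate_scan(ph, tip, grid, seed=seed)
    if noise == 0:
        img.metadata["background_sd"] = 0.05
    thr = 0.5 if noise == 0 else None
    tr = trace.trace_filament(img, (nx // 2, ny // 2), threshold=thr)
    tmp = trace.straighten(img, tr.centerline, 16.0,
                           trace.FilamentTrace(tr.centerline,
                                               img.pixel_size))
    est0 = trace.estimate_periodicity(tmp.profile, img.pixel_size,
                                      img.background_sd)
    cod0 = est0.cod if est0.determinate else pitch / sym
    cl = trace.smooth_centerline(tr.centerline, 1.3 * cod0 / img.pixel_size)
    tr = trace.straighten(img, cl, 16.0, tr)
    est = trace.estimate_periodicity(tr.profile, img.pixel_size,
                                     img.background_sd)
    cod = est.cod if est.determinate else pitch / sym
    hnd_meas, conf = trace.determine_handedness(tr.straightened,
                                                cod / img.pixel_size)
    est.confidence = conf
    cloud = cpr.deconvolve(tr, tip, threshold=thr)
    if symmetry_known:
        use_sym = sym
    else:
        use_sym, _, _ = cpr.estimate_symmetry(tr, cloud,
                                              cod / img.pixel_size,
                                              hnd_meas or hnd, tip)
    cfg = cpr.ReconstructionConfig(symmetry=use_sym,
                                   periodicity_px=cod / img.pixel_size,
                                   handedness=hnd_meas or hnd)
    env = cpr.reconstruct(cloud, cfg)
    return ph, img, tr, est, hnd_meas, env


def registered_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Exhaustive-minimum RMSD over all cyclic shifts (test oracle)."""
    return min(float(np.sqrt(np.mean((np.roll(a, k) - b) ** 2)))
               for k in range(len(a)))


@pytest.fixture(scope="session")
def study_population():
    """The 400-filament four-condition population with planted matches."""
    envs, planted = pipeline.planted_population(n=400, seed=2026)
    return envs, planted


@pytest.fixture(scope="session")
def study_matrix(study_population):
    envs, _ = study_population
    return population.distance_matrix(envs)


@pytest.fixture(scope="session")
def reference_set():
    return pipeline.reference_envelopes(5.5)


@pytest.fixture(scope="session")
def null_envelope_set():
    from afmhelix import cryoem

    specs = synthetic.sample_null_fibrils(4000, seed=2027)
    return specs, cryoem.render_null_envelopes(specs, 5.5)
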