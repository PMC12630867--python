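"""Contact-point reconstruction and helical surface envelopes.

An AFM image records, at every pixel, the lowest position of the tip
apex for which the tip surface still clears the sample — a morphological
dilation of the sample surface by the reflected tip.  Eroding the image
with the same tip gives the certified surface estimate, and for each
pixel the point of that surface which achieved the dilation maximum is
the true tip-sample contact point.  Re-sampling the filament at those
contact points undoes the lateral broadening and recovers sub-pixel
lateral sampling.

The 3D envelope of a twisted filament is then reconstructed by helical
averaging: contact points are rotated about the helical axis according
to their axial position and the measured twist rate, pooled, and a
closed periodic spline is fitted to the pooled cross-section, giving the
mean tip-accessible radial profile r(theta) on a 1-degree grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import (TipModel, ScanGrid, simulate_scan, tip_profile,
                        GroundTruthFilament, erode_height_map)
from .trace import FilamentTrace, determine_handedness

__all__ = [
    "ContactPointCloud", "ReconstructionConfig", "HelicalEnvelope",
    "CrossSectionDensityMap", "deconvolve", "reconstruct",
    "estimate_symmetry", "density_map", "unwind_cloud",
]


# --------------------------------------------------------------------------- #
# Types
# --------------------------------------------------------------------------- #

@dataclass
class ContactPointCloud:
    """Tip-sample contact points recovered from a straightened raster.

    Coordinates in nm: x lateral (across the filament), y axial (along
    it), z height above the substrate.  ``pixel_index`` maps each point
    back to its source pixel (row, col); ``ambiguous`` flags pixels with
    flat (non-unique) tangency.
    """

    points: np.ndarray                 # (n, 3) x, y, z nm
    pixel_index: np.ndarray            # (n, 2) row, col
    pixel_size: float
    ambiguous: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ReconstructionConfig:
    """Helical parameters driving the moving-window reconstruction."""

    symmetry: int
    periodicity_px: float              # crossover repeat in pixels
    handedness: int
    spline_knots: int = 24
    axis: tuple[float, float] | None = None   # (x0, z0) nm; None = estimate
    #: contact points are only trusted near the apex of the filament, where
    #: the tip meets the surface almost vertically; the helical twist brings
    #: every azimuth through this window along the filament axis
    max_lab_azimuth: float = 50.0

    @property
    def twist_per_pixel(self) -> float:
        """Physical rotation per axial pixel, degrees (> 0)."""
        return 360.0 / (self.periodicity_px * self.symmetry)

    @property
    def window_half_length(self) -> int:
        """Axial half-window in px covering 180 degrees of twist."""
        return int(np.ceil(180.0 / self.twist_per_pixel))

    def __post_init__(self) -> None:
        if self.periodicity_px <= 0 or self.symmetry < 1:
            raise ValueError("invalid helical parameters")
        if self.handedness not in (-1, 1):
            raise ValueError("handedness must be -1 or +1")


@dataclass
class HelicalEnvelope:
    """Per-filament averaged tip-accessible cross-section r(theta).

    The unit of all population-level analysis: 360 radial samples on a
    1-degree azimuthal grid (theta measured in the azimuthal frame of
    the axial origin), plus the helical parameters.  ``dpf`` is the
    signed reciprocal of the crossover repeat (pitch_360 / symmetry):
    negative for left-handed filaments.
    """

    r: np.ndarray                       # (360,) nm
    pitch_360: float                    # nm
    handedness: int
    symmetry: int
    filament_id: str = ""
    condition: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (360,):
            raise ValueError("envelope must have 360 samples")
        if np.any(self.r <= 0):
            raise ValueError("envelope radii must be > 0")

    @property
    def periodicity(self) -> float:
        """Crossover repeat (apparent height-profile period), nm."""
        return self.pitch_360 / self.symmetry

    @property
    def dpf(self) -> float:
        """Directional periodic frequency, 1/nm (sign = handedness)."""
        return self.handedness / self.periodicity

    @property
    def dpf_360(self) -> float:
        """dpf computed against the full 360-degree pitch, 1/nm."""
        return self.handedness / self.pitch_360


@dataclass
class CrossSectionDensityMap:
    """Bivariate-normal KDE of untwisted cross-section contact points."""

    grid: np.ndarray                   # density, 1/nm^2
    extent: tuple[float, float, float, float]   # x0, x1, z0, z1 nm
    bandwidth: float                   # h (H = h^2 I), nm
    n: int
    step: float = 0.05                 # grid spacing, nm

    def integral(self) -> float:
        return float(self.grid.sum() * self.step ** 2)


# --------------------------------------------------------------------------- #
# Deconvolution (contact-point resampling)
# --------------------------------------------------------------------------- #

def deconvolve(straightened: FilamentTrace | np.ndarray, tip: TipModel | float,
               pixel_size: float | None = None,
               threshold: float | None = None,
               oversample: int = 4) -> ContactPointCloud:
    """Recover tip-sample contact points from a straightened filament.

    The raster is upsampled (cubic) to ``pixel_size / oversample``, eroded
    by the tip to the certified surface estimate, and for each filament
    pixel the contact point is the surface position maximizing
    ``surface - tip_profile`` under the tip apex — the tangency point of
    the tip with the eroded surface.  Pixels whose tangency is flat
    (several positions within 0.01 nm of the optimum) are flagged as
    ambiguous but kept.

    A tip radius of exactly 0 denotes the ideal tip: contact points are
    the pixel coordinates themselves.  Negative radii are rejected.
    """
    if isinstance(straightened, FilamentTrace):
        raster = straightened.straightened
        if raster is None:
            raise ValueError("trace has no straightened raster")
        px = straightened.pixel_size
        bg = straightened.background_sd
    else:
        raster = np.asarray(straightened, dtype=float)
        if pixel_size is None:
            raise ValueError("pixel_size required for a bare raster")
        px = pixel_size
        bg = 0.0
    radius = tip.radius if isinstance(tip, TipModel) else float(tip)
    if radius < 0:
        raise ValueError("tip radius must be >= 0")
    thr = 3.0 * bg if threshold is None else threshold

    rows, cols = np.nonzero(raster > thr)
    if radius == 0:
        pts = np.column_stack([cols * px, rows * px, raster[rows, cols]])
        return ContactPointCloud(points=pts,
                                 pixel_index=np.column_stack([rows, cols]),
                                 pixel_size=px,
                                 ambiguous=np.zeros(len(pts), bool),
                                 metadata={"tip_radius": 0.0})

    tip_obj = tip if isinstance(tip, TipModel) else TipModel(radius=radius)
    step = px / oversample
    # exact upsampling: fine index f samples original coordinate f/oversample
    ny0, nx0 = raster.shape
    fy_g = np.arange((ny0 - 1) * oversample + 1) / oversample
    fx_g = np.arange((nx0 - 1) * oversample + 1) / oversample
    YY, XX = np.meshgrid(fy_g, fx_g, indexing="ij")
    fine = ndimage.map_coordinates(raster, [YY.ravel(), XX.ravel()],
                                   order=3, mode="nearest"
                                   ).reshape(YY.shape)
    eroded = erode_height_map(fine, step, tip_obj)

    zrange = float(raster.max() - raster.min())
    rho = np.linspace(0, max(4 * radius, 4 * zrange, step), 4096)
    prof = tip_obj.profile(rho)
    reach = rho[min(np.searchsorted(prof, zrange), len(rho) - 1)]
    half = max(1, int(np.ceil(reach / step)))
    dyx = np.mgrid[-half:half + 1, -half:half + 1].reshape(2, -1)
    t_off = tip_obj.profile(np.hypot(*dyx) * step)
    keep = t_off <= zrange
    dyx = dyx[:, keep]
    t_off = t_off[keep]

    ny, nx = eroded.shape
    pts = np.empty((len(rows), 3))
    amb = np.zeros(len(rows), bool)
    fy = rows * oversample
    fx = cols * oversample
    for i in range(len(rows)):
        yy = fy[i] + dyx[0]
        xx = fx[i] + dyx[1]
        ok = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
        gain = eroded[yy[ok], xx[ok]] - t_off[ok]
        j = int(np.argmax(gain))
        near = np.count_nonzero(gain > gain[j] - 0.01)
        amb[i] = near > 1
        # z: the contact point lies on the tip surface through the
        # measured apex height AND on/below the certified (eroded)
        # surface; the smaller of the two bounds avoids the upward
        # interpolation bias of either estimate alone
        z_tip = raster[rows[i], cols[i]] + t_off[ok][j]
        pts[i] = (xx[ok][j] * step, yy[ok][j] * step,
                  min(z_tip, float(eroded[yy[ok], xx[ok]][j])))
    return ContactPointCloud(points=pts,
                             pixel_index=np.column_stack([rows, cols]),
                             pixel_size=px, ambiguous=amb,
                             metadata={"tip_radius": radius,
                                       "oversample": oversample})


# --------------------------------------------------------------------------- #
# Helical reconstruction
# --------------------------------------------------------------------------- #

def _estimate_axis(points: np.ndarray) -> tuple[float, float]:
    """Lateral position and height of the helical axis.

    x0: midpoint of the lateral extent of the upper half of the cloud
    (robust against one-sided coverage); z0: half the maximum height
    (the filament rests on the substrate and its widest azimuth touches
    both substrate and apex over one full twist).
    """
    z = points[:, 2]
    zmax = float(np.quantile(z, 0.999))    # robust apex under noise
    top = points[z > 0.5 * zmax]
    x0 = 0.5 * (np.quantile(top[:, 0], 0.02) + np.quantile(top[:, 0], 0.98))
    return float(x0), 0.5 * zmax


def _refine_axis(pts: np.ndarray, pitch_nm: float, handedness: int,
                 x0: float, z0: float) -> tuple[float, float]:
    """Refine the axis position by minimizing azimuthal envelope scatter.

    For the correct axis the unwound radii form a single-valued smooth
    function of azimuth; a mis-placed axis adds twist-phase-correlated
    scatter.  Minimizes the pooled within-bin variance of r(theta) over
    (x0, z0) with Nelder-Mead.
    """
    from scipy.optimize import minimize_scalar

    rot = -handedness * 360.0 * pts[:, 1] / pitch_nm

    def objective(x):
        dx = x - pts[:, 0]
        dz = pts[:, 2] - z0
        theta = (np.rad2deg(np.arctan2(dx, dz)) + rot) % 360.0
        r = np.hypot(dx, dz)
        b = np.floor(theta / 5.0).astype(int) % 72
        cnt = np.bincount(b, minlength=72)
        s1 = np.bincount(b, weights=r, minlength=72)
        s2 = np.bincount(b, weights=r * r, minlength=72)
        good = cnt > 1
        var = s2[good] / cnt[good] - (s1[good] / cnt[good]) ** 2
        return float(np.sum(var * cnt[good]) / cnt[good].sum())

    # z0 is pinned: for a filament resting on the substrate and sampled
    # over a full twist, apex height = 2 * axis height exactly, so the
    # lateral position is the only free axis coordinate.
    span = 3.0
    res = minimize_scalar(objective, bounds=(x0 - span, x0 + span),
                          method="bounded", options={"xatol": 1e-3})
    return float(res.x), z0


def unwind_cloud(cloud: ContactPointCloud, config: ReconstructionConfig,
                 axis: tuple[float, float] | None = None) -> np.ndarray:
    """Rotate every contact point to the azimuthal frame of y = 0.

    Returns an (n, 3) array of (x, z, theta_deg): radial plane
    coordinates after unwinding plus the unwound azimuth.  The rotation
    angle of a point at axial position y is ``-hnd * 360 * y /
    pitch_360`` about the axis, undoing the twist.
    """
    pts = cloud.points
    x0, z0 = axis if axis is not None else (
        config.axis if config.axis is not None else _estimate_axis(pts))
    pitch_nm = config.periodicity_px * cloud.pixel_size * config.symmetry
    rot = -config.handedness * 360.0 * pts[:, 1] / pitch_nm
    dx = x0 - pts[:, 0]     # azimuth runs from +z toward -lateral
    dz = pts[:, 2] - z0
    theta = np.rad2deg(np.arctan2(dx, dz))
    r = np.hypot(dx, dz)
    th_new = (theta + rot) % 360.0
    x_new = r * np.sin(np.deg2rad(th_new))
    z_new = r * np.cos(np.deg2rad(th_new))
    return np.column_stack([x_new, z_new, th_new])


def _periodic_lsq_spline(theta: np.ndarray, r: np.ndarray,
                         n_knots: int) -> np.ndarray:
    """Least-squares periodic cubic spline of r(theta), sampled at 1 deg."""
    from scipy.interpolate import LSQUnivariateSpline

    order = np.argsort(theta)
    th = theta[order]
    rr = r[order]
    # wrap-extend by 60 degrees so the fit is continuous across 0/360
    lo = th >= 300.0
    hi = th < 60.0
    th_ext = np.concatenate([th[lo] - 360.0, th, th[hi] + 360.0])
    rr_ext = np.concatenate([rr[lo], rr, rr[hi]])
    knots = np.linspace(0, 360, n_knots, endpoint=False)
    inner = knots[(knots > th_ext.min() + 1) & (knots < th_ext.max() - 1)]
    spl = LSQUnivariateSpline(th_ext, rr_ext, inner, k=3)
    return spl(np.arange(360.0))


def reconstruct(cloud: ContactPointCloud, config: ReconstructionConfig,
                window_stride: int | None = None) -> HelicalEnvelope:
    """Moving-window helical averaging of the contact-point cloud.

    Windows of axial half-length covering 180 degrees of twist are
    placed along the filament; within each window, points are rotated
    about the helical axis by their axial distance from the window
    centre times the twist per pixel (sign per handedness) and then
    referred to the common y=0 azimuthal frame, so that windows can be
    averaged without smearing.  Pooled radii are binned at 1 degree with
    3xMAD outlier rejection, averaged across windows, and smoothed with
    a closed least-squares periodic cubic spline.
    """
    if len(cloud) < config.spline_knots:
        raise ValueError("too few contact points for reconstruction")
    pts = cloud.points
    if np.ptp(pts[:, 0]) < 1e-9 or np.ptp(pts[:, 2]) < 1e-9:
        raise ValueError("degenerate (collinear) point cloud")
    if config.axis is not None:
        axis = config.axis
    else:
        x0, z0 = _estimate_axis(pts)
        pitch_nm = config.periodicity_px * cloud.pixel_size * config.symmetry
        axis = _refine_axis(pts, pitch_nm, config.handedness, x0, z0)
    lab_theta = np.rad2deg(np.arctan2(axis[0] - pts[:, 0],
                                      pts[:, 2] - axis[1]))
    trust = np.abs(lab_theta) <= config.max_lab_azimuth
    if trust.sum() < config.spline_knots:
        trust = np.ones(len(pts), dtype=bool)
    unwound = unwind_cloud(cloud, config, axis=axis)[trust]
    theta = unwound[:, 2]
    r = np.hypot(unwound[:, 0], unwound[:, 1])

    px = cloud.pixel_size
    y_px = pts[trust, 1] / px
    w = config.window_half_length
    stride = window_stride if window_stride else max(1, w // 4)
    centers = np.arange(y_px.min() + w, y_px.max() - w + 1e-9, stride)
    if len(centers) == 0:       # filament shorter than one window: widen
        import warnings
        warnings.warn("filament shorter than one helical window; "
                      "pooling all points")
        centers = np.array([0.5 * (y_px.min() + y_px.max())])
        w = np.inf

    bins = np.floor(theta).astype(int) % 360
    profiles = np.full((len(centers), 360), np.nan)
    for k, c in enumerate(centers):
        sel = np.abs(y_px - c) <= w
        if not np.any(sel):
            continue
        tb = bins[sel]
        rb = r[sel]
        sums = np.bincount(tb, weights=rb, minlength=360)
        cnts = np.bincount(tb, minlength=360)
        with np.errstate(invalid="ignore"):
            profiles[k] = np.where(cnts > 0, sums / np.maximum(cnts, 1),
                                   np.nan)
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(profiles, axis=0)
        mad = np.nanmedian(np.abs(profiles - med), axis=0)
        good = np.abs(profiles - med) <= 3.0 * 1.4826 * np.maximum(mad, 1e-3)
        mean_prof = np.nanmean(np.where(good, profiles, np.nan), axis=0)

    have = ~np.isnan(mean_prof)
    if have.sum() < config.spline_knots:
        raise ValueError("azimuthal coverage too sparse for spline fit")
    th_have = np.arange(360.0)[have]
    r_have = mean_prof[have]
    r_fit = _periodic_lsq_spline(th_have, r_have, config.spline_knots)
    r_fit = np.clip(r_fit, 1e-3, None)
    # enforce the assumed rotational symmetry by symmetrizing
    if config.symmetry > 1:
        step = 360 // config.symmetry
        r_fit = np.mean([np.roll(r_fit, s * step)
                         for s in range(config.symmetry)], axis=0)
    pitch_nm = config.periodicity_px * px * config.symmetry
    return HelicalEnvelope(r=r_fit, pitch_360=pitch_nm,
                           handedness=config.handedness,
                           symmetry=config.symmetry,
                           metadata={"axis": axis,
                                     "n_points": len(cloud),
                                     "n_windows": len(centers)})


# --------------------------------------------------------------------------- #
# Symmetry estimation
# --------------------------------------------------------------------------- #

def estimate_symmetry(straightened: FilamentTrace, cloud: ContactPointCloud,
                      periodicity_px: float, handedness: int, tip: TipModel,
                      candidates: tuple[int, ...] = (1, 2, 3, 4),
                      low_confidence_margin: float = 0.005
                      ) -> tuple[int, dict[int, float], bool]:
    """Choose the cross-sectional symmetry by back-simulation.

    For each candidate symmetry an envelope is reconstructed, a
    noiseless AFM image of it is re-simulated with the same tip, and the
    simulated twist pattern is scored against the observed straightened
    image (Pearson correlation over the filament region after axial
    phase alignment, plus agreement of the diagonal spectral asymmetry).
    Returns (best symmetry, per-candidate scores, low_confidence): when
    all scores agree within ``low_confidence_margin`` the cross-section
    is effectively rotation-invariant and symmetry 1 is reported with
    the low-confidence flag set.
    """
    obs = straightened.straightened
    px = straightened.pixel_size
    scores: dict[int, float] = {}
    for s in candidates:
        try:
            cfg = ReconstructionConfig(symmetry=s,
                                       periodicity_px=periodicity_px,
                                       handedness=handedness)
            env = reconstruct(cloud, cfg)
            sim = simulate_envelope_image(env, tip, px,
                                          n_rows=obs.shape[0],
                                          n_cols=obs.shape[1])
            scores[s] = _pattern_score(obs, sim, periodicity_px)
        except ValueError:
            scores[s] = -np.inf
    best = max(scores, key=lambda s_: scores[s_])
    vals = sorted(scores.values(), reverse=True)
    low_conf = len(vals) > 1 and (vals[0] - vals[1]) < low_confidence_margin
    if low_conf:
        best = 1
    return best, scores, low_conf


def simulate_envelope_image(env: HelicalEnvelope, tip: TipModel,
                            pixel_size: float, n_rows: int, n_cols: int
                            ) -> np.ndarray:
    """Noiseless re-simulated AFM image of an envelope (rows axial)."""
    filament = GroundTruthFilament(
        cross_section=env.r, symmetry=env.symmetry, pitch_360=env.pitch_360,
        handedness=env.handedness, length=n_rows * pixel_size)
    grid = ScanGrid(pixel_size=pixel_size, nx=n_rows, ny=n_cols,
                    noise_sd=0.0)
    img = simulate_scan(filament, tip, grid, seed=0)
    return img.heights.T        # transpose: rows axial, like straightened


def _pattern_score(obs: np.ndarray, sim: np.ndarray,
                   periodicity_px: float) -> float:
    """Correlation of observed and simulated twist patterns.

    Axial phase is aligned by maximizing the circular cross-correlation
    of the central-line profiles over one repeat; the score is the
    Pearson correlation of the two rasters over the filament region.
    """
    n = min(obs.shape[0], sim.shape[0])
    m = min(obs.shape[1], sim.shape[1])
    o = obs[:n, (obs.shape[1] - m) // 2:(obs.shape[1] - m) // 2 + m]
    s = sim[:n, (sim.shape[1] - m) // 2:(sim.shape[1] - m) // 2 + m]
    per = max(2, int(round(periodicity_px)))
    best = -np.inf
    o0 = o - o.mean()
    for shift in range(min(per, n - 1)):
        s_shift = np.roll(s, shift, axis=0)
        s0 = s_shift - s_shift.mean()
        denom = np.linalg.norm(o0) * np.linalg.norm(s0)
        c = float((o0 * s0).sum() / denom) if denom > 0 else -np.inf
        best = max(best, c)
    return best


# --------------------------------------------------------------------------- #
# Tip-accessible envelopes
# --------------------------------------------------------------------------- #

def accessible_envelope(r: np.ndarray, tip_radius: float,
                        grid_step: float = 0.05) -> np.ndarray:
    """Tip-accessible version of a polar cross-section r(theta).

    Concavities whose radius of curvature is smaller than the tip cannot
    be probed; the accessible cross-section is the morphological closing
    of the section with a disk of the tip radius.  Implemented by
    rasterizing the polygon on a fine grid, closing with a disk
    structuring element, and re-extracting the boundary radius on the
    1-degree grid.
    """
    r = np.asarray(r, dtype=float)
    n = len(r)
    if tip_radius <= 0:
        return r.copy()
    th = np.deg2rad(np.arange(n) * 360.0 / n)
    rmax = r.max() + 2 * tip_radius
    half = int(np.ceil(rmax / grid_step)) + 2
    size = 2 * half + 1
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    ang = (np.rad2deg(np.arctan2(xx, yy)) % 360.0)
    rad = np.hypot(xx, yy) * grid_step
    r_at = np.interp(ang, np.append(np.arange(n) * 360.0 / n, 360.0),
                     np.append(r, r[0]))
    mask = rad <= r_at
    # closing with a disk via Euclidean distance transforms (radius-free cost)
    disk_px = tip_radius / grid_step
    dilated = ndimage.distance_transform_edt(~mask) <= disk_px
    closed = ndimage.distance_transform_edt(dilated) > disk_px
    closed |= mask        # closing is extensive
    return _mask_boundary_radii(closed, half, grid_step, n)


def _mask_boundary_radii(mask: np.ndarray, half: int, grid_step: float,
                         n: int = 360) -> np.ndarray:
    """Outer boundary radius of a centred binary mask along n ray directions."""
    th = np.deg2rad(np.arange(n) * 360.0 / n)
    nr = half
    rr = np.arange(nr) * grid_step
    ys = (rr[None, :] * np.cos(th)[:, None]) / grid_step + half
    xs = (rr[None, :] * np.sin(th)[:, None]) / grid_step + half
    vals = ndimage.map_coordinates(mask.astype(np.uint8),
                                   [ys.ravel(), xs.ravel()], order=0
                                   ).reshape(n, nr)
    out = np.zeros(n)
    for i in range(n):
        idx = np.nonzero(vals[i])[0]
        out[i] = rr[idx[-1]] if len(idx) else 0.0
    return out


# --------------------------------------------------------------------------- #
# Contact-point density maps
# --------------------------------------------------------------------------- #

def silverman_bandwidth(points_2d: np.ndarray) -> float:
    """Scalar Silverman rule for a bivariate KDE: sigma * n^(-1/6)."""
    n = len(points_2d)
    sigma = np.sqrt(0.5 * (points_2d[:, 0].var(ddof=1) +
                           points_2d[:, 1].var(ddof=1)))
    return float(max(sigma, 1e-6) * n ** (-1.0 / 6.0))


def density_map(points_2d: np.ndarray, bandwidth: float | None = None,
                grid_step: float = 0.05, pad: float | None = None
                ) -> CrossSectionDensityMap:
    """Bivariate normal KDE of untwisted cross-section points.

    ``f(x) = (1/n) sum_i K_H(x - x_i)`` with ``K_H`` the bivariate
    normal kernel and ``H = h^2 I``; ``h`` defaults to the Silverman
    rule on the pooled points.  The map is gridded at 0.05 nm (0.5 A).
    Exact kernel summation for small clouds; histogram + Gaussian
    filter (equivalent to discretized kernel summation) for large ones.
    """
    pts = np.asarray(points_2d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("points must be (n, 2)")
    pts = pts[:, :2]
    n = len(pts)
    if n < 10:
        raise ValueError("need at least 10 points for a density map")
    h = silverman_bandwidth(pts) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be > 0")
    if pad is None:
        pad = 4.0 * h
    x0, x1 = pts[:, 0].min() - pad, pts[:, 0].max() + pad
    z0, z1 = pts[:, 1].min() - pad, pts[:, 1].max() + pad
    xs = np.arange(x0, x1 + grid_step, grid_step)
    zs = np.arange(z0, z1 + grid_step, grid_step)
    if n * len(xs) * len(zs) <= 4e7:
        dx = xs[None, :] - pts[:, 0:1]
        dz = zs[None, :] - pts[:, 1:2]
        gx = np.exp(-0.5 * (dx / h) ** 2)
        gz = np.exp(-0.5 * (dz / h) ** 2)
        grid = (gz.T @ gx) / (n * 2 * np.pi * h * h)
    else:
        hist, _, _ = np.histogram2d(pts[:, 1], pts[:, 0], bins=[len(zs),
                                                                len(xs)],
                                    range=[[z0, zs[-1]], [x0, xs[-1]]])
        grid = ndimage.gaussian_filter(hist, h / grid_step, mode="constant")
        grid /= grid.sum() * grid_step ** 2
    return CrossSectionDensityMap(grid=grid,
                                  extent=(x0, xs[-1], z0, zs[-1]),
                                  bandwidth=h, n=n, step=grid_step)
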