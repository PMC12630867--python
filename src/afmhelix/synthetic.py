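"""Synthetic twisted-filament phantoms and rigid-body AFM scan simulation.

The ground truth here is a helical filament: a star-shaped cross-section
``r(theta)`` that rotates about the filament axis as one moves along it,
completing 360 degrees over one helical pitch.  An AFM image of such an
object is, under rigid-body contact, the morphological dilation of its
surface by the reflected tip.  This module builds phantoms, renders their
substrate-supported height maps, dilates them with a sphere-capped-cone
tip, adds Gaussian background noise, and samples the randomized
("null") fibril specifications used for match-significance testing.

Units: lengths in nm, angles in degrees unless noted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------- #
# Tip model
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class TipModel:
    """Sphere-capped conical AFM tip.

    Parameters
    ----------
    radius : float
        Apex sphere radius in nm.  The nominal scanning probe is 2 nm;
        5.5 nm is the average effective radius used for map comparison.
    cone_half_angle : float
        Half-angle of the supporting cone, degrees from the tip axis.
    tip_height : float
        Total tip height in nm; only limits the profile's validity range.
    """

    radius: float = 2.0
    cone_half_angle: float = 18.0
    tip_height: float = 2500.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("tip radius must be > 0")
        if not (0 < self.cone_half_angle < 90):
            raise ValueError("cone_half_angle must be in (0, 90) degrees")
        if self.tip_height < self.radius:
            raise ValueError("tip_height must be >= radius")

    def profile(self, rho: np.ndarray) -> np.ndarray:
        """Height of the tip surface above its apex at lateral distance rho.

        Spherical cap out to the sphere/cone tangency circle, then the
        tangent cone.  Monotone increasing in |rho|.
        """
        return tip_profile(np.asarray(rho, dtype=float), self.radius,
                           self.cone_half_angle)


def tip_profile(rho: np.ndarray, radius: float, cone_half_angle: float = 18.0
                ) -> np.ndarray:
    """Sphere-capped-cone height profile; ``radius == 0`` is the ideal tip."""
    rho = np.abs(np.asarray(rho, dtype=float))
    if radius == 0:
        # delta tip: zero at the apex, effectively infinite elsewhere
        out = np.where(rho == 0.0, 0.0, np.inf)
        return out
    alpha = np.deg2rad(cone_half_angle)
    rho_t = radius * np.cos(alpha)          # tangency circle
    z_t = radius * (1.0 - np.sin(alpha))
    sphere = radius - np.sqrt(np.clip(radius**2 - rho**2, 0.0, None))
    cone = z_t + (rho - rho_t) / np.tan(alpha)
    return np.where(rho <= rho_t, sphere, cone)


# --------------------------------------------------------------------------- #
# Cross-sections and phantoms
# --------------------------------------------------------------------------- #

_THETA_1DEG = np.arange(360.0)


def ellipse_cross_section(a: float, b: float, n: int = 360) -> np.ndarray:
    """Polar radii of an ellipse with semi-axes a (theta=90) and b (theta=0).

    theta is measured from the +z direction of the cross-section plane, so
    at theta = 0 the radius is b and at theta = 90 deg it is a.
    """
    th = np.deg2rad(np.arange(n) * 360.0 / n)
    return a * b / np.sqrt((b * np.sin(th)) ** 2 + (a * np.cos(th)) ** 2)


def lobed_cross_section(r_min: float, r_max: float, lobes: int,
                        n: int = 360) -> np.ndarray:
    """Smooth k-lobed star section: cosine interpolation r_min..r_max."""
    if not r_min < r_max:
        raise ValueError("r_min must be < r_max")
    th = np.deg2rad(np.arange(n) * 360.0 / n)
    return r_min + (r_max - r_min) * 0.5 * (1.0 + np.cos(lobes * th))


def protofilament_cross_section(rho: float, d: float, n_pf: int = 2,
                                n: int = 360) -> np.ndarray:
    """Cross-section of ``n_pf`` round protofilaments around the axis.

    The union of n_pf disks of radius rho centred at distance d from
    the helical axis (d < rho so the union is star-shaped about the
    axis) — the canonical lobed outline of multi-protofilament amyloid
    fibrils, distinct from the cosine-lobe family.
    """
    if not 0 <= d < rho:
        raise ValueError("need 0 <= d < rho for a star-shaped union")
    th = np.deg2rad(np.arange(n) * 360.0 / n)
    r = np.zeros(n)
    for k in range(max(1, n_pf)):
        phi = th - 2 * np.pi * k / max(1, n_pf)
        rk = d * np.cos(phi) + np.sqrt(rho ** 2 - (d * np.sin(phi)) ** 2)
        r = np.maximum(r, rk)
    return r


def _interp_cross_section(control: Sequence[tuple[float, float]],
                          n: int = 360) -> np.ndarray:
    """Periodic cubic interpolation of (theta_deg, r) control points."""
    from scipy.interpolate import CubicSpline

    pts = sorted((float(t) % 360.0, float(r)) for t, r in control)
    th = np.array([p[0] for p in pts])
    rr = np.array([p[1] for p in pts])
    th = np.append(th, th[0] + 360.0)
    rr = np.append(rr, rr[0])
    cs = CubicSpline(th, rr, bc_type="periodic")
    ang = np.arange(n) * 360.0 / n
    return cs(np.where(ang < th[0], ang + 360.0, ang))


@dataclass(frozen=True)
class PhantomParams:
    """Specification of a ground-truth twisted filament."""

    cross_section: object  # name, (name, args), control points, or array
    symmetry: int = 1
    pitch_360: float = 200.0          # nm per full 360 degree turn
    handedness: int = -1              # -1 left, +1 right
    length: float = 800.0             # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.symmetry not in (1, 2, 3, 4):
            raise ValueError("symmetry must be one of {1,2,3,4}")
        if self.pitch_360 <= 0:
            raise ValueError("pitch_360 must be > 0")
        if self.handedness not in (-1, 1):
            raise ValueError("handedness must be -1 or +1")
        if self.length <= 0:
            raise ValueError("length must be > 0")


@dataclass
class GroundTruthFilament:
    """Helical filament defined by a 1-degree sampled cross-section.

    ``radius(theta, z)`` returns the cross-section rotated by
    ``handedness * 360 * z / pitch_360``; the axis runs along z
    (rendered along the image x-axis by :func:`render_height_map`).
    """

    cross_section: np.ndarray       # radii at 0..359 deg, nm
    symmetry: int
    pitch_360: float
    handedness: int
    length: float

    def __post_init__(self) -> None:
        self.cross_section = np.asarray(self.cross_section, dtype=float)
        if self.cross_section.shape != (360,):
            raise ValueError("cross_section must be sampled on a 1 degree grid")
        if np.any(self.cross_section <= 0):
            raise ValueError("all cross-section radii must be > 0")

    @property
    def r_max(self) -> float:
        return float(self.cross_section.max())

    @property
    def r_min(self) -> float:
        return float(self.cross_section.min())

    def section_at(self, theta_deg: np.ndarray) -> np.ndarray:
        """Cross-section radii at arbitrary angles (linear interp, periodic)."""
        th = np.asarray(theta_deg, dtype=float) % 360.0
        return np.interp(th, np.arange(361.0),
                         np.append(self.cross_section, self.cross_section[0]))

    def radius(self, theta_deg, z) -> np.ndarray:
        """r(theta, z) of the twisted surface."""
        rot = self.handedness * 360.0 * np.asarray(z, dtype=float) / self.pitch_360
        return self.section_at(np.asarray(theta_deg, dtype=float) - rot)


def make_phantom(params: PhantomParams) -> GroundTruthFilament:
    """Build the ground-truth filament for a phantom specification.

    The cross-section may be given as a named template (``("circle", r)``,
    ``("ellipse", a, b)``, ``("lobed", r_min, r_max)`` — lobe count taken
    from ``symmetry``), a list of (theta, r) control points, or a
    360-sample radius array.  The section is symmetrized by averaging its
    rotations by multiples of 360/symmetry, so the stated symmetry is
    exact by construction.
    """
    cs = params.cross_section
    if isinstance(cs, tuple) and cs and isinstance(cs[0], str):
        name = cs[0]
        if name == "circle":
            r = np.full(360, float(cs[1]))
        elif name == "ellipse":
            r = ellipse_cross_section(float(cs[1]), float(cs[2]))
        elif name == "lobed":
            r = lobed_cross_section(float(cs[1]), float(cs[2]), params.symmetry)
        else:
            raise ValueError(f"unknown cross-section template {name!r}")
    elif isinstance(cs, np.ndarray) or (isinstance(cs, Sequence) and cs and
                                        np.isscalar(cs[0])):
        r = np.asarray(cs, dtype=float)
        if r.shape != (360,):
            raise ValueError("radius array cross_section must have 360 samples")
    else:
        r = _interp_cross_section(cs)

    if np.any(r <= 0):
        raise ValueError("cross-section radii must all be > 0")
    # enforce the stated rotational symmetry exactly
    if params.symmetry > 1:
        step = 360 // params.symmetry
        r = np.mean([np.roll(r, k * step) for k in range(params.symmetry)],
                    axis=0)
    return GroundTruthFilament(cross_section=r, symmetry=params.symmetry,
                               pitch_360=params.pitch_360,
                               handedness=params.handedness,
                               length=params.length)


# --------------------------------------------------------------------------- #
# Height-map rendering and scan simulation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class ScanGrid:
    """Raster geometry and background noise of a simulated scan."""

    pixel_size: float = 1.953125    # nm/px (4 um / 2048 px)
    nx: int = 256                   # columns (x, filament axis)
    ny: int = 64                    # rows (y, across the filament)
    noise_sd: float = 0.255         # nm, background Gaussian noise

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def render_height_map(filament: GroundTruthFilament, step: float,
                      nx: int, ny: int,
                      y_center: float | None = None,
                      axis_height: float | None = None,
                      centerline: Callable[[np.ndarray], np.ndarray] | None = None,
                      n_azimuth: int = 1440) -> np.ndarray:
    """Top-view height map of the filament resting on the substrate z=0.

    The filament axis runs along the x (column) direction at row-position
    ``y_center`` (grid units of ``step``), at height ``axis_height``
    (default: the maximal cross-sectional radius, so the filament touches
    the substrate at its widest azimuth).  ``centerline``, if given, maps
    x (nm) to a lateral offset y (nm), producing a bent filament for
    tracing tests; the cross-section is swept perpendicular to x (valid
    for bend radii much larger than the filament width).
    """
    if y_center is None:
        y_center = ny / 2.0
    if axis_height is None:
        axis_height = filament.r_max
    x_nm = np.arange(nx) * step
    inside = x_nm <= filament.length
    alpha = np.arange(n_azimuth) * 360.0 / n_azimuth   # azimuth from +z
    rot = filament.handedness * 360.0 * x_nm / filament.pitch_360
    offsets = np.zeros(nx) if centerline is None else np.asarray(
        centerline(x_nm), dtype=float)
    sin_a = np.sin(np.deg2rad(alpha))
    cos_a = np.cos(np.deg2rad(alpha))
    base = np.append(filament.cross_section, filament.cross_section[0])
    grid_th = np.arange(361.0)
    # scatter-max into 4x lateral sub-cells, then sample the sub-cell at
    # each cell centre: plain per-cell maxima would report the highest
    # point anywhere in the cell and bias sloped surfaces upward
    sub = 4
    fine = np.zeros((ny * sub, nx))
    for i in np.nonzero(inside)[0]:
        r = np.interp((alpha - rot[i]) % 360.0, grid_th, base)
        # azimuth runs from +z toward -y so that handedness +1 is a
        # physically right-handed screw about the +x axis
        y = (y_center * step + offsets[i] - r * sin_a) / (step / sub)
        z = axis_height + r * cos_a
        j = np.rint(y).astype(int)
        ok = (j >= 0) & (j < ny * sub) & (z > 0)
        np.maximum.at(fine[:, i], j[ok], z[ok])
    return fine[::sub, :]


@dataclass
class HeightImage:
    """Calibrated topographic AFM height raster (heights in nm)."""

    heights: np.ndarray
    pixel_size: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def background_sd(self) -> float:
        """Robust background noise estimate (1.4826 x MAD of all pixels).

        Valid while the background dominates the image area, which holds
        for sparse filament preparations.
        """
        if "background_sd" in self.metadata:
            return float(self.metadata["background_sd"])
        h = self.heights
        med = np.median(h)
        return float(1.4826 * np.median(np.abs(h - med)))


def dilate_height_map(surface: np.ndarray, step: float, tip: TipModel
                      ) -> np.ndarray:
    """Grayscale dilation of a height map by the reflected tip.

    ``out(x) = max_u [surface(u) - T(x - u)]`` with T the tip profile;
    the footprint is truncated where T exceeds the surface height range.
    """
    surface = np.asarray(surface, dtype=float)
    zrange = float(surface.max() - surface.min())
    if zrange <= 0:
        return surface.copy()
    # lateral reach where the tip profile reaches the height range
    rho = np.linspace(0, max(4 * tip.radius, 4 * zrange, step), 4096)
    prof = tip.profile(rho)
    reach = rho[min(np.searchsorted(prof, zrange), len(rho) - 1)]
    half = max(1, int(np.ceil(reach / step)))
    dy, dx = np.mgrid[-half:half + 1, -half:half + 1]
    dist = np.hypot(dx, dy) * step
    t = tip.profile(dist)
    footprint = t <= zrange
    structure = np.where(footprint, -t, 0.0)
    return ndimage.grey_dilation(surface, footprint=footprint,
                                 structure=structure, mode="nearest")


def erode_height_map(image: np.ndarray, step: float, tip: TipModel
                     ) -> np.ndarray:
    """Grayscale erosion by the reflected tip (certified surface estimate)."""
    image = np.asarray(image, dtype=float)
    zrange = float(image.max() - image.min())
    if zrange <= 0:
        return image.copy()
    rho = np.linspace(0, max(4 * tip.radius, 4 * zrange, step), 4096)
    prof = tip.profile(rho)
    reach = rho[min(np.searchsorted(prof, zrange), len(rho) - 1)]
    half = max(1, int(np.ceil(reach / step)))
    dy, dx = np.mgrid[-half:half + 1, -half:half + 1]
    dist = np.hypot(dx, dy) * step
    t = tip.profile(dist)
    footprint = t <= zrange
    structure = np.where(footprint, -t, 0.0)
    return ndimage.grey_erosion(image, footprint=footprint,
                                structure=structure, mode="nearest")


def simulate_scan(surface: GroundTruthFilament | np.ndarray,
                  tip: TipModel, grid: ScanGrid, seed: int | None = None,
                  oversample: int = 4,
                  centerline: Callable | None = None) -> HeightImage:
    """Simulate an AFM scan: tip dilation of the surface plus noise.

    ``surface`` is a phantom filament or a pre-rendered height map at the
    fine-grid resolution ``grid.pixel_size / oversample`` (shape
    ``(ny * oversample, nx * oversample)``).  Each output pixel is the
    maximum over the fine grid of ``z_surface - tip_profile(lateral
    distance)``, i.e. the morphological dilation of the surface by the
    reflected tip, evaluated at pixel centres; i.i.d. Gaussian noise of
    sd ``grid.noise_sd`` is added afterwards.
    """
    step = grid.pixel_size / oversample
    if isinstance(surface, GroundTruthFilament):
        if surface.length > grid.nx * grid.pixel_size:
            import warnings
            warnings.warn("filament longer than scan area; truncated")
        fine = render_height_map(surface, step, grid.nx * oversample,
                                 grid.ny * oversample, centerline=centerline)
    else:
        fine = np.asarray(surface, dtype=float)
        if fine.shape != (grid.ny * oversample, grid.nx * oversample):
            raise ValueError("height-map surface shape does not match grid")
    dil = dilate_height_map(fine, step, tip)
    img = dil[::oversample, ::oversample].copy()
    meta = {"tip_radius": tip.radius, "cone_half_angle": tip.cone_half_angle,
            "noise_sd": grid.noise_sd, "seed": seed,
            "oversample": oversample}
    if grid.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, grid.noise_sd, img.shape)
    else:
        meta["background_sd"] = 0.0
    return HeightImage(heights=img, pixel_size=grid.pixel_size, metadata=meta)


# --------------------------------------------------------------------------- #
# Randomized null fibrils
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class NullFibrilSpec:
    """Random-morphometrics fibril used for match significance testing."""

    r_max: float
    r_min: float
    symmetry: int
    pitch_360: float
    handedness: int

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be < r_max")

    def envelope(self, n: int = 360) -> np.ndarray:
        """Smooth star cross-section (cosine lobes) realizing the spec."""
        return lobed_cross_section(self.r_min, self.r_max, self.symmetry, n)

    @property
    def dpf(self) -> float:
        """Signed reciprocal of the cross-over repeat, 1/nm."""
        return self.handedness * self.symmetry / self.pitch_360


#: Default sampling bounds for the randomized null set.  Chosen to span the
#: morphometric ranges of in vitro amyloid populations: cross-over repeats
#: of 25-200 nm (10-40 crossovers/um and slower twists), radii covering
#: thin protofilaments to thick multi-protofilament fibrils, 1-3-fold
#: cross-sectional symmetry and either handedness.
DEFAULT_NULL_BOUNDS: dict[str, tuple[float, float]] = {
    "r_min": (0.75, 6.0),
    "r_max": (0.75, 6.0),
    "symmetry": (1, 3),
    "pitch_360": (50.0, 400.0),
}


def sample_null_fibrils(n: int, bounds: dict | None = None,
                        seed: int | None = None) -> list[NullFibrilSpec]:
    """Draw n random fibril specs, uniform within bounds, r_min < r_max.

    Pairs violating the hard rule r_min < r_max are rejection-resampled.
    Symmetry is an integer drawn uniformly on its inclusive range;
    handedness is a fair coin unless a ``"handedness"`` bound pins it.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    b = dict(DEFAULT_NULL_BOUNDS)
    if bounds:
        b.update(bounds)
    for key in ("r_min", "r_max", "symmetry", "pitch_360"):
        lo, hi = b[key]
        if lo > hi:
            raise ValueError(f"bound {key}: lo > hi")
    if b["r_min"][0] >= b["r_max"][1]:
        raise ValueError("r_min bound must extend below the r_max bound")
    rng = np.random.default_rng(seed)
    specs: list[NullFibrilSpec] = []
    while len(specs) < n:
        r_min = rng.uniform(*b["r_min"])
        r_max = rng.uniform(*b["r_max"])
        if not r_min < r_max:
            continue
        sym = int(rng.integers(int(b["symmetry"][0]),
                               int(b["symmetry"][1]) + 1))
        pitch = rng.uniform(*b["pitch_360"])
        if "handedness" in b:
            lo, hi = b["handedness"]
            hnd = int(lo) if lo == hi else int(rng.choice([-1, 1]))
        else:
            hnd = int(rng.choice([-1, 1]))
        specs.append(NullFibrilSpec(r_max=r_max, r_min=r_min, symmetry=sym,
                                    pitch_360=pitch, handedness=hnd))
    return specs
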