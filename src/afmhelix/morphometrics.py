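"""Per-filament morphometric parameters and polymorph distribution maps.

From a filament's helical envelope and height profile the following are
computed, all in nm-based units:

h      average height of the central ridge (mean of crossover peaks)
cod    mean cross-over distance (apparent repeat of the height profile)
hnd    twist handedness, -1 left / +1 right
dpf    directional periodic frequency, hnd / cod (1/nm)
csa    tip-accessible cross-sectional area by polar integration,
       csa = 1/2 * integral r(theta)^2 dtheta
csr    mean cross-sectional radius, csr = <r(theta)>
csjz   second polar moment of area about the helical axis,
       csjz = 1/4 * integral r(theta)^4 dtheta (equivalently the sum of
       the two in-plane second moments by the perpendicular-axis theorem)

Populations of records are visualized as 2D kernel-density "polymorph
maps" of (dpf, h) or (dpf, csa), the plane in which distinct polymorph
classes separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .cpr import HelicalEnvelope
from .trace import FilamentTrace, PeriodicityEstimate

__all__ = ["MorphometricRecord", "PolymorphMap", "morphometrics",
           "polymorph_map", "records_to_frame", "envelope_moments"]


@dataclass
class MorphometricRecord:
    filament_id: str
    h: float                 # nm
    cod: float               # nm
    hnd: int                 # -1 / +1
    dpf: float               # 1/nm, sign equals hnd
    csa: float               # nm^2
    csr: float               # nm
    csjz: float              # nm^4
    h_mean: float = np.nan   # full-profile mean height (alternative h)
    condition: str = ""

    def __post_init__(self) -> None:
        if self.h <= 0 or self.cod <= 0 or self.csa <= 0 or self.csr <= 0 \
                or self.csjz <= 0:
            raise ValueError("morphometric parameters must be positive")
        if np.sign(self.dpf) != self.hnd:
            raise ValueError("sign of dpf must equal hnd")


def envelope_moments(r: np.ndarray) -> tuple[float, float, float]:
    """(csa, csr, csjz) of a polar cross-section by trapezoidal quadrature."""
    r = np.asarray(r, dtype=float)
    n = len(r)
    rw = np.append(r, r[0])
    th = np.arange(n + 1) * 2 * np.pi / n
    csa = 0.5 * np.trapezoid(rw ** 2, th)
    csr = np.trapezoid(rw, th) / (2 * np.pi)
    csjz = 0.25 * np.trapezoid(rw ** 4, th)
    return float(csa), float(csr), float(csjz)


def morphometrics(envelope: HelicalEnvelope,
                  trace: FilamentTrace | None = None,
                  periodicity: PeriodicityEstimate | None = None,
                  condition: str = "") -> MorphometricRecord:
    """Morphometric record of one filament.

    ``h`` is the mean of the central-line profile values at the
    crossover peaks (sampling the maximal-height ridge avoids the
    twist-phase bias of a plain profile mean); the full-profile mean is
    also exported as ``h_mean``.  If no trace is available, h falls back
    to the envelope's apex height ``2 * max r`` (filament resting on the
    substrate).
    """
    csa, csr, csjz = envelope_moments(envelope.r)
    cod = envelope.periodicity
    hnd = envelope.handedness
    dpf = envelope.dpf
    h_mean = np.nan
    if trace is not None and trace.profile is not None:
        prof = np.asarray(trace.profile, dtype=float)
        h_mean = float(prof.mean())
        if periodicity is not None and periodicity.cod:
            dist = max(1, int(0.6 * periodicity.cod / trace.pixel_size))
        else:
            dist = max(1, int(0.6 * cod / trace.pixel_size))
        prom = max(2.0 * trace.background_sd, 1e-9)
        peaks, _ = signal.find_peaks(prof, prominence=prom, distance=dist)
        h = float(prof[peaks].mean()) if len(peaks) else float(prof.max())
    else:
        h = 2.0 * float(envelope.r.max())
    return MorphometricRecord(filament_id=envelope.filament_id or "",
                              h=h, cod=float(cod), hnd=hnd, dpf=float(dpf),
                              csa=csa, csr=csr, csjz=csjz, h_mean=h_mean,
                              condition=condition or envelope.condition)


def records_to_frame(records: Sequence[MorphometricRecord]) -> pd.DataFrame:
    """Tabulate records with the column layout of the exported CSV."""
    return pd.DataFrame([{
        "id": r.filament_id, "condition": r.condition, "h_nm": r.h,
        "cod_nm": r.cod, "hnd": r.hnd, "dpf_per_nm": r.dpf,
        "csa_nm2": r.csa, "csr_nm": r.csr, "csjz_nm4": r.csjz,
        "h_mean_nm": r.h_mean,
    } for r in records])


# --------------------------------------------------------------------------- #
# Polymorph distribution maps
# --------------------------------------------------------------------------- #

@dataclass
class PolymorphMap:
    density: np.ndarray                 # (nz, nx), integrates to 1
    x_grid: np.ndarray                  # dpf axis, 1/nm
    y_grid: np.ndarray                  # h or csa axis
    y_field: str
    bandwidths: tuple[float, float]
    contour_levels: dict[float, float] = field(default_factory=dict)
    references: pd.DataFrame | None = None

    def integral(self) -> float:
        dx = self.x_grid[1] - self.x_grid[0]
        dy = self.y_grid[1] - self.y_grid[0]
        return float(self.density.sum() * dx * dy)


def _silverman_1d(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25])) / 1.349
    s = min(sd, iqr) if iqr > 0 else sd
    return float(0.9 * s * n ** (-0.2))


def polymorph_map(records: Sequence[MorphometricRecord] | pd.DataFrame,
                  y_field: str = "h", grid_n: int = 200,
                  mass_levels: tuple[float, ...] = (0.25, 0.50, 0.75),
                  references: pd.DataFrame | None = None) -> PolymorphMap:
    """2D Gaussian KDE of (dpf, y) with per-axis Silverman bandwidths.

    ``y_field`` is "h" (average height) or "csa" (cross-sectional area).
    Contour levels are highest-density thresholds enclosing the given
    probability masses.  ``references`` (columns dpf, <y_field>, label)
    are carried through for overlay plotting, e.g. cryo-EM map entries.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        x = df["dpf_per_nm"].to_numpy(float)
        y = df[{"h": "h_nm", "csa": "csa_nm2"}[y_field]].to_numpy(float)
    else:
        if len(records) < 10:
            raise ValueError("need at least 10 records for a polymorph map")
        x = np.array([r.dpf for r in records])
        y = np.array([getattr(r, y_field) for r in records])
    hx = _silverman_1d(x)
    hy = _silverman_1d(y)
    if hx <= 0 or hy <= 0:
        raise ValueError("degenerate variance on an axis; jitter the data "
                         "or supply bandwidths")
    xg = np.linspace(x.min() - 3 * hx, x.max() + 3 * hx, grid_n)
    yg = np.linspace(y.min() - 3 * hy, y.max() + 3 * hy, grid_n)
    gx = np.exp(-0.5 * ((xg[None, :] - x[:, None]) / hx) ** 2)
    gy = np.exp(-0.5 * ((yg[None, :] - y[:, None]) / hy) ** 2)
    dens = (gy.T @ gx) / (len(x) * 2 * np.pi * hx * hy)
    dx = xg[1] - xg[0]
    dy = yg[1] - yg[0]
    # highest-density contour levels for the requested masses
    flat = np.sort(dens.ravel())[::-1]
    cum = np.cumsum(flat) * dx * dy
    levels = {}
    for m in mass_levels:
        idx = int(np.searchsorted(cum, m))
        levels[m] = float(flat[min(idx, len(flat) - 1)])
    return PolymorphMap(density=dens, x_grid=xg, y_grid=yg, y_field=y_field,
                        bandwidths=(hx, hy), contour_levels=levels,
                        references=references)


def plot_polymorph_map(pmap: PolymorphMap, ax=None, cmap: str = "viridis"):
    """Contour plot of a polymorph map (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    X, Y = np.meshgrid(pmap.x_grid, pmap.y_grid)
    levels = sorted(pmap.contour_levels.values())
    ax.contourf(X, Y, pmap.density, levels=[*levels, pmap.density.max()],
                cmap=cmap, alpha=0.8)
    ax.contour(X, Y, pmap.density, levels=levels, colors="k",
               linewidths=0.5)
    if pmap.references is not None:
        ycol = {"h": "h_nm", "csa": "csa_nm2"}[pmap.y_field]
        ax.scatter(pmap.references["dpf_per_nm"], pmap.references[ycol],
                   marker="o", s=25, facecolor="none", edgecolor="crimson")
    ax.set_xlabel("dpf (1/nm)")
    ax.set_ylabel({"h": "average height (nm)",
                   "csa": "cross-sectional area (nm$^2$)"}[pmap.y_field])
    return ax
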