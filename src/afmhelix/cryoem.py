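"""Cryo-EM reference maps: ingestion, helical extension, tip-accessible
envelopes, simulated AFM images, and population matching.

Cryo-EM density maps of amyloid filaments (MRC/CCP4 format, e.g. EMDB
depositions) describe a short axial segment of the filament core at the
author-recommended iso-contour.  To compare them with AFM-derived
envelopes the map is thresholded and denoised, its principal axis is
aligned to z, the segment is extended by the deposited helical screw
operation (twist per subunit, rise per subunit), and the tip-accessible
cross-section under a stated probe radius is derived — directly
comparable, via the structural distance d_xi, with the per-filament
envelopes reconstructed from AFM height images.

Map I/O goes through gemmi.  Maps themselves are never bundled: a
manifest CSV (accession, contour, twist, rise, symmetry, handedness)
identifies the references, and synthetic stand-in maps can be written
for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .cpr import (HelicalEnvelope, _mask_boundary_radii, accessible_envelope)
from .synthetic import HeightImage, ScanGrid, TipModel, dilate_height_map
from . import population

__all__ = [
    "ReferenceMap", "ReferenceEnvelope", "load_map", "write_map",
    "align_extend", "reference_envelope", "simulate_reference_image",
    "match", "null_match_rate", "render_null_envelopes",
]


@dataclass
class ReferenceMap:
    """A cryo-EM voxel map plus the deposition's helical metadata."""

    voxels: np.ndarray          # (nz, ny, nx) density
    voxel_size: float           # Angstrom
    contour_level: float
    twist: float                # degrees per subunit, signed
    rise: float                 # Angstrom per subunit
    accession: str = ""
    handedness: int | None = None    # override; None = sign of twist
    symmetry: int = 1

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.rise <= 0:
            raise ValueError("rise must be > 0")
        if not np.any(self.voxels >= self.contour_level):
            raise ValueError("empty iso-surface at the requested contour")

    @property
    def hnd(self) -> int:
        if self.handedness is not None:
            return self.handedness
        return -1 if self.twist < 0 else 1

    @property
    def periodicity_nm(self) -> float:
        """Crossover repeat in nm from (twist, rise, symmetry)."""
        return (360.0 / abs(self.twist)) * self.rise / 10.0 / self.symmetry

    @property
    def dpf(self) -> float:
        return self.hnd / self.periodicity_nm


@dataclass
class ReferenceEnvelope(HelicalEnvelope):
    """Tip-accessible radial profile of a reference map (HelicalEnvelope
    with the accession recorded as the filament id)."""

    accession: str = ""


# --------------------------------------------------------------------------- #
# Map I/O (gemmi)
# --------------------------------------------------------------------------- #

def load_map(path: str | Path, contour_level: float, twist: float,
             rise: float, accession: str = "", symmetry: int = 1,
             handedness: int | None = None,
             denoise_fraction: float = 0.05) -> ReferenceMap:
    """Read an MRC/CCP4 map and denoise it at the contour level.

    Denoising keeps only connected components of the thresholded mask
    with at least ``denoise_fraction`` of the largest component's voxel
    count (stray noise blobs in deposited maps are discarded).
    """
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    m.setup(float("nan"))
    arr = np.array(m.grid, copy=True)
    arr = np.nan_to_num(arr, nan=0.0)
    voxel = float(m.grid.unit_cell.a / m.grid.nu)
    mask = arr >= contour_level
    if not mask.any():
        raise ValueError(f"empty iso-surface at contour {contour_level}")
    labels, nlab = ndimage.label(mask)
    if nlab > 1:
        counts = np.bincount(labels.ravel())[1:]
        keep = np.nonzero(counts >= denoise_fraction * counts.max())[0] + 1
        arr = np.where(np.isin(labels, keep), arr, 0.0)
    return ReferenceMap(voxels=arr, voxel_size=voxel,
                        contour_level=contour_level, twist=twist, rise=rise,
                        accession=accession, symmetry=symmetry,
                        handedness=handedness)


def write_map(path: str | Path, voxels: np.ndarray, voxel_size: float
              ) -> None:
    """Write a density grid as an MRC/CCP4 map (mode 2 float)."""
    import gemmi

    grid = gemmi.FloatGrid(np.ascontiguousarray(voxels, dtype=np.float32))
    nz, ny, nx = voxels.shape
    grid.set_unit_cell(gemmi.UnitCell(voxel_size * nz, voxel_size * ny,
                                      voxel_size * nx, 90, 90, 90))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


# --------------------------------------------------------------------------- #
# Axis alignment and helical extension
# --------------------------------------------------------------------------- #

def align_extend(ref: ReferenceMap, target_length: float = 200.0
                 ) -> np.ndarray:
    """Axis-aligned, helically extended surface point cloud (nm).

    The iso-surface is triangulated (marching cubes), its principal
    inertia axis is rotated onto z, and the segment is replicated with
    the deposited screw operation (rotate by twist, translate by rise)
    until ``target_length`` nm is covered.  Returns (n, 3) vertices in
    nm, axis along z, centred laterally.
    """
    from skimage import measure

    verts, _faces, _, _ = measure.marching_cubes(ref.voxels,
                                                 level=ref.contour_level)
    verts = verts * ref.voxel_size / 10.0          # voxel idx -> nm
    verts = verts[:, ::-1]                          # (z,y,x) -> (x,y,z)
    ctr = verts.mean(axis=0)
    v = verts - ctr
    _u, _s, vt = np.linalg.svd(v, full_matrices=False)
    axis = vt[0]
    if axis[2] < 0:
        axis = -axis
    z = np.array([0.0, 0.0, 1.0])
    # helical depositions put the filament axis along box z; the principal
    # inertia axis only refines small tilts.  For stubby segments whose
    # lateral extent rivals the axial one, PCA is unreliable — keep z.
    if axis @ z < np.cos(np.deg2rad(30.0)):
        axis = z
    c = np.cross(axis, z)
    s = np.linalg.norm(c)
    if s < 1e-12:
        rot = np.eye(3)
    else:
        cmat = np.array([[0, -c[2], c[1]], [c[2], 0, -c[0]],
                         [-c[1], c[0], 0]])
        cos = float(axis @ z)
        rot = np.eye(3) + cmat + cmat @ cmat * ((1 - cos) / s ** 2)
    v = v @ rot.T

    rise_nm = ref.rise / 10.0
    seg_len = float(np.ptp(v[:, 2]))
    if ref.twist == 0:
        n_ops = int(np.ceil(target_length / max(seg_len, rise_nm)))
        pieces = [v + np.array([0, 0, k * seg_len])
                  for k in range(-n_ops, n_ops + 1)]
        out = np.vstack(pieces)
    else:
        n_ops = int(np.ceil((target_length / 2 + seg_len) / rise_nm))
        ks = np.arange(-n_ops, n_ops + 1)
        ang = np.deg2rad(ref.twist) * ks
        pieces = []
        for a, k in zip(ang, ks):
            ca, sa = np.cos(a), np.sin(a)
            rotz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
            pieces.append(v @ rotz.T + np.array([0, 0, k * rise_nm]))
        out = np.vstack(pieces)
    keep = np.abs(out[:, 2] - np.median(out[:, 2])) <= target_length / 2
    out = out[keep]
    out[:, :2] -= out[:, :2].mean(axis=0)
    return out


def reference_envelope(surface: np.ndarray | ReferenceMap,
                       tip: TipModel | float, twist: float | None = None,
                       rise: float | None = None, symmetry: int = 1,
                       handedness: int | None = None,
                       accession: str = "",
                       grid_step: float = 0.05) -> ReferenceEnvelope:
    """Tip-accessible 1-degree radial profile of a reference filament.

    The extended surface is "unwound" (each vertex rotated back by the
    twist accumulated at its axial position), projected into the
    cross-section plane, and closed with a disk of the tip radius —
    the rolling-tip accessibility of the mean cross-section.
    """
    if isinstance(surface, ReferenceMap):
        ref = surface
        twist, rise = ref.twist, ref.rise
        symmetry = ref.symmetry
        handedness = ref.hnd
        accession = accession or ref.accession
        surface = align_extend(ref)
    if twist is None or rise is None:
        raise ValueError("twist and rise are required with a bare surface")
    pts = np.asarray(surface, dtype=float)
    rise_nm = rise / 10.0
    ang = -np.deg2rad(twist) * pts[:, 2] / rise_nm
    ca, sa = np.cos(ang), np.sin(ang)
    x = pts[:, 0] * ca - pts[:, 1] * sa
    y = pts[:, 0] * sa + pts[:, 1] * ca
    sec = np.column_stack([x, y])

    # polar profile of the unwound section: max radius per 1 deg bin;
    # azimuth sense matches the AFM frame (up toward -lateral)
    th = np.rad2deg(np.arctan2(-sec[:, 0], sec[:, 1])) % 360.0
    r = np.hypot(sec[:, 0], sec[:, 1])
    bins = np.floor(th).astype(int) % 360
    prof = np.zeros(360)
    np.maximum.at(prof, bins, r)
    empty = prof == 0
    if empty.any():
        have = np.nonzero(~empty)[0]
        prof[empty] = np.interp(np.nonzero(empty)[0], have, prof[have],
                                period=360)
    tip_radius = tip.radius if isinstance(tip, TipModel) else float(tip)
    acc = accessible_envelope(prof, tip_radius, grid_step=grid_step)
    hnd = handedness if handedness is not None else (-1 if twist < 0 else 1)
    periodicity_nm = (360.0 / abs(twist)) * rise_nm / symmetry if twist \
        else np.inf
    return ReferenceEnvelope(r=np.clip(acc, 1e-3, None),
                             pitch_360=periodicity_nm * symmetry,
                             handedness=hnd, symmetry=symmetry,
                             filament_id=accession, accession=accession)


def simulate_reference_image(surface: np.ndarray, tip: TipModel,
                             grid: ScanGrid, seed: int | None = None,
                             oversample: int = 4) -> HeightImage:
    """Simulated AFM scan of an extended reference surface.

    The surface (axis along z) is laid on the substrate with its axis
    along the image x-direction at height max cross-sectional radius,
    rasterized by scatter-max, dilated by the tip and noised — the same
    contract as scanning a phantom filament.
    """
    pts = np.asarray(surface, dtype=float)
    r_lat = np.hypot(pts[:, 0], pts[:, 1])
    r_max = float(r_lat.max())
    step = grid.pixel_size / oversample
    nyf, nxf = grid.ny * oversample, grid.nx * oversample
    # axis z -> image x; x -> lateral y; y -> height z
    xi = pts[:, 2] - pts[:, 2].min()
    yi = pts[:, 0] + nyf * step / 2.0
    zi = pts[:, 1] + r_max
    fine = np.zeros((nyf, nxf))
    ix = np.rint(xi / step).astype(int)
    iy = np.rint(yi / step).astype(int)
    ok = (ix >= 0) & (ix < nxf) & (iy >= 0) & (iy < nyf) & (zi > 0)
    np.maximum.at(fine, (iy[ok], ix[ok]), zi[ok])
    dil = dilate_height_map(fine, step, tip)
    img = dil[::oversample, ::oversample].copy()
    meta = {"tip_radius": tip.radius, "noise_sd": grid.noise_sd,
            "seed": seed}
    if grid.noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, grid.noise_sd, img.shape)
    else:
        meta["background_sd"] = 0.0
    return HeightImage(heights=img, pixel_size=grid.pixel_size,
                       metadata=meta)


# --------------------------------------------------------------------------- #
# Matching and the randomized null
# --------------------------------------------------------------------------- #

def match(envelopes: Sequence[HelicalEnvelope],
          references: Sequence[HelicalEnvelope],
          sigma_cs: float, sigma_dpf: float,
          seed_threshold: float = 0.5, member_threshold: float = 1.0,
          within: "population.DistanceMatrix | None" = None
          ) -> tuple[pd.DataFrame, dict[str, list[int]]]:
    """Rank all population x reference comparisons and extract clusters.

    Returns the globally ranked table (ascending d_xi) and, when the
    within-population matrix is supplied, the per-reference match
    clusters under the seed/member distance rules.
    """
    d = population.cross_distances(envelopes, references, sigma_cs,
                                   sigma_dpf)
    rows = []
    for i, e in enumerate(envelopes):
        for j, ref in enumerate(references):
            rows.append((e.filament_id or str(i),
                         getattr(ref, "accession", None) or
                         ref.filament_id or str(j), d[i, j]))
    table = pd.DataFrame(rows, columns=["filament_id", "accession", "d_xi"])
    table = table.sort_values("d_xi", kind="stable").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    clusters: dict[str, list[int]] = {}
    if within is not None:
        for j, ref in enumerate(references):
            key = getattr(ref, "accession", None) or ref.filament_id or str(j)
            clusters[key] = population.extract_match_cluster(
                d[:, j], within, seed_threshold, member_threshold)
    return table, clusters


def render_null_envelopes(specs, tip_radius: float = 5.5,
                          grid_step: float = 0.1) -> list[HelicalEnvelope]:
    """Realize null fibril specs as tip-accessible helical envelopes."""
    out = []
    for k, s in enumerate(specs):
        r = accessible_envelope(s.envelope(), tip_radius,
                                grid_step=grid_step) if tip_radius > 0 \
            else s.envelope()
        out.append(HelicalEnvelope(r=np.clip(r, 1e-3, None),
                                   pitch_360=s.pitch_360,
                                   handedness=s.handedness,
                                   symmetry=s.symmetry,
                                   filament_id=f"null{k:05d}"))
    return out


def null_match_rate(null_envelopes: Sequence[HelicalEnvelope],
                    references: Sequence[HelicalEnvelope],
                    sigma_cs: float, sigma_dpf: float,
                    threshold: float = 0.5) -> tuple[float, int, int]:
    """Chance-match frequency of a randomized fibril set.

    Returns (fraction, count, total) of null x reference d_xi values
    below the match threshold.
    """
    if not null_envelopes or not references:
        raise ValueError("empty null or reference set")
    d = population.cross_distances(null_envelopes, references, sigma_cs,
                                   sigma_dpf)
    count = int((d < threshold).sum())
    total = d.size
    return count / total, count, total


# --------------------------------------------------------------------------- #
# Reference manifest
# --------------------------------------------------------------------------- #

#: EMDB depositions of Abeta(1-42) and Abeta(1-40) filament polymorphs used
#: as matching references, with the deposited helical parameters to be read
#: from each entry's metadata at load time.  Maps are supplied by the user;
#: this manifest only fixes the entry list and identities.
EMDB_ACCESSIONS: tuple[str, ...] = (
    "EMD-1649", "EMD-5052", "EMD-3132", "EMD-3851", "EMD-12592",
    "EMD-16434", "EMD-12593", "EMD-31428", "EMD-28740", "EMD-28741",
    "EMD-15770", "EMD-15771", "EMD-13800", "EMD-13809", "EMD-16022",
    "EMD-10204", "EMD-4864", "EMD-4866", "EMD-21501", "EMD-16023",
    "EMD-16027",
)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a reference manifest CSV.

    Columns: accession, map_path, contour_level, twist_deg, rise_A,
    symmetry, handedness (optional override, -1/+1/empty).
    """
    df = pd.read_csv(path)
    required = {"accession", "map_path", "contour_level", "twist_deg",
                "rise_A"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    return df


def envelopes_from_manifest(manifest: pd.DataFrame, tip: TipModel | float,
                            base_dir: str | Path = "."
                            ) -> list[ReferenceEnvelope]:
    """Load every manifest entry and derive its reference envelope."""
    out = []
    for _, row in manifest.iterrows():
        hnd = row.get("handedness")
        hnd = None if pd.isna(hnd) else int(hnd)
        ref = load_map(Path(base_dir) / row["map_path"],
                       contour_level=float(row["contour_level"]),
                       twist=float(row["twist_deg"]),
                       rise=float(row["rise_A"]),
                       accession=str(row["accession"]),
                       symmetry=int(row.get("symmetry", 1) or 1),
                       handedness=hnd)
        out.append(reference_envelope(ref, tip))
    return out
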