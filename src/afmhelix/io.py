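"""File I/O: height images (TIFF/ASCII), traces, envelopes, matrices.

All lengths are nm.  Height images travel as 32-bit float TIFF with a
JSON sidecar holding the calibration (pixel_size, noise, tip, seed);
tabular data as CSV with a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cpr import ContactPointCloud, HelicalEnvelope
from .population import DistanceMatrix
from .synthetic import HeightImage


def write_height_image(path: str | Path, image: HeightImage) -> None:
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, image.heights.astype(np.float32))
    side = {"pixel_size_nm": image.pixel_size}
    side.update({k: v for k, v in image.metadata.items()
                 if isinstance(v, (int, float, str, bool, type(None)))})
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def read_height_image(path: str | Path,
                      pixel_size: float | None = None) -> HeightImage:
    """Read a float TIFF (with optional JSON sidecar) or an ASCII matrix."""
    path = Path(path)
    meta: dict = {}
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        heights = tifffile.imread(path).astype(float)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
    else:
        heights = np.loadtxt(path)
    px = pixel_size if pixel_size is not None else meta.get(
        "pixel_size_nm", 1.953125)
    img = HeightImage(heights=heights, pixel_size=float(px), metadata=meta)
    return img


def write_cloud(path: str | Path, cloud: ContactPointCloud) -> None:
    df = pd.DataFrame({
        "x_nm": cloud.points[:, 0], "y_nm": cloud.points[:, 1],
        "z_nm": cloud.points[:, 2],
        "pixel_row": cloud.pixel_index[:, 0],
        "pixel_col": cloud.pixel_index[:, 1],
    })
    df.to_csv(path, index=False)


def write_envelope(path: str | Path, env: HelicalEnvelope) -> None:
    path = Path(path)
    pd.DataFrame({"theta_deg": np.arange(360), "r_nm": env.r}
                 ).to_csv(path, index=False)
    head = {"pitch_360_nm": env.pitch_360, "handedness": env.handedness,
            "symmetry": env.symmetry, "dpf_per_nm": env.dpf,
            "dpf_360_per_nm": env.dpf_360,
            "filament_id": env.filament_id, "condition": env.condition}
    path.with_suffix(".json").write_text(json.dumps(head, indent=1))


def read_envelope(path: str | Path) -> HelicalEnvelope:
    path = Path(path)
    df = pd.read_csv(path)
    head = json.loads(path.with_suffix(".json").read_text())
    return HelicalEnvelope(r=df["r_nm"].to_numpy(float),
                           pitch_360=head["pitch_360_nm"],
                           handedness=int(head["handedness"]),
                           symmetry=int(head["symmetry"]),
                           filament_id=head.get("filament_id", ""),
                           condition=head.get("condition", ""))


def write_distance_matrix(path: str | Path, dm: DistanceMatrix) -> None:
    """Square CSV; sigma constants in the header comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sigma_cs={dm.sigma_cs!r} sigma_dpf={dm.sigma_dpf!r}\n")
        pd.DataFrame(dm.square(), index=dm.ids, columns=dm.ids
                     ).to_csv(fh)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    from scipy.spatial.distance import squareform

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, index_col=0)
    parts = dict(p.split("=") for p in header.lstrip("# ").split())
    cond = squareform(df.to_numpy(float), checks=False)
    return DistanceMatrix(ids=[str(c) for c in df.columns], d_xi=cond,
                          d_cs_raw=np.full_like(cond, np.nan),
                          d_dpf_raw=np.full_like(cond, np.nan),
                          sigma_cs=float(parts["sigma_cs"]),
                          sigma_dpf=float(parts["sigma_dpf"]))
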