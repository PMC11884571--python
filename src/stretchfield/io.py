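"""Reading and writing stacks, fields, series and traces.

Image stacks travel as multi-page TIFF (or numbered PNG series) with a JSON
sidecar carrying calibration, per-frame time/state/mode and the generator
seed. Gridded fields and tidy per-cell tables are exported as CSV so they
interoperate with spreadsheet and plotting tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import imageio.v3 as iio

from .dic import DisplacementField
from .strainfield import StrainField, StrainSeries


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (frames, h, w) stack as multi-page TIFF (float32)."""
    tifffile.imwrite(
        str(path), np.asarray(stack, dtype=np.float32), photometric="minisblack"
    )


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF or a single image into a (frames, h, w) array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(str(path))
    else:
        arr = iio.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def write_png_series(directory: str | Path, stack: np.ndarray, prefix: str = "frame") -> list[Path]:
    """Write a stack as numbered 16-bit PNG files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(stack):
        arr = np.clip(frame, 0, None)
        scale = 65535.0 / max(float(arr.max()), 1e-12)
        p = directory / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, (arr * scale).astype(np.uint16))
        paths.append(p)
    return paths


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def displacement_to_frame(field: DisplacementField) -> pd.DataFrame:
    """Tidy export of a displacement field (invalid vectors flagged, kept)."""
    return pd.DataFrame(
        {
            "x_px": field.grid_x.ravel(),
            "y_px": field.grid_y.ravel(),
            "u_px": field.u.ravel(),
            "v_px": field.v.ravel(),
            "u_um": field.u_um.ravel(),
            "v_um": field.v_um.ravel(),
            "valid": field.valid.ravel(),
        }
    )


def strain_to_frame(strain: StrainField) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "x_um": strain.grid_x_um.ravel(),
            "y_um": strain.grid_y_um.ravel(),
            "Exx": strain.Exx.ravel(),
            "Eyy": strain.Eyy.ravel(),
            "Exy": strain.Exy.ravel(),
            "valid": strain.valid.ravel(),
        }
    )


def series_to_frame(series: StrainSeries) -> pd.DataFrame:
    data = {
        "t_s": series.times,
        "avg_Exx": series.avg_Exx,
        "avg_Eyy": series.avg_Eyy,
        "avg_Exy": series.avg_Exy,
    }
    if series.norm_Exx is not None:
        data["norm_Exx"] = series.norm_Exx
        data["norm_Eyy"] = series.norm_Eyy
    return pd.DataFrame(data)


def tracks_to_frame(tracks) -> pd.DataFrame:
    """One row per cell per frame."""
    rows = []
    for tr in tracks:
        for i, t in enumerate(tr.frames):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "frame": t,
                    "x_um": tr.centroids_um[i][0],
                    "y_um": tr.centroids_um[i][1],
                    "area_um2": tr.area_um2[i],
                    "perimeter_um": tr.perimeter_um[i],
                    "circularity": tr.circularity[i],
                    "shape_factor": tr.shape_factor[i],
                }
            )
    return pd.DataFrame(rows)


def trace_to_frame(trace) -> pd.DataFrame:
    return pd.DataFrame({"t_s": trace.times, "p_bar": trace.pressure})
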