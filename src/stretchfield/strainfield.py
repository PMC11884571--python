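"""Green–Lagrange strain fields and their temporal statistics.

The finite-deformation (Green–Lagrange) strain tensor is computed from the
displacement field U on the DIC grid as

    E = 1/2 (grad U + grad U^T + grad U^T grad U),

equivalently E = 1/2 (F^T F - I) with deformation gradient F = I + grad U.
Gradients are taken by central differences on the calibrated grid (one-sided
at the edges), so E is dimensionless regardless of the um/px calibration.
For small strains E_xx reduces to the engineering strain du/dx.

Spatial averages over a region of interest (with the border grid points
cropped to suppress DIC boundary artifacts), normalization of the resulting
time series to its t = 0 value, and long-term stability metrics follow the
standard reduction used for cyclic-stretch stability characterisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dic import DisplacementField

__all__ = [
    "StrainField",
    "StrainSeries",
    "green_lagrange",
    "crop_and_average",
    "normalize_series",
    "stability_metrics",
    "poisson_deflection",
]


@dataclass
class StrainField:
    """Symmetric in-plane strain components on the DIC grid (µm coords)."""

    Exx: np.ndarray
    Eyy: np.ndarray
    Exy: np.ndarray
    grid_x_um: np.ndarray
    grid_y_um: np.ndarray
    valid: np.ndarray
    crop_margin: int = 1


@dataclass
class StrainSeries:
    """Spatially averaged strain components over time, plus normalized form."""

    times: np.ndarray  # s
    avg_Exx: np.ndarray
    avg_Eyy: np.ndarray
    avg_Exy: np.ndarray
    norm_Exx: np.ndarray | None = None
    norm_Eyy: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("avg_Exx", "avg_Eyy", "avg_Exy"):
            if len(getattr(self, name)) != n:
                raise ValueError("series lengths inconsistent")


def green_lagrange(field: DisplacementField, crop_margin: int = 1) -> StrainField:
    """Green–Lagrange strain from a displacement field.

    ``crop_margin`` records how many border grid points downstream averaging
    should discard (DIC boundary artifacts); the full grid is returned so
    callers can inspect the borders. Grid points flagged invalid in the
    source field stay flagged here.
    """
    if int(field.valid.sum()) == 0:
        raise ValueError("displacement field has no valid vectors")
    if min(field.u.shape) < 3:
        raise ValueError("need at least a 3x3 grid to differentiate")
    x = field.grid_x_um[0, :]
    y = field.grid_y_um[:, 0]
    u = field.u_um
    v = field.v_um
    du_dy, du_dx = np.gradient(u, y, x)
    dv_dy, dv_dx = np.gradient(v, y, x)
    Exx = du_dx + 0.5 * (du_dx**2 + dv_dx**2)
    Eyy = dv_dy + 0.5 * (du_dy**2 + dv_dy**2)
    Exy = 0.5 * (du_dy + dv_dx) + 0.5 * (du_dx * du_dy + dv_dx * dv_dy)
    return StrainField(
        Exx=Exx,
        Eyy=Eyy,
        Exy=Exy,
        grid_x_um=field.grid_x_um,
        grid_y_um=field.grid_y_um,
        valid=field.valid.copy(),
        crop_margin=crop_margin,
    )


def crop_and_average(
    strain: StrainField,
    roi_um: tuple[float, float, float, float] | None = None,
    exclude: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """Spatial average of (Exx, Eyy, Exy) over a region of interest.

    ``roi_um`` is (x_min, x_max, y_min, y_max) in µm; ``None`` averages the
    whole grid. The ``crop_margin`` border ring, invalid grid points, NaNs
    and any points in the ``exclude`` mask (e.g. user-identified defocused
    regions) are left out of the mean.
    """
    m = strain.crop_margin
    sel = np.zeros(strain.Exx.shape, dtype=bool)
    inner = (slice(m, strain.Exx.shape[0] - m or None), slice(m, strain.Exx.shape[1] - m or None))
    sel[inner] = True
    sel &= strain.valid
    if exclude is not None:
        sel &= ~exclude
    if roi_um is not None:
        x_min, x_max, y_min, y_max = roi_um
        sel &= (
            (strain.grid_x_um >= x_min)
            & (strain.grid_x_um <= x_max)
            & (strain.grid_y_um >= y_min)
            & (strain.grid_y_um <= y_max)
        )
    sel &= np.isfinite(strain.Exx) & np.isfinite(strain.Eyy) & np.isfinite(strain.Exy)
    if not sel.any():
        raise ValueError("no strain data points remain after cropping")
    return (
        float(strain.Exx[sel].mean()),
        float(strain.Eyy[sel].mean()),
        float(strain.Exy[sel].mean()),
    )


def roi_point_count(strain: StrainField, roi_um) -> int:
    """Number of grid points contributing to a crop_and_average call."""
    m = strain.crop_margin
    sel = np.zeros(strain.Exx.shape, dtype=bool)
    sel[m : strain.Exx.shape[0] - m or None, m : strain.Exx.shape[1] - m or None] = True
    sel &= strain.valid
    x_min, x_max, y_min, y_max = roi_um
    sel &= (
        (strain.grid_x_um >= x_min)
        & (strain.grid_x_um <= x_max)
        & (strain.grid_y_um >= y_min)
        & (strain.grid_y_um <= y_max)
    )
    return int(sel.sum())


def normalize_series(series: StrainSeries) -> StrainSeries:
    """Divide each averaged component by its value at the first time point.

    The normalized series starts at exactly 1 by construction; a zero
    baseline is rejected (ratio undefined).
    """
    if series.avg_Exx[0] == 0 or series.avg_Eyy[0] == 0:
        raise ValueError("cannot normalize: zero strain baseline at t = 0")
    return StrainSeries(
        times=series.times,
        avg_Exx=series.avg_Exx,
        avg_Eyy=series.avg_Eyy,
        avg_Exy=series.avg_Exy,
        norm_Exx=np.asarray(series.avg_Exx) / series.avg_Exx[0],
        norm_Eyy=np.asarray(series.avg_Eyy) / series.avg_Eyy[0],
    )


def stability_metrics(series: StrainSeries) -> dict:
    """Long-term stability summary of a cyclic-stretch strain series.

    Returns the maximum relative fluctuation |norm(t) - 1| per normalized
    component and the maximum absolute change |avg(t) - avg(0)| over both
    normal components, matching the way strain stability is reported for
    multi-hour cyclic stretching.
    """
    if len(series.times) < 2:
        raise ValueError("need at least two time points")
    s = series if series.norm_Exx is not None else normalize_series(series)
    rel_xx = float(np.max(np.abs(np.asarray(s.norm_Exx) - 1.0)))
    rel_yy = float(np.max(np.abs(np.asarray(s.norm_Eyy) - 1.0)))
    abs_xx = np.max(np.abs(np.asarray(s.avg_Exx) - s.avg_Exx[0]))
    abs_yy = np.max(np.abs(np.asarray(s.avg_Eyy) - s.avg_Eyy[0]))
    return {
        "max_rel_fluct_Exx": rel_xx,
        "max_rel_fluct_Eyy": rel_yy,
        "max_abs_change": float(max(abs_xx, abs_yy)),
    }


def poisson_deflection(nu: float, eps: float, h: float) -> float:
    """Out-of-plane deflection of the top membrane surface by Poisson thinning.

    For a nearly incompressible elastomer membrane of thickness ``h`` (µm)
    under equibiaxial strain ``eps``, volume conservation thins the membrane
    and lowers the focal (top) surface by dz_P = 1/2 * nu * eps * h.

    >>> poisson_deflection(0.5, 0.10, 100.0)
    2.5
    """
    if not 0 <= nu <= 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5]")
    if h <= 0:
        raise ValueError("membrane thickness must be positive")
    return 0.5 * nu * eps * h
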