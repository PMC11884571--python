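"""Digital image correlation by multi-pass windowed FFT cross-correlation.

Displacement fields between relaxed/stretched image pairs are estimated with
the classic multi-pass window-deformation scheme: each pass correlates
interrogation windows between the reference image and the (current-estimate
warped) deformed image via normalized FFT cross-correlation, locates the
correlation peak to subpixel precision with a 3-point Gaussian fit, rejects
outliers with a normalized median test, and hands a refined grid plus a
deformed-image warp to the next pass. The default pass schedule is
320 px windows / 160 px step, then 160/80, then 80/40 (50% overlap
throughout), and speckle images are contrast-normalized beforehand with
CLAHE (64 px tiles).

Sign convention: the returned displacement U maps reference (relaxed)
coordinates to deformed (stretched) coordinates — a feature at x in the
reference sits at x + U(x) in the deformed image.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage import exposure

logger = logging.getLogger(__name__)

__all__ = [
    "ImagePair",
    "PassSchedule",
    "DisplacementField",
    "clahe",
    "pair_frames",
    "estimate_displacement",
    "displacement_to_velocity",
]

DEFAULT_PASSES = [(320, 160), (160, 80), (80, 40)]


@dataclass(frozen=True)
class ImagePair:
    """A relaxed (reference) / stretched (deformed) frame pair."""

    reference: np.ndarray
    deformed: np.ndarray
    calibration: float = 1.0  # um / px
    pair_time: float = 0.0  # s, time stamp assigned to the pair

    def __post_init__(self) -> None:
        if self.reference.shape != self.deformed.shape:
            raise ValueError("reference and deformed images must share a shape")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")


@dataclass(frozen=True)
class PassSchedule:
    """Ordered (window_size, step) pairs; windows strictly decreasing."""

    passes: tuple[tuple[int, int], ...] = tuple(DEFAULT_PASSES)

    def __post_init__(self) -> None:
        sizes = [w for w, _ in self.passes]
        if any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("window sizes must be strictly decreasing")
        if any(s > w for w, s in self.passes):
            raise ValueError("step must not exceed window size")
        if any(w < 4 for w, _ in self.passes):
            raise ValueError("window sizes must be >= 4 px")


@dataclass
class DisplacementField:
    """Gridded displacement vectors with a validity mask.

    ``u``/``v`` are in px; ``u_um``/``v_um`` in micrometres. ``valid`` flags
    vectors that passed the correlation-quality and median-residual tests;
    replaced outliers are marked invalid and are never exported silently.
    """

    grid_x: np.ndarray  # px, shape (ny, nx)
    grid_y: np.ndarray
    u: np.ndarray  # px
    v: np.ndarray
    valid: np.ndarray
    calibration: float = 1.0

    @property
    def u_um(self) -> np.ndarray:
        return self.u * self.calibration

    @property
    def v_um(self) -> np.ndarray:
        return self.v * self.calibration

    @property
    def grid_x_um(self) -> np.ndarray:
        return self.grid_x * self.calibration

    @property
    def grid_y_um(self) -> np.ndarray:
        return self.grid_y * self.calibration


def clahe(image: np.ndarray, window: int = 64) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization, tile size ``window`` px.

    Output spans the same intensity range as the input. A constant image is
    returned unchanged; a window exceeding the image collapses to single-tile
    equalization with a warning.
    """
    if window < 2:
        raise ValueError("window must be >= 2 px")
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi - lo == 0:
        return img.copy()
    if window > min(img.shape):
        warnings.warn("CLAHE window exceeds image size; using single-tile equalization")
        window = min(img.shape)
    norm = (img - lo) / (hi - lo)
    eq = exposure.equalize_adapthist(norm, kernel_size=window, clip_limit=0.01)
    return lo + eq * (hi - lo)


def pair_frames(states, frames=None, times=None):
    """Pair each stretched frame with the relaxed frame of its own period.

    Implements the "A+B, C+D" pairwise sequencing: the relaxed reference is
    updated at every period, so each stretched frame is referred to the most
    recent relaxed frame. A stretched frame with no relaxed frame before it
    in its period is skipped with a logged warning; extra stretched frames
    after the first in a period are likewise skipped.

    Returns a list of index pairs ``(i_relaxed, i_stretched)``; if ``frames``
    is given, a list of :class:`ImagePair` instead (with ``times`` supplying
    pair time stamps from the stretched frame).
    """
    idx_pairs: list[tuple[int, int]] = []
    last_relaxed: int | None = None
    consumed = True
    for i, s in enumerate(states):
        if s == "relaxed":
            last_relaxed = i
            consumed = False
        elif s == "stretched":
            if last_relaxed is None or consumed:
                logger.warning("stretched frame %d has no fresh relaxed reference; skipped", i)
                continue
            idx_pairs.append((last_relaxed, i))
            consumed = True
        else:
            raise ValueError(f"unknown actuation state {s!r}")
    if frames is None:
        return idx_pairs
    out = []
    for ir, is_ in idx_pairs:
        t = times[is_] if times is not None else float(is_)
        out.append(ImagePair(frames[ir], frames[is_], pair_time=t))
    return out


# ---------------------------------------------------------------------------
# correlation internals


def _window_grid(shape, window, step):
    """Centers of interrogation windows fully inside the image."""
    h, w = shape
    tls_y = np.arange(0, h - window + 1, step)
    tls_x = np.arange(0, w - window + 1, step)
    cy = tls_y + (window - 1) / 2.0
    cx = tls_x + (window - 1) / 2.0
    return tls_y, tls_x, cy, cx


def _extract_windows(img, tls_y, tls_x, window):
    view = sliding_window_view(img, (window, window))
    return view[np.ix_(tls_y, tls_x)]  # (ny, nx, window, window)


def _subpixel_1d(cm, cc, cp):
    """3-point Gaussian peak offset; parabolic fallback for non-positive lobes."""
    if cm > 0 and cc > 0 and cp > 0:
        lm, lc, lp = np.log(cm), np.log(cc), np.log(cp)
        denom = 2 * lc - lm - lp
        if denom != 0:
            return (lm - lp) / (2 * denom) * -1.0
    denom = 2 * cc - cm - cp
    if denom != 0:
        return (cp - cm) / (2 * denom)
    return 0.0


def _correlate_pass(ref_win, def_win, peak_ratio_min=1.3):
    """Per-window displacement from normalized FFT cross-correlation.

    Returns (du, dv, valid) arrays of shape (ny, nx). Windows are zero-meaned
    and correlated *linearly* (zero-padded FFT); the plane is divided by the
    triangular overlap factor and by the window energies, so peak values are
    unbiased correlation-coefficient estimates — circular correlation without
    the overlap correction drags broad peaks toward zero lag. The peak is
    searched within a quarter window of zero lag (the PIV one-quarter rule:
    at larger lags the windows barely overlap and the overlap normalization
    amplifies noise into spurious peaks).
    Validity requires an interior peak and a primary/secondary peak ratio
    above ``peak_ratio_min``.
    """
    ny, nx, win, _ = ref_win.shape
    a = ref_win - ref_win.mean(axis=(-2, -1), keepdims=True)
    b = def_win - def_win.mean(axis=(-2, -1), keepdims=True)
    denom = (
        np.sqrt((a**2).sum(axis=(-2, -1)) * (b**2).sum(axis=(-2, -1))) + 1e-12
    )
    n2 = 2 * win
    corr = np.fft.irfft2(
        np.conj(np.fft.rfft2(a, s=(n2, n2))) * np.fft.rfft2(b, s=(n2, n2)), s=(n2, n2)
    )
    corr = np.fft.fftshift(corr, axes=(-2, -1))
    lag = np.arange(n2) - n2 // 2
    overlap = np.maximum(win - np.abs(lag), 1) / win
    corr = corr / (overlap[:, None] * overlap[None, :])
    corr = corr / denom[..., None, None]
    center = n2 // 2
    r = max(win // 4, 3)  # one-quarter-rule search radius

    du = np.zeros((ny, nx))
    dv = np.zeros((ny, nx))
    valid = np.ones((ny, nx), dtype=bool)
    search = corr[..., center - r : center + r + 1, center - r : center + r + 1]
    flat = search.reshape(ny, nx, -1)
    peak_idx = flat.argmax(axis=-1)
    py, px = np.unravel_index(peak_idx, search.shape[-2:])
    py = py + center - r
    px = px + center - r
    for j in range(ny):
        for i in range(nx):
            cpl = corr[j, i]
            yj, xi = py[j, i], px[j, i]
            if abs(yj - center) >= r or abs(xi - center) >= r:
                valid[j, i] = False
                continue
            peak1 = cpl[yj, xi]
            masked = search[j, i].copy()
            sy, sx = yj - (center - r), xi - (center - r)
            masked[max(sy - 2, 0) : sy + 3, max(sx - 2, 0) : sx + 3] = -np.inf
            peak2 = masked.max()
            if peak1 <= 0 or (peak2 > 0 and peak1 / peak2 < peak_ratio_min):
                valid[j, i] = False
            du[j, i] = xi - center + _subpixel_1d(cpl[yj, xi - 1], peak1, cpl[yj, xi + 1])
            dv[j, i] = yj - center + _subpixel_1d(cpl[yj - 1, xi], peak1, cpl[yj + 1, xi])
    return du, dv, valid


def _median_filter_outliers(u, v, valid, threshold=2.0, eps=0.1):
    """Normalized median test; outliers invalidated and replaced by local median."""
    ny, nx = u.shape
    pad_u = np.pad(u, 1, mode="edge")
    pad_v = np.pad(v, 1, mode="edge")
    out_u, out_v = u.copy(), v.copy()
    flags = valid.copy()
    for j in range(ny):
        for i in range(nx):
            nb_u = np.delete(pad_u[j : j + 3, i : i + 3].ravel(), 4)
            nb_v = np.delete(pad_v[j : j + 3, i : i + 3].ravel(), 4)
            med_u, med_v = np.median(nb_u), np.median(nb_v)
            res_u = np.median(np.abs(nb_u - med_u))
            res_v = np.median(np.abs(nb_v - med_v))
            norm_u = abs(u[j, i] - med_u) / (res_u + eps)
            norm_v = abs(v[j, i] - med_v) / (res_v + eps)
            if max(norm_u, norm_v) > threshold or not valid[j, i]:
                out_u[j, i] = med_u
                out_v[j, i] = med_v
                if max(norm_u, norm_v) > threshold:
                    flags[j, i] = False
    return out_u, out_v, flags


def _interp_field(cy, cx, u, shape):
    """Linear interpolant of a gridded component with nearest-edge extrapolation."""
    interp = RegularGridInterpolator(
        (cy, cx), u, method="linear", bounds_error=False, fill_value=None
    )
    return interp


def _warp_deformed(deformed, cy, cx, u, v):
    """Backward-warp the deformed image by the current field estimate:
    warped(x) = deformed(x + U(x)). Correlating the reference against the
    result yields the residual displacement."""
    h, w = deformed.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    uu = _interp_field(cy, cx, u, deformed.shape)(pts).reshape(h, w)
    vv = _interp_field(cy, cx, v, deformed.shape)(pts).reshape(h, w)
    return ndimage.map_coordinates(
        deformed, [yy + vv, xx + uu], order=3, mode="nearest"
    )


def estimate_displacement(
    pair: ImagePair,
    schedule: PassSchedule = PassSchedule(),
    peak_ratio_min: float = 1.3,
    outlier_threshold: float = 2.0,
    final_iterations: int = 2,
) -> DisplacementField:
    """Multi-pass window-deformation displacement estimation.

    Each pass correlates interrogation windows (normalized FFT
    cross-correlation, 3-point Gaussian subpixel peak), invalidates outliers
    by the normalized median test and replaces them with the local median,
    then warps the deformed image by the interpolated field before the next,
    finer pass. The last pass is repeated ``final_iterations`` times in total
    (window deformation converges geometrically, and at strains of several
    percent a single pass at the final window size leaves a visible residual).
    The final field is reported on the last pass's grid. Boundary windows
    that would extend outside the image are dropped.
    """
    ref = np.asarray(pair.reference, dtype=float)
    de = np.asarray(pair.deformed, dtype=float)
    first_win = schedule.passes[0][0]
    if min(ref.shape) < first_win:
        raise ValueError(
            f"image smaller than first-pass window ({first_win} px); "
            "use a smaller schedule"
        )

    if final_iterations < 1:
        raise ValueError("final_iterations must be >= 1")
    passes = list(schedule.passes) + [schedule.passes[-1]] * (final_iterations - 1)
    cy_prev = cx_prev = None
    u_prev = v_prev = None
    valid = None
    for p, (win, step) in enumerate(passes):
        tls_y, tls_x, cy, cx = _window_grid(ref.shape, win, step)
        if len(cy) == 0 or len(cx) == 0:
            raise ValueError("no interrogation windows fit inside the image")
        if u_prev is None:
            u0 = np.zeros((len(cy), len(cx)))
            v0 = np.zeros((len(cy), len(cx)))
            de_work = de
        else:
            gy, gx = np.meshgrid(cy, cx, indexing="ij")
            pts = np.column_stack([gy.ravel(), gx.ravel()])
            u0 = _interp_field(cy_prev, cx_prev, u_prev, ref.shape)(pts).reshape(gy.shape)
            v0 = _interp_field(cy_prev, cx_prev, v_prev, ref.shape)(pts).reshape(gy.shape)
            de_work = _warp_deformed(de, cy_prev, cx_prev, u_prev, v_prev)

        ref_win = _extract_windows(ref, tls_y, tls_x, win)
        def_win = _extract_windows(de_work, tls_y, tls_x, win)
        du, dv, ok = _correlate_pass(ref_win, def_win, peak_ratio_min)
        u = u0 + du
        v = v0 + dv
        u, v, valid = _median_filter_outliers(u, v, ok, outlier_threshold)
        if p < len(passes) - 1:
            # smooth the predictor handed to the next pass; grid-scale noise
            # in the warp field otherwise stalls convergence ("mirror" keeps
            # linear ramps exact at the boundary)
            u = ndimage.gaussian_filter(u, 0.8, mode="mirror")
            v = ndimage.gaussian_filter(v, 0.8, mode="mirror")
        cy_prev, cx_prev, u_prev, v_prev = cy, cx, u, v

    gy, gx = np.meshgrid(cy_prev, cx_prev, indexing="ij")
    n_bad = int((~valid).sum())
    if n_bad:
        logger.info("DIC: %d of %d vectors flagged invalid", n_bad, valid.size)
    return DisplacementField(
        grid_x=gx, grid_y=gy, u=u_prev, v=v_prev, valid=valid, calibration=pair.calibration
    )


def displacement_to_velocity(field: DisplacementField, dt: float = 1.0) -> DisplacementField:
    """Divide displacements by ``dt`` (s). With the conventional pseudo-time
    step of 1 s the velocity field is numerically equal to the displacement
    field."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return DisplacementField(
        grid_x=field.grid_x,
        grid_y=field.grid_y,
        u=field.u / dt,
        v=field.v / dt,
        valid=field.valid,
        calibration=field.calibration,
    )
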