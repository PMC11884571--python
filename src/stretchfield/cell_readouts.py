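"""Cell-level readouts: kinematics, junctional fluorescence, morphometrics.

Three pipelines over monolayer time-lapses:

* mean cell speed by single-pass windowed correlation between consecutive
  unstretched frames (32 px windows, 16 px step) — stretch displacement
  never enters the motility estimate because only relaxed frames are
  compared;
* junctional-fluorescence quantification: rolling-ball background
  subtraction (100 px disk) followed by whole-FOV integration, normalized
  to the first frame;
* per-cell shape morphometrics from label masks: registration to a
  landmark, segment cropping, centroid tracking, area / perimeter /
  circularity / shape factor, and per-cell normalization to t = 0 with a
  population mean ± SEM.

Circularity is 4*pi*area/perimeter^2 (1 for a circle) and the shape factor
(shape index) is perimeter/sqrt(area), bounded below by 2*sqrt(pi) ~ 3.545;
epithelial monolayers near the solid-liquid transition sit close to the
critical value 3.81. Perimeters use the Crofton multi-direction estimator —
naive boundary-pixel counting overestimates perimeter and biases
circularity low.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import measure, registration, restoration, transform

from .dic import ImagePair, PassSchedule, estimate_displacement

logger = logging.getLogger(__name__)

__all__ = [
    "SpeedSeries",
    "FluorSeries",
    "CellTrack",
    "mean_cell_speed",
    "rolling_ball_subtract",
    "fluorescence_integral_series",
    "register_to_landmark",
    "crop_segment",
    "track_labels",
    "shape_metrics",
    "normalize_per_cell",
]

ISOPERIMETRIC_BOUND = 2 * math.sqrt(math.pi)  # minimum shape factor (circle)


@dataclass
class SpeedSeries:
    times: np.ndarray  # h
    mean_speed: np.ndarray  # um/h
    normalized: np.ndarray  # ratio to first interval


@dataclass
class FluorSeries:
    times: np.ndarray  # h
    integral: np.ndarray  # summed background-corrected intensity (a.u.)
    normalized: np.ndarray  # ratio to first frame


@dataclass
class CellTrack:
    """Per-cell time series of morphometric parameters (calibrated units)."""

    cell_id: int
    frames: list[int] = field(default_factory=list)
    centroids_um: list[tuple[float, float]] = field(default_factory=list)
    area_um2: list[float] = field(default_factory=list)
    perimeter_um: list[float] = field(default_factory=list)
    circularity: list[float] = field(default_factory=list)
    shape_factor: list[float] = field(default_factory=list)

    def normalized(self, key: str) -> np.ndarray:
        vals = np.asarray(getattr(self, key), dtype=float)
        return vals / vals[0]


def mean_cell_speed(
    stack: np.ndarray,
    dt_min: float = 2.0,
    calibration: float = 1.0,
    window: int = 32,
    step: int = 16,
) -> SpeedSeries:
    """Mean cell speed from consecutive unstretched phase-contrast frames.

    Single-pass windowed cross-correlation between each frame and the next
    yields a displacement field; the mean displacement magnitude over the
    FOV divided by the frame interval is the mean speed (µm/h). The series
    is normalized to its first interval.
    """
    if dt_min <= 0:
        raise ValueError("frame interval must be positive")
    if len(stack) < 2:
        raise ValueError("need at least two frames")
    schedule = PassSchedule(((window, step),))
    speeds = []
    for a, b in zip(stack[:-1], stack[1:]):
        # two correlation iterations: the second measures a near-zero residual,
        # cancelling the small-window bias on subpixel displacements
        f = estimate_displacement(
            ImagePair(a, b, calibration=calibration), schedule, final_iterations=2
        )
        mag = np.hypot(f.u_um, f.v_um)
        speeds.append(float(mag[f.valid].mean()) / dt_min * 60.0)
    speeds = np.asarray(speeds)
    times = np.arange(1, len(stack)) * dt_min / 60.0
    baseline = speeds[0] if speeds[0] > 0 else np.nan
    return SpeedSeries(times=times, mean_speed=speeds, normalized=speeds / baseline)


def rolling_ball_subtract(image: np.ndarray, radius: int = 100) -> np.ndarray:
    """Rolling-ball background subtraction; negative residuals clipped to 0.

    Structures much narrower than ``radius`` (junction ridges) survive with
    their peak heights nearly intact while smooth background is removed. A
    radius at least as large as the image collapses to global-minimum
    subtraction (with a warning).
    """
    if radius < 1:
        raise ValueError("radius must be >= 1 px")
    img = np.asarray(image, dtype=float)
    if radius >= min(img.shape):
        warnings.warn("rolling-ball radius exceeds image size; subtracting global minimum")
        return np.clip(img - img.min(), 0, None)
    # large radii: block-minimum shrink, roll the ball on the shrunk image,
    # then enlarge (the ImageJ strategy) — the block minimum drops narrow
    # bright structures so they never contaminate the background estimate
    shrink = min(8, max(1, int(radius / 12)))
    if shrink > 1:
        h, w = img.shape
        ph, pw = (-h) % shrink, (-w) % shrink
        padded = np.pad(img, ((0, ph), (0, pw)), mode="edge")
        small = measure.block_reduce(padded, (shrink, shrink), func=np.min)
        bg_small = restoration.rolling_ball(small, radius=radius / shrink)
        bg = transform.resize(bg_small, padded.shape, order=1, anti_aliasing=False)
        bg = bg[:h, :w]
    else:
        bg = restoration.rolling_ball(img, radius=radius)
    return np.clip(img - bg, 0, None)


def fluorescence_integral_series(
    stack: np.ndarray, radius: int = 100, times_h: np.ndarray | None = None
) -> FluorSeries:
    """Whole-FOV integral of background-subtracted fluorescence per frame,
    normalized to the first frame."""
    if len(stack) < 1:
        raise ValueError("empty stack")
    integrals = np.array(
        [float(rolling_ball_subtract(frame, radius).sum()) for frame in stack]
    )
    if times_h is None:
        times_h = np.arange(len(stack), dtype=float)
    return FluorSeries(
        times=np.asarray(times_h, dtype=float),
        integral=integrals,
        normalized=integrals / integrals[0],
    )


def register_to_landmark(
    stack: np.ndarray, landmark: tuple[int, int], patch: int = 64
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Integer-pixel translation registration of a stack to a landmark.

    The patch around ``landmark`` (x, y) in the first frame is located in
    every frame by cross-correlation; each frame is rolled by the integer
    offset so the landmark stays fixed. Returns the registered stack and the
    per-frame (dx, dy) offsets that were removed. Frames in which the
    landmark patch would leave the field of view are dropped with a warning.
    """
    x0, y0 = landmark
    h, w = stack[0].shape
    if not (0 <= x0 < w and 0 <= y0 < h):
        raise ValueError("landmark must lie inside the image")
    half = patch // 2
    sl = (slice(max(y0 - half, 0), y0 + half), slice(max(x0 - half, 0), x0 + half))
    ref_patch = np.asarray(stack[0][sl], dtype=float)
    registered, offsets = [], []
    for i, frame in enumerate(stack):
        shift, _, _ = registration.phase_cross_correlation(
            ref_patch, np.asarray(frame[sl], dtype=float), upsample_factor=1
        )
        dy, dx = int(round(shift[0])), int(round(shift[1]))
        if abs(dx) >= w or abs(dy) >= h or not (0 <= x0 - dx < w and 0 <= y0 - dy < h):
            logger.warning("landmark left the FOV in frame %d; frame dropped", i)
            continue
        registered.append(np.roll(np.roll(frame, dy, axis=0), dx, axis=1))
        offsets.append((dx, dy))
    return np.stack(registered), offsets


def crop_segment(
    stack: np.ndarray, size_um: float, center_px: tuple[int, int], calibration: float
) -> np.ndarray:
    """Centered crop of ``size_um`` (rounded to an even pixel count).

    165 µm at 0.55 µm/px gives a 300 px crop. Crops extending beyond the
    image bounds are rejected.
    """
    size_px = int(round(size_um / calibration / 2.0)) * 2
    x0, y0 = center_px
    half = size_px // 2
    frames = np.asarray(stack)
    if frames.ndim == 2:
        frames = frames[None]
    h, w = frames.shape[-2:]
    if y0 - half < 0 or x0 - half < 0 or y0 + half > h or x0 + half > w:
        raise ValueError("crop exceeds image bounds")
    out = frames[..., y0 - half : y0 + half, x0 - half : x0 + half]
    return out if np.asarray(stack).ndim == 3 else out[0]


def shape_metrics(area: float, perimeter: float) -> tuple[float, float]:
    """(circularity, shape_factor) from area and perimeter.

    circularity = 4*pi*A/P^2; shape_factor = P/sqrt(A). Both are scale
    invariant; a circle gives (1, 2*sqrt(pi)) and a unit square
    (pi/4, 4).
    """
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4 * math.pi * area / perimeter**2, perimeter / math.sqrt(area)


def _regions(mask: np.ndarray, calibration: float) -> dict[int, dict]:
    h, w = mask.shape
    out = {}
    for rp in measure.regionprops(mask):
        minr, minc, maxr, maxc = rp.bbox
        touches = minr == 0 or minc == 0 or maxr == h or maxc == w
        area = rp.area * calibration**2
        perim = rp.perimeter_crofton * calibration
        out[rp.label] = {
            "centroid_um": (rp.centroid[1] * calibration, rp.centroid[0] * calibration),
            "area_um2": float(area),
            "perimeter_um": float(perim),
            "touches_border": touches,
        }
    return out


def track_labels(
    masks: np.ndarray, calibration: float = 1.0, gate_um: float = 15.0
) -> list[CellTrack]:
    """Track labeled cells across frames by nearest centroid.

    A cell in frame t is matched to the candidate in frame t+1 whose centroid
    is nearest, within a maximum-displacement gate (default 15 µm/frame);
    distance ties are broken by the smallest relative area change. Tracks end
    when the cell touches the image border, loses its match, or the frame is
    empty. Morphometrics are computed in calibrated units; generator label
    identity is deliberately ignored so the tracker works on arbitrary masks.
    """
    masks = np.asarray(masks)
    if masks.ndim != 3:
        raise ValueError("expected a (frames, h, w) label stack")
    per_frame = [_regions(m, calibration) for m in masks]

    tracks: list[CellTrack] = []
    active: dict[int, tuple[CellTrack, dict]] = {}  # current label -> (track, props)
    next_id = 1
    for t, regions in enumerate(per_frame):
        new_active: dict[int, tuple[CellTrack, dict]] = {}
        unmatched = dict(regions)
        # extend existing tracks
        for label, (track, prev) in active.items():
            best = None
            for cand_label, props in unmatched.items():
                d = math.dist(prev["centroid_um"], props["centroid_um"])
                if d > gate_um:
                    continue
                da = abs(props["area_um2"] - prev["area_um2"]) / prev["area_um2"]
                key = (round(d, 6), da)
                if best is None or key < best[0]:
                    best = (key, cand_label, props)
            if best is None:
                continue
            _, cand_label, props = best
            if props["touches_border"]:
                continue  # track ends at the last fully contained frame
            del unmatched[cand_label]
            _append(track, t, props)
            new_active[cand_label] = (track, props)
        # open new tracks for unmatched, fully contained cells
        for cand_label, props in unmatched.items():
            if props["touches_border"]:
                continue
            track = CellTrack(cell_id=next_id)
            next_id += 1
            _append(track, t, props)
            tracks.append(track)
            new_active[cand_label] = (track, props)
        active = new_active
    return [tr for tr in tracks if tr.frames]


def _append(track: CellTrack, t: int, props: dict) -> None:
    circ, sf = shape_metrics(props["area_um2"], props["perimeter_um"])
    track.frames.append(t)
    track.centroids_um.append(props["centroid_um"])
    track.area_um2.append(props["area_um2"])
    track.perimeter_um.append(props["perimeter_um"])
    track.circularity.append(circ)
    track.shape_factor.append(sf)


def normalize_per_cell(
    tracks: list[CellTrack], n_frames: int, key: str = "area_um2"
) -> dict:
    """Per-cell series normalized to frame 0, with population mean ± SEM.

    Tracks that do not start at frame 0 or do not span all ``n_frames``
    frames are excluded with a warning. SEM is reported as 0 for a single
    cell.
    """
    series = []
    for tr in tracks:
        if tr.frames[0] != 0 or len(tr.frames) < n_frames:
            logger.warning("cell %d missing frame 0 or incomplete; excluded", tr.cell_id)
            continue
        series.append(tr.normalized(key)[:n_frames])
    if not series:
        raise ValueError("no track spans the requested frames from t = 0")
    arr = np.vstack(series)
    mean = arr.mean(axis=0)
    sem = (
        arr.std(axis=0, ddof=1) / math.sqrt(arr.shape[0])
        if arr.shape[0] > 1
        else np.zeros(n_frames)
    )
    return {"per_cell": arr, "mean": mean, "sem": sem, "n_cells": arr.shape[0]}
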