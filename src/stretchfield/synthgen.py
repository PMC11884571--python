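"""Synthetic fixtures with known ground truth.

Generates the three kinds of raw data the analysis stack consumes:

* speckle images of fluorescent tracer particles attached to an elastomeric
  membrane, warped by prescribed homogeneous deformations (for DIC),
* monolayer time-lapses (phase-like texture, junction fluorescence and
  ground-truth label masks) with controllable drift and junction-intensity
  ramp (for the cell readouts), and
* actuation schedules of alternating relaxed/stretched frames.

All generators are deterministic under a fixed seed, and every deformation
carries an analytic ground-truth displacement query so downstream estimates
can be scored against exact values.

Coordinate convention: pixel centers at integer coordinates, origin top-left,
x rightward (columns), y downward (rows). The deformation center defaults to
the image center and the displacement there is exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "SpeckleSpec",
    "DeformationSpec",
    "MonolayerSpec",
    "ActuationFrame",
    "ActuationSchedule",
    "generate_speckle",
    "apply_deformation",
    "generate_monolayer_sequence",
]


@dataclass(frozen=True)
class SpeckleSpec:
    """Speckle image of Gaussian tracer-particle spots.

    Emulates 0.2-0.5 um fluorescent tracer particles imaged at 10-20x:
    each particle renders as an isotropic Gaussian of width ``particle_sigma``
    pixels on a uniform background, with additive Gaussian read noise.
    """

    image_size: tuple[int, int] = (1000, 1000)  # (rows, cols)
    particle_density: float = 3e-3  # particles / px^2
    particle_sigma: float = 1.2  # px
    peak_intensity: float = 150.0  # gray levels
    background_level: float = 20.0
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image_size must be positive")
        if self.particle_density < 0:
            raise ValueError("particle_density must be >= 0")
        if self.particle_sigma <= 0:
            raise ValueError("particle_sigma must be > 0")


@dataclass(frozen=True)
class DeformationSpec:
    """Homogeneous in-plane deformation with analytic displacement.

    ``affine``: ground truth U(x) = (F - I)(x - center), F the 2x2
    deformation gradient (must have det F > 0).
    ``radial``: U(x) = eps_r (x - center), i.e. homogeneous equibiaxial
    strain — the idealisation of radial membrane stretch about its center.
    The displacement at ``center`` is exactly zero in both cases.
    """

    kind: Literal["affine", "radial"] = "affine"
    F: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    radial_strain: float = 0.0
    center: tuple[float, float] | None = None  # (x, y) px; None -> image center

    def gradient(self) -> np.ndarray:
        """Deformation gradient F as a 2x2 array (x-first convention)."""
        if self.kind == "radial":
            return (1.0 + self.radial_strain) * np.eye(2)
        F = np.asarray(self.F, dtype=float)
        if F.shape != (2, 2):
            raise ValueError("F must be 2x2")
        if np.linalg.det(F) <= 0:
            raise ValueError("deformation gradient must have positive determinant")
        return F

    def resolve_center(self, shape: tuple[int, int]) -> np.ndarray:
        if self.center is not None:
            return np.asarray(self.center, dtype=float)
        # pixel-center convention: center of an N-px axis is (N-1)/2
        return np.array([(shape[1] - 1) / 2.0, (shape[0] - 1) / 2.0])

    def displacement(self, x, y, shape: tuple[int, int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Exact analytic displacement (u, v) at points (x, y) in px."""
        if self.center is None and shape is None:
            raise ValueError("need image shape to resolve default center")
        c = self.resolve_center(shape if shape is not None else (0, 0))
        F = self.gradient()
        dx = np.asarray(x, dtype=float) - c[0]
        dy = np.asarray(y, dtype=float) - c[1]
        A = F - np.eye(2)
        return A[0, 0] * dx + A[0, 1] * dy, A[1, 0] * dx + A[1, 1] * dy


@dataclass(frozen=True)
class MonolayerSpec:
    """Confluent monolayer emulation: Voronoi cells, junction fluorescence.

    The label mask is a complete seeded tessellation (every pixel labeled);
    junction fluorescence lives within ``junction_halfwidth`` px of label
    boundaries and is scaled per frame by ``junction_amplitude_schedule``.
    ``drift_speed`` translates the whole monolayer rigidly, emulating
    collective migration at a controlled mean speed.
    """

    n_cells: int = 60
    image_size: tuple[int, int] = (512, 512)
    calibration: float = 0.55  # um / px
    drift_speed: float = 0.0  # um / h
    drift_direction: tuple[float, float] = (1.0, 0.0)  # unit-ish (x, y)
    junction_amplitude_schedule: Sequence[float] | None = None  # per frame
    junction_halfwidth: int = 2  # px
    junction_peak: float = 120.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")


@dataclass(frozen=True)
class ActuationFrame:
    time: float  # s
    state: Literal["relaxed", "stretched"]
    mode: Literal["radial", "uniaxial_x", "uniaxial_y", "biaxial"] = "radial"
    deformation: DeformationSpec = field(default_factory=DeformationSpec)


@dataclass
class ActuationSchedule:
    """Per-frame actuation record; times strictly increasing."""

    frames: list[ActuationFrame]

    def __post_init__(self) -> None:
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def states(self) -> list[str]:
        return [f.state for f in self.frames]

    @classmethod
    def alternating(
        cls,
        n_pairs: int,
        period: float = 20.0,
        deformation: DeformationSpec = DeformationSpec(),
        mode: str = "radial",
        settle_delay: float = 3.0,
        start: float = 0.0,
    ) -> "ActuationSchedule":
        """Relaxed/stretched alternation: one image pair per stretch period.

        Within each period the relaxed frame is taken ``settle_delay`` s after
        the period start and the stretched frame ``settle_delay`` s after the
        half-period transition, mirroring acquisition timed to the pneumatic
        stabilization phase.
        """
        frames = []
        for k in range(n_pairs):
            t0 = start + k * period
            frames.append(ActuationFrame(t0 + settle_delay, "relaxed", mode, deformation))
            frames.append(
                ActuationFrame(t0 + period / 2 + settle_delay, "stretched", mode, deformation)
            )
        return cls(frames)


def _render_particles(shape, xs, ys, sigma, peak):
    """Accumulate Gaussian spots at subpixel positions (vectorised stamps)."""
    img = np.zeros(shape, dtype=float)
    r = max(3, int(np.ceil(4 * sigma)))
    offs = np.arange(-r, r + 1)
    for x0, y0 in zip(xs, ys):
        ix, iy = int(round(x0)), int(round(y0))
        gx = np.exp(-((ix + offs - x0) ** 2) / (2 * sigma**2))
        gy = np.exp(-((iy + offs - y0) ** 2) / (2 * sigma**2))
        x_lo, x_hi = ix - r, ix + r + 1
        y_lo, y_hi = iy - r, iy + r + 1
        sx = slice(max(x_lo, 0), min(x_hi, shape[1]))
        sy = slice(max(y_lo, 0), min(y_hi, shape[0]))
        if sx.start >= sx.stop or sy.start >= sy.stop:
            continue
        stamp = peak * np.outer(gy[sy.start - y_lo : sy.stop - y_lo], gx[sx.start - x_lo : sx.stop - x_lo])
        img[sy, sx] += stamp
    return img


def sample_particles(spec: SpeckleSpec, rng: np.random.Generator | None = None):
    """Draw particle positions: count ~ Poisson(density * area), uniform over
    a margin-extended field so the in-image density stays uniform up to the
    border."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    margin = max(3, int(np.ceil(4 * spec.particle_sigma)))
    area = (h + 2 * margin) * (w + 2 * margin)
    n = rng.poisson(spec.particle_density * area)
    xs = rng.uniform(-margin, w + margin, size=n)
    ys = rng.uniform(-margin, h + margin, size=n)
    return xs, ys


def generate_speckle(spec: SpeckleSpec) -> np.ndarray:
    """Render a speckle image from a :class:`SpeckleSpec`.

    Particle positions come from :func:`sample_particles`; spots render as
    Gaussians of width ``particle_sigma``. Additive Gaussian noise is applied
    and values clipped to [0, 255] (8-bit range).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    xs, ys = sample_particles(spec, rng)
    img = spec.background_level + _render_particles((h, w), xs, ys, spec.particle_sigma, spec.peak_intensity)
    img += rng.normal(0.0, spec.noise_sd, size=(h, w))
    return np.clip(img, 0.0, 255.0)


def apply_deformation(
    image: np.ndarray,
    spec: DeformationSpec,
    order: int = 3,
    fill: float | None = None,
) -> tuple[np.ndarray, Callable]:
    """Warp ``image`` by the prescribed deformation; return the warped image
    and a ground-truth displacement query ``U(x, y) -> (u, v)``.

    The warp is computed by inverse mapping: the output pixel at material
    point x' samples the input at ``center + F^-1 (x' - center)``, so that a
    feature originally at x appears at ``center + F (x - center)``. Intensity
    interpolation is spline of the given ``order`` (bicubic by default);
    pass ``order=0`` for label masks so labels stay integral. Out-of-frame
    content is filled with ``fill`` (default: image minimum for smooth
    images, 0 for order-0 masks).
    """
    img = np.asarray(image)
    F = spec.gradient()
    Finv = np.linalg.inv(F)
    c = spec.resolve_center(img.shape)
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    dx = xx - c[0]
    dy = yy - c[1]
    src_x = c[0] + Finv[0, 0] * dx + Finv[0, 1] * dy
    src_y = c[1] + Finv[1, 0] * dx + Finv[1, 1] * dy
    if fill is None:
        fill = 0.0 if order == 0 else float(np.min(img))
    warped = ndimage.map_coordinates(
        img.astype(float), [src_y, src_x], order=order, mode="constant", cval=fill
    )
    if order == 0:
        warped = warped.astype(img.dtype)

    def ground_truth(x, y):
        return spec.displacement(x, y, shape=img.shape)

    return warped, ground_truth


def _tessellate(spec: MonolayerSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded Voronoi label mask, labels 1..n_cells, complete tessellation."""
    h, w = spec.image_size
    pts = np.column_stack(
        [rng.uniform(0, w, spec.n_cells), rng.uniform(0, h, spec.n_cells)]
    )
    yy, xx = np.mgrid[0:h, 0:w]
    tree = cKDTree(pts)
    _, idx = tree.query(np.column_stack([xx.ravel(), yy.ravel()]))
    return (idx + 1).reshape(h, w).astype(np.int32)


def _junction_image(mask: np.ndarray, halfwidth: int, peak: float) -> np.ndarray:
    """Fluorescence ridge along label boundaries, zero elsewhere."""
    boundary = np.zeros(mask.shape, dtype=bool)
    boundary[:, :-1] |= mask[:, :-1] != mask[:, 1:]
    boundary[:-1, :] |= mask[:-1, :] != mask[1:, :]
    dist = ndimage.distance_transform_edt(~boundary)
    ridge = np.where(dist <= halfwidth, peak * np.exp(-(dist**2) / max(halfwidth, 1) ** 2), 0.0)
    return ridge


def _phase_texture(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Phase-contrast-like texture: per-cell shading + smoothed granularity."""
    shades = rng.uniform(60, 140, size=int(mask.max()) + 1)
    img = shades[mask]
    grain = ndimage.gaussian_filter(rng.normal(0, 30, size=mask.shape), 1.5)
    edges = _junction_image(mask, 1, 60.0)
    return img + grain + edges


def _shift_image(img: np.ndarray, shift_xy: tuple[float, float], order: int, fill: float) -> np.ndarray:
    sx, sy = shift_xy
    if sx == 0.0 and sy == 0.0:
        return img.copy()  # spline resampling would leave float dust on exact zeros
    out = ndimage.shift(img.astype(float), (sy, sx), order=order, mode="constant", cval=fill)
    if order == 0:
        out = out.astype(img.dtype)
    return out


def generate_monolayer_sequence(
    spec: MonolayerSpec, schedule: ActuationSchedule
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (phase stack, fluorescence stack, label-mask stack).

    A single relaxed monolayer is tessellated once; each frame is that
    pattern rigidly translated by the accumulated drift (bicubic for
    intensities, nearest-neighbor for labels so integer identities persist),
    and — for stretched frames — additionally warped by the frame's
    deformation. Junction fluorescence is scaled per frame by the amplitude
    schedule; read noise is added to the phase channel only.
    """
    if len(schedule) < 1:
        raise ValueError("schedule must contain at least one frame")
    rng = np.random.default_rng(spec.seed)
    mask0 = _tessellate(spec, rng)
    phase0 = _phase_texture(mask0, rng)
    fluor0 = _junction_image(mask0, spec.junction_halfwidth, spec.junction_peak)

    amps = spec.junction_amplitude_schedule
    if amps is None:
        amps = [1.0] * len(schedule)
    if len(amps) != len(schedule):
        raise ValueError("junction_amplitude_schedule length must match schedule")

    t0 = schedule.frames[0].time
    drift_px_per_s = spec.drift_speed / 3600.0 / spec.calibration
    dvec = np.asarray(spec.drift_direction, dtype=float)
    dvec = dvec / (np.linalg.norm(dvec) or 1.0)

    phase, fluor, masks = [], [], []
    for frame, amp in zip(schedule.frames, amps):
        shift = tuple(drift_px_per_s * (frame.time - t0) * dvec)
        ph = _shift_image(phase0, shift, order=3, fill=float(phase0.mean()))
        fl = _shift_image(fluor0, shift, order=3, fill=0.0)
        mk = _shift_image(mask0, shift, order=0, fill=0)
        if frame.state == "stretched":
            ph, _ = apply_deformation(ph, frame.deformation, order=3, fill=float(phase0.mean()))
            fl, _ = apply_deformation(fl, frame.deformation, order=3, fill=0.0)
            mk, _ = apply_deformation(mk, frame.deformation, order=0, fill=0)
        ph = ph + rng.normal(0, spec.noise_sd, size=ph.shape)
        # fluorescence stays noise-free: junction signal is exactly zero away
        # from label boundaries, which downstream integrals rely on
        fl = amp * np.clip(fl, 0, None)
        phase.append(np.clip(ph, 0, 255))
        fluor.append(fl)
        masks.append(mk)
    return np.stack(phase), np.stack(fluor), np.stack(masks)


def write_sidecar(path: str | Path, schedule: ActuationSchedule, calibration: float, seed: int, extra: dict | None = None) -> None:
    """JSON sidecar: calibration, per-frame time/state/mode, seed, ground truth."""
    records = []
    for f in schedule.frames:
        d = f.deformation
        records.append(
            {
                "time_s": f.time,
                "state": f.state,
                "mode": f.mode,
                "deformation": {
                    "kind": d.kind,
                    "F": np.asarray(d.gradient()).tolist(),
                    "radial_strain": d.radial_strain,
                    "center": d.center,
                },
            }
        )
    payload = {"calibration_um_per_px": calibration, "seed": seed, "frames": records}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
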