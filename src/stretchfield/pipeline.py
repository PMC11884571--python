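"""End-to-end in-silico experiments with known ground truth.

Each experiment mirrors one of the platform-characterisation protocols:

* ``strain_vacuum_sweep`` — vacuum 5–50% in 5% steps, one relaxed/stretched
  speckle pair per level, DIC + strain, then a least-squares line through
  strain vs vacuum (the strain–vacuum characteristic is linear);
* ``long_term_stability`` — cyclic stretching imaged as periodic pairs,
  spatially averaged strain per pair, normalized to t = 0, with stability
  metrics (scaled down by default; the full 18 h / 10-min protocol is a
  config choice);
* ``mode_switch`` — radial / uniaxial-x / uniaxial-y / biaxial segments
  cycled repeatedly, with per-mode average strains;
* ``cell_readouts`` — monolayer time-lapse with drift and a junction
  amplitude ramp, feeding speed, fluorescence and morphometric pipelines.

All randomness is funnelled through one seed per run; re-running a config
reproduces its outputs bit for bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import stats

from . import synthgen
from .dic import ImagePair, PassSchedule, clahe, estimate_displacement
from .strainfield import StrainSeries, crop_and_average, green_lagrange, normalize_series, stability_metrics
from .cell_readouts import fluorescence_integral_series, mean_cell_speed, track_labels, normalize_per_cell
from .pneumatics import cycles_in_duration

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "run_strain_vacuum_sweep",
    "run_long_term_stability",
    "run_mode_switch",
    "run_cell_readouts",
    "run_experiment",
]

# default vacuum -> strain sensitivities (Lagrange strain per % vacuum),
# linear through the origin as observed for both stretch modes; the
# quantity that is linear in vacuum is the measured Green-Lagrange strain,
# so the generator converts the target E to a stretch via lambda = sqrt(1+2E)
RADIAL_SLOPE = 0.08 / 35.0  # 8% strain at 35% vacuum
UNIAXIAL_SLOPE_X = 0.12 / 35.0  # 12% axial strain at 35% vacuum
UNIAXIAL_SLOPE_LAT = -0.04 / 35.0  # lateral contraction, -4% at 35% vacuum


def _stretch(E: float) -> float:
    """Principal stretch from a Green-Lagrange strain target."""
    return float(np.sqrt(1.0 + 2.0 * E))


@dataclass
class ExperimentConfig:
    """Fully serializable run description; same config + seed => same outputs."""

    experiment: str = "strain_vacuum_sweep"
    image_size: tuple[int, int] = (768, 768)
    calibration: float = 0.5675  # um/px (40 px DIC step -> 22.7 um grid spacing)
    particle_density: float = 3e-3
    noise_sd: float = 3.0
    seed: int = 0
    passes: tuple[tuple[int, int], ...] = ((320, 160), (160, 80), (80, 40))
    clahe_window: int = 64
    crop_margin: int = 1
    period_s: float = 20.0
    # strain_vacuum_sweep
    mode: str = "radial"
    vacuum_levels: tuple[float, ...] = tuple(range(5, 55, 5))
    # long_term_stability
    n_pairs: int = 13
    pair_interval_s: float = 600.0
    start_strain: float = 0.08
    end_strain: float | None = None  # None -> constant
    full_duration_s: float = 64800.0
    # mode_switch
    segment_pairs: int = 2
    n_repeats: int = 1
    # cell_readouts
    n_cells: int = 60
    cell_image_size: tuple[int, int] = (512, 512)
    cell_calibration: float = 0.55
    drift_speed_um_h: float = 5.0
    fluor_ramp: float = 1.5
    n_frames: int = 10
    frame_dt_min: float = 2.0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "ExperimentConfig":
        raw = json.loads(text)
        for key in ("image_size", "cell_image_size", "vacuum_levels"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "passes" in raw:
            raw["passes"] = tuple(tuple(p) for p in raw["passes"])
        return cls(**raw)


def _deformation_for(mode: str, vacuum_percent: float) -> synthgen.DeformationSpec:
    """Map a stretch mode and vacuum level to a homogeneous deformation."""
    if mode == "radial":
        lam = _stretch(RADIAL_SLOPE * vacuum_percent)
        return synthgen.DeformationSpec(kind="radial", radial_strain=lam - 1.0)
    ax = _stretch(UNIAXIAL_SLOPE_X * vacuum_percent)
    lat = _stretch(UNIAXIAL_SLOPE_LAT * vacuum_percent)
    if mode == "uniaxial_x":
        F = ((ax, 0.0), (0.0, lat))
    elif mode == "uniaxial_y":
        F = ((lat, 0.0), (0.0, ax))
    elif mode == "biaxial":
        # anisotropic biaxial: full strain along x, half along y
        F = ((ax, 0.0), (0.0, _stretch(UNIAXIAL_SLOPE_X * vacuum_percent / 2)))
    else:
        raise ValueError(f"unknown stretch mode {mode!r}")
    return synthgen.DeformationSpec(kind="affine", F=F)


def _speckle_pair(
    cfg: ExperimentConfig,
    deformation: synthgen.DeformationSpec,
    rng: np.random.Generator,
    pair_time: float = 0.0,
) -> tuple[ImagePair, callable]:
    """One relaxed/stretched pair: fixed particle field, fresh read noise."""
    clean_spec = synthgen.SpeckleSpec(
        image_size=cfg.image_size,
        particle_density=cfg.particle_density,
        noise_sd=0.0,
        seed=cfg.seed,
    )
    clean = synthgen.generate_speckle(clean_spec)
    warped, gt = synthgen.apply_deformation(clean, deformation)
    ref = np.clip(clean + rng.normal(0, cfg.noise_sd, clean.shape), 0, 255)
    de = np.clip(warped + rng.normal(0, cfg.noise_sd, clean.shape), 0, 255)
    pair = ImagePair(
        clahe(ref, cfg.clahe_window),
        clahe(de, cfg.clahe_window),
        calibration=cfg.calibration,
        pair_time=pair_time,
    )
    return pair, gt


def _pair_to_avg_strain(cfg: ExperimentConfig, pair: ImagePair) -> tuple[float, float, float]:
    f = estimate_displacement(pair, PassSchedule(cfg.passes))
    strain = green_lagrange(f, crop_margin=cfg.crop_margin)
    return crop_and_average(strain)


def run_strain_vacuum_sweep(cfg: ExperimentConfig) -> dict:
    """Sweep vacuum levels, recover average strain per level, fit the line.

    Returns the per-level table, the least-squares slope / intercept / R²
    for Exx vs vacuum %, and the generator's true sensitivity for
    comparison.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    rows = []
    for v in cfg.vacuum_levels:
        deformation = _deformation_for(cfg.mode, v)
        pair, _ = _speckle_pair(cfg, deformation, rng)
        try:
            exx, eyy, exy = _pair_to_avg_strain(cfg, pair)
        except ValueError as err:
            logger.warning("DIC failed at vacuum %s%%: %s; level flagged", v, err)
            rows.append({"vacuum_percent": v, "avg_Exx": np.nan, "avg_Eyy": np.nan})
            continue
        F = deformation.gradient()
        Etrue = 0.5 * (F.T @ F - np.eye(2))
        rows.append(
            {
                "vacuum_percent": float(v),
                "avg_Exx": exx,
                "avg_Eyy": eyy,
                "avg_Exy": exy,
                "true_Exx": float(Etrue[0, 0]),
                "true_Eyy": float(Etrue[1, 1]),
            }
        )
    ok = [r for r in rows if np.isfinite(r["avg_Exx"])]
    vac = np.array([r["vacuum_percent"] for r in ok])
    exx = np.array([r["avg_Exx"] for r in ok])
    fit = stats.linregress(vac, exx)
    return {
        "table": rows,
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(fit.rvalue**2),
        "generator_slope": RADIAL_SLOPE if cfg.mode == "radial" else UNIAXIAL_SLOPE_X,
    }


def run_long_term_stability(cfg: ExperimentConfig) -> dict:
    """Cyclic-stretch stability: per-pair averaged strain, normalized series,
    stability metrics, and the full-protocol cycle count.

    The strain magnitude ramps linearly from ``start_strain`` to
    ``end_strain`` over the run (constant when ``end_strain`` is None),
    emulating slow drift of the actuation; per-period referencing means a
    drift-free run should give a flat normalized series up to DIC noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    end = cfg.end_strain if cfg.end_strain is not None else cfg.start_strain
    times, exx, eyy, exy = [], [], [], []
    for k in range(cfg.n_pairs):
        frac = k / max(cfg.n_pairs - 1, 1)
        eps = cfg.start_strain + (end - cfg.start_strain) * frac
        deformation = synthgen.DeformationSpec(kind="radial", radial_strain=eps)
        t = k * cfg.pair_interval_s
        pair, _ = _speckle_pair(cfg, deformation, rng, pair_time=t)
        a, b, c = _pair_to_avg_strain(cfg, pair)
        times.append(t)
        exx.append(a)
        eyy.append(b)
        exy.append(c)
    series = normalize_series(
        StrainSeries(
            times=np.asarray(times),
            avg_Exx=np.asarray(exx),
            avg_Eyy=np.asarray(eyy),
            avg_Exy=np.asarray(exy),
        )
    )
    metrics = stability_metrics(series)
    true_rel_change = abs(end - cfg.start_strain) / cfg.start_strain
    return {
        "series": series,
        "metrics": metrics,
        "true_relative_change": true_rel_change,
        "full_protocol_cycles": cycles_in_duration(cfg.full_duration_s, cfg.period_s),
    }


MODE_SEQUENCE = ("radial", "uniaxial_x", "uniaxial_y", "biaxial")


def run_mode_switch(cfg: ExperimentConfig, vacuum_percent: float = 35.0) -> dict:
    """Cycle through the four stretch modes; report per-mode average strains.

    The full protocol holds each mode for 400 s (20 cycles at 20 s) and
    repeats the four-mode pattern five times — 8000 s in total; the
    scaled-down default analyses ``segment_pairs`` pairs per segment and
    ``n_repeats`` repeats, with segment boundaries taken from the schedule.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    segments = []
    t = 0.0
    for _ in range(cfg.n_repeats):
        for mode in MODE_SEQUENCE:
            deformation = _deformation_for(mode, vacuum_percent)
            vals = []
            for _k in range(cfg.segment_pairs):
                pair, _ = _speckle_pair(cfg, deformation, rng, pair_time=t)
                vals.append(_pair_to_avg_strain(cfg, pair))
                t += cfg.period_s
            F = deformation.gradient()
            Etrue = 0.5 * (F.T @ F - np.eye(2))
            vals = np.asarray(vals)
            segments.append(
                {
                    "mode": mode,
                    "avg_Exx": float(vals[:, 0].mean()),
                    "avg_Eyy": float(vals[:, 1].mean()),
                    "true_Exx": float(Etrue[0, 0]),
                    "true_Eyy": float(Etrue[1, 1]),
                }
            )
    full_protocol_s = 4 * 400.0 * 5
    return {"segments": segments, "full_protocol_duration_s": full_protocol_s}


def run_cell_readouts(cfg: ExperimentConfig) -> dict:
    """Monolayer generation plus the three cell-level pipelines."""
    amps = np.linspace(1.0, cfg.fluor_ramp, cfg.n_frames)
    spec = synthgen.MonolayerSpec(
        n_cells=cfg.n_cells,
        image_size=cfg.cell_image_size,
        calibration=cfg.cell_calibration,
        drift_speed=cfg.drift_speed_um_h,
        junction_amplitude_schedule=list(amps),
        seed=cfg.seed,
    )
    frames = [
        synthgen.ActuationFrame(k * cfg.frame_dt_min * 60.0, "relaxed")
        for k in range(cfg.n_frames)
    ]
    schedule = synthgen.ActuationSchedule(frames)
    phase, fluor, masks = synthgen.generate_monolayer_sequence(spec, schedule)
    speed = mean_cell_speed(phase, dt_min=cfg.frame_dt_min, calibration=cfg.cell_calibration)
    fl = fluorescence_integral_series(fluor, times_h=np.array([f.time / 3600 for f in frames]))
    tracks = track_labels(masks, calibration=cfg.cell_calibration)
    morpho = normalize_per_cell(tracks, cfg.n_frames, key="area_um2")
    return {
        "speed": speed,
        "fluorescence": fl,
        "tracks": tracks,
        "morphometrics": morpho,
        "true_drift_speed": cfg.drift_speed_um_h,
        "true_fluor_ramp": cfg.fluor_ramp,
    }


_RUNNERS = {
    "strain_vacuum_sweep": run_strain_vacuum_sweep,
    "long_term_stability": run_long_term_stability,
    "mode_switch": run_mode_switch,
    "cell_readouts": run_cell_readouts,
}


def run_experiment(cfg: ExperimentConfig) -> dict:
    try:
        runner = _RUNNERS[cfg.experiment]
    except KeyError:
        raise ValueError(f"unknown experiment {cfg.experiment!r}") from None
    return runner(cfg)
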