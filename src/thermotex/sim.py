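"""Synthetic microwave-ablation case generator.

Emulates a bench ablation of ex vivo liver: a needle heats tissue for
``duration_s`` seconds while a B-mode probe films the plane containing the
needle and seven thermocouple points, and a thermometer logs those points at
``temp_rate_hz``.

Ground-truth temperature model
------------------------------
An elliptical Gaussian aligned with the needle axis, ramping exponentially
in time::

    T(u, v, t) = baseline + (peak - baseline) * r(t) * exp(-(u^2/sa(t)^2 + v^2/sb(t)^2))
    r(t)  = 1 - exp(-t / tau),          tau = 30 s
    sa(t) = sa0 + ga * sqrt(t)          (along the needle, mm)
    sb(t) = sb0 + gb * sqrt(t)          (across the needle, mm)

This is the simplest model producing a fusiform (needle-elongated)
coagulation zone with 75-100 C peaks; no bioheat PDE is solved.

B-mode renderer
---------------
Mean intensity is a saturating increasing function of local temperature;
multiplicative Rayleigh speckle rides on it with a relative scale that
falls linearly with normalized temperature, so hot tissue is brighter and
more uniform (higher minimum, lower variance/MAD — the texture drift the
regression exploits).  Heating-induced microbubbles are rendered as
Poisson shot noise smoothed to blob scale inside the hyperechoic ellipse:
the 54 C isotherm ellipse with axes scaled by s(t) = 1.16 + 0.5*exp(-t/45),
so the bright region strictly contains the isotherm early and shrinks
toward a residual margin, ending ~35% larger in area — the mismatch that
makes hyperechoic-area reading an imperfect proxy for the coagulation zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

TAU_RAMP_S = 30.0
LETHAL_ISOTHERM_C = 54.0
DEFAULT_PEAKS = {"P15": 85.0, "P20": 100.0}

# renderer constants (8-bit intensity units unless noted)
MEAN_BASE = 70.0  # mean echo intensity of 37 C tissue
MEAN_GAIN = 25.0  # intensity rise to peak temperature
MEAN_SAT_RATE = 2.0  # exponential saturation rate of the mean-intensity curve
SPECKLE_SIGMA0 = 0.45  # relative speckle scale at baseline temperature
SPECKLE_DAMP = 0.95  # fractional speckle reduction at peak temperature
BUBBLE_DENSITY_MM2 = 5.0  # final bubble density inside the hyperechoic ellipse
BUBBLE_SIGMA_MM = 1.0  # blob smoothing scale
BUBBLE_MEAN_INTENSITY = 30.0  # mean added brightness at full density
_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)


def _hyper_scale(time_s: float) -> float:
    return 1.16 + 0.5 * math.exp(-time_s / 45.0)


@dataclass(frozen=True)
class SimConfig:
    """Geometry, timing and acoustics of one synthetic ablation case.

    Coordinates are 0-based pixels, ``(x=column, y=row)``, origin top-left.
    The seven probe points must lie below the needle axis (larger y), as in
    the physical mold.
    """

    grid_height_px: int = 480
    grid_width_px: int = 640
    mm_per_px: float = 0.1
    duration_s: float = 180.0
    frame_rate_fps: float = 12.0
    temp_rate_hz: float = 2.0
    power_preset: str = "P15"
    peak_temp_C: float | None = None
    baseline_temp_C: float = 37.0
    preheat_s: float = 15.0
    probe_noise_C: float = 0.3
    probe_points: tuple[tuple[int, int], ...] | None = None
    needle_axis: tuple[tuple[float, float], tuple[float, float]] | None = None
    rng_seed: int = 0
    # field shape parameters (mm, mm/sqrt(s))
    sigma_along_mm0: float = 1.5
    sigma_along_growth: float = 0.55
    sigma_across_mm0: float = 1.0
    sigma_across_growth: float = 0.35
    speckle_sigma0: float = SPECKLE_SIGMA0

    def __post_init__(self) -> None:
        if self.grid_height_px <= 0 or self.grid_width_px <= 0 or self.mm_per_px <= 0:
            raise ValueError("grid dimensions and spacing must be positive")
        if self.power_preset not in DEFAULT_PEAKS:
            raise ValueError(f"unknown power preset {self.power_preset!r}")
        if self.peak_temp_C is None:
            object.__setattr__(self, "peak_temp_C", DEFAULT_PEAKS[self.power_preset])
        if self.baseline_temp_C >= self.peak_temp_C:
            raise ValueError("baseline temperature must be below peak")
        n_readings = self.duration_s * self.temp_rate_hz
        if abs(n_readings - round(n_readings)) > 1e-9:
            raise ValueError("duration_s * temp_rate_hz must be an integer")
        if self.needle_axis is None:
            object.__setattr__(self, "needle_axis", self._default_needle_axis())
        if self.probe_points is None:
            object.__setattr__(self, "probe_points", self._default_probe_points())
        if len(self.probe_points) != 7:
            raise ValueError("exactly 7 probe points are required")
        axis_y = max(self.needle_axis[0][1], self.needle_axis[1][1])
        for x, y in self.probe_points:
            if not (0 <= x < self.grid_width_px and 0 <= y < self.grid_height_px):
                raise ValueError(f"probe point ({x}, {y}) outside the grid")
            if y <= axis_y:
                raise ValueError(
                    f"probe point ({x}, {y}) is not below the needle axis"
                )

    # -- default geometry: needle horizontal, tip on the left; point 1 left of
    #    the tip, points 2..7 spread below the needle at increasing depth
    def _default_needle_axis(self):
        h, w = self.grid_height_px, self.grid_width_px
        y = 0.40 * h
        return ((0.85 * w, y), (0.35 * w, y))

    def _default_probe_points(self):
        cx, cy = self.ablation_center_px
        mm = [(-5.0, 2.0), (0.0, 2.0), (3.0, 3.5), (-2.0, 5.0),
              (1.0, 6.5), (4.0, 8.5), (2.0, 11.0)]
        pts = []
        for du, dv in mm:
            pts.append(
                (int(round(cx + du / self.mm_per_px)),
                 int(round(cy + dv / self.mm_per_px)))
            )
        return tuple(pts)

    @property
    def ablation_center_px(self) -> tuple[float, float]:
        """Radiation centre: on the axis, slightly behind the tip."""
        (x0, y0), (x1, y1) = self.needle_axis  # entry -> tip
        return (x1 + 0.15 * (x0 - x1), y1 + 0.15 * (y0 - y1))

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_s * self.frame_rate_fps))

    @property
    def amplitude_C(self) -> float:
        return self.peak_temp_C - self.baseline_temp_C

    def sigmas_mm(self, time_s: float) -> tuple[float, float]:
        rt = math.sqrt(max(time_s, 0.0))
        return (
            self.sigma_along_mm0 + self.sigma_along_growth * rt,
            self.sigma_across_mm0 + self.sigma_across_growth * rt,
        )

    def ramp(self, time_s: float) -> float:
        return 1.0 - math.exp(-time_s / TAU_RAMP_S)

    @property
    def cold_speckle_variance(self) -> float:
        """Intensity variance of baseline-temperature speckle (pre-clipping)."""
        return (MEAN_BASE * self.speckle_sigma0) ** 2 * (4.0 - math.pi) / math.pi


@dataclass(frozen=True)
class TemperatureField:
    """Ground-truth tissue temperature (degrees C) at one instant."""

    time_s: float
    values: np.ndarray


def _axis_coords(cfg: SimConfig, x: np.ndarray, y: np.ndarray):
    """Along/across-needle coordinates (mm) of pixel positions."""
    (x0, y0), (x1, y1) = cfg.needle_axis
    dx, dy = x0 - x1, y0 - y1
    norm = math.hypot(dx, dy)
    ex, ey = dx / norm, dy / norm
    cx, cy = cfg.ablation_center_px
    u = ((x - cx) * ex + (y - cy) * ey) * cfg.mm_per_px
    v = (-(x - cx) * ey + (y - cy) * ex) * cfg.mm_per_px
    return u, v


def _elliptic_rho(cfg: SimConfig, time_s: float, x: np.ndarray, y: np.ndarray):
    sa, sb = cfg.sigmas_mm(time_s)
    u, v = _axis_coords(cfg, x, y)
    return (u / sa) ** 2 + (v / sb) ** 2


_UV_CACHE: dict[SimConfig, tuple[np.ndarray, np.ndarray]] = {}


def _grid_uv(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Along/across-needle mm coordinates of every grid pixel (cached: the
    geometry does not depend on time)."""
    if cfg not in _UV_CACHE:
        y, x = np.mgrid[0 : cfg.grid_height_px, 0 : cfg.grid_width_px]
        _UV_CACHE[cfg] = _axis_coords(cfg, x.astype(np.float64), y.astype(np.float64))
        if len(_UV_CACHE) > 32:
            _UV_CACHE.pop(next(iter(_UV_CACHE)))
    return _UV_CACHE[cfg]


def _grid_rho(cfg: SimConfig, time_s: float) -> np.ndarray:
    u, v = _grid_uv(cfg)
    sa, sb = cfg.sigmas_mm(time_s)
    return (u / sa) ** 2 + (v / sb) ** 2


def field_values_at(cfg: SimConfig, time_s: float, points) -> np.ndarray:
    """Closed-form field temperature at arbitrary (x, y) pixel positions."""
    pts = np.asarray(points, dtype=np.float64)
    rho = _elliptic_rho(cfg, time_s, pts[..., 0], pts[..., 1])
    return cfg.baseline_temp_C + cfg.amplitude_C * cfg.ramp(time_s) * np.exp(-rho)


def simulate_field(cfg: SimConfig, time_s: float) -> TemperatureField:
    """Ground-truth temperature field over the full grid at ``time_s``."""
    if not 0.0 <= time_s <= cfg.duration_s:
        raise ValueError(f"time {time_s} outside [0, {cfg.duration_s}]")
    rho = _grid_rho(cfg, time_s)
    values = cfg.baseline_temp_C + cfg.amplitude_C * cfg.ramp(time_s) * np.exp(-rho)
    return TemperatureField(time_s=time_s, values=values)


def isotherm_rho(cfg: SimConfig, time_s: float, threshold_C: float) -> float | None:
    """Elliptic-radius bound of the ``threshold_C`` isotherm, or None if the
    field has not yet reached the threshold anywhere."""
    excess = cfg.amplitude_C * cfg.ramp(time_s)
    if excess <= threshold_C - cfg.baseline_temp_C:
        return None
    return math.log(excess / (threshold_C - cfg.baseline_temp_C))


def hyperechoic_mask(cfg: SimConfig, time_s: float) -> np.ndarray:
    """Boolean mask of the rendered hyperechoic (microbubble) ellipse."""
    r54 = isotherm_rho(cfg, time_s, LETHAL_ISOTHERM_C)
    if r54 is None:
        return np.zeros((cfg.grid_height_px, cfg.grid_width_px), dtype=bool)
    return _grid_rho(cfg, time_s) <= r54 * _hyper_scale(time_s) ** 2


def hyperechoic_diameters_mm(cfg: SimConfig, time_s: float) -> tuple[float, float]:
    """(major diameter a, half minor diameter b) of the hyperechoic ellipse,
    in mm — the quantities a sonographer reads off the final frame."""
    r54 = isotherm_rho(cfg, time_s, LETHAL_ISOTHERM_C)
    if r54 is None:
        return (0.0, 0.0)
    sa, sb = cfg.sigmas_mm(time_s)
    s = _hyper_scale(time_s)
    semi_major = sa * math.sqrt(r54) * s
    semi_minor = sb * math.sqrt(r54) * s
    return (2.0 * semi_major, semi_minor)


def render_frame(
    field: TemperatureField, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Render one 8-bit B-mode frame from a temperature field.

    With ``cfg.speckle_sigma0 == 0`` the output is the deterministic
    mean-intensity map (speckle and bubbles off) — the noise-free limit.
    """
    t_norm = np.clip(
        (field.values - cfg.baseline_temp_C) / cfg.amplitude_C, 0.0, 1.0
    )
    sat = (1.0 - np.exp(-MEAN_SAT_RATE * t_norm)) / (1.0 - math.exp(-MEAN_SAT_RATE))
    mean = MEAN_BASE + MEAN_GAIN * sat
    if cfg.speckle_sigma0 == 0:
        return np.clip(np.rint(mean), 0, 255).astype(np.uint8)

    sigma_rel = cfg.speckle_sigma0 * (1.0 - SPECKLE_DAMP * t_norm)
    speckle = rng.rayleigh(scale=1.0, size=mean.shape) / _RAYLEIGH_MEAN - 1.0
    img = mean * (1.0 + sigma_rel * speckle)

    mask = hyperechoic_mask(cfg, field.time_s)
    if mask.any():
        density_px = (
            BUBBLE_DENSITY_MM2
            * cfg.mm_per_px**2
            * (field.time_s / cfg.duration_s)
        )
        amp = BUBBLE_MEAN_INTENSITY / (BUBBLE_DENSITY_MM2 * cfg.mm_per_px**2)
        sigma_px = BUBBLE_SIGMA_MM / cfg.mm_per_px
        # the shot-noise field is local: only work inside the mask's
        # bounding box plus the blob support
        pad = int(np.ceil(4 * sigma_px))
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        y0, y1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, mask.shape[0])
        x0, x1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, mask.shape[1])
        sub = mask[y0:y1, x0:x1]
        counts = rng.poisson(lam=density_px, size=sub.shape) * sub
        img[y0:y1, x0:x1] += ndimage.gaussian_filter(
            counts.astype(np.float64) * amp, sigma=sigma_px
        )
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class SyntheticCase:
    """One simulated ablation: frames, probe log, and ground truth."""

    cfg: SimConfig
    case_id: str
    frames: np.ndarray  # (n_frames, H, W) uint8, ablation clock
    frame_times_s: np.ndarray  # (n_frames,)
    probe_times_s: np.ndarray  # thermometer clock, includes preheat
    probe_values_C: np.ndarray  # (7, n_readings)
    final_field: TemperatureField
    truth_isotherm_area_mm2: float
    truth_hyperechoic: tuple[float, float]  # (a, b) mm

    def field_at(self, time_s: float) -> TemperatureField:
        """Recompute the (deterministic) ground-truth field at any time."""
        return simulate_field(self.cfg, time_s)


def sample_probes(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Thermocouple log: 7 channels sampled at ``temp_rate_hz``.

    The thermometer starts ``preheat_s`` before the ablation; pre-ablation
    readings sit at baseline.  Returns ``(times_s, values_C)`` with times on
    the thermometer clock and ``values_C`` of shape (7, n_readings).
    """
    pts = np.asarray(cfg.probe_points, dtype=np.float64)
    n = int(round((cfg.preheat_s + cfg.duration_s) * cfg.temp_rate_hz))
    times = np.arange(n) / cfg.temp_rate_hz
    values = np.empty((7, n))
    for j, t in enumerate(times):
        values[:, j] = field_values_at(cfg, max(t - cfg.preheat_s, 0.0), pts)
    if rng is not None and cfg.probe_noise_C > 0:
        values = values + rng.normal(0.0, cfg.probe_noise_C, size=values.shape)
    return times, values


def generate_case(
    cfg: SimConfig, case_id: str = "case", out_dir=None
) -> SyntheticCase:
    """Simulate one full ablation case, optionally writing it to ``out_dir``.

    All randomness flows from one generator seeded with ``cfg.rng_seed``:
    identical configs produce bit-identical cases.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n_frames = cfg.n_frames
    frame_times = np.arange(n_frames) / cfg.frame_rate_fps
    frames = np.empty((n_frames, cfg.grid_height_px, cfg.grid_width_px), dtype=np.uint8)
    for i, t in enumerate(frame_times):
        frames[i] = render_frame(simulate_field(cfg, t), cfg, rng)
    probe_times, probe_values = sample_probes(cfg, rng)
    final_field = simulate_field(cfg, cfg.duration_s)
    area = float(
        np.count_nonzero(final_field.values >= LETHAL_ISOTHERM_C) * cfg.mm_per_px**2
    )
    case = SyntheticCase(
        cfg=cfg,
        case_id=case_id,
        frames=frames,
        frame_times_s=frame_times,
        probe_times_s=probe_times,
        probe_values_C=probe_values,
        final_field=final_field,
        truth_isotherm_area_mm2=area,
        truth_hyperechoic=hyperechoic_diameters_mm(cfg, cfg.duration_s),
    )
    if out_dir is not None:
        from . import io as _io

        _io.write_case(case, out_dir)
    return case


def preset_config(power: str, seed: int, **overrides) -> SimConfig:
    """Convenience builder for a P15/P20 case config."""
    return replace(SimConfig(power_preset=power, rng_seed=seed), **overrides)
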