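"""Synthetic scene-bundle generator.

Emulates the statistical structure of annotated outdoor motion/distance
datasets so the whole receptive-field pipeline is testable without any
recorded data:

* mostly-slow ground motion with a censored (sub-threshold) floor,
* fast, horizontally-biased, per-figure-coherent figure motion, giving a
  bimodal global speed distribution,
* bimodal distances with figures nearer than the ground plane behind them,
* spatially contiguous figure regions with irregular (smooth-blob) borders,
* a sky band at the top of the frame, excluded from analysis,
* a luminance channel from which a stand-in saliency map is derived.

Speeds are modelled on a log10 scale.  Valid (above noise-floor) log
speeds are drawn from normals truncated at the motion-validity threshold;
when ``fg_logspeed_offset`` is configured, the figure location parameter
is solved so that the population mean log10 speed of valid figure pixels
exceeds that of valid ground pixels by exactly the configured offset —
this is the recoverable ground truth for parameter-recovery checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.stats import truncnorm

from .scene_model import (
    GROUND,
    SKY,
    SPEED_THRESHOLD_DEG_S,
    SceneBundle,
    SceneMetadata,
)
from .gaze_sim import stand_in_saliency

__all__ = ["SceneGenParams", "generate_scene", "generate_dataset", "generate_mean_speed_series"]

_LOG_THRESHOLD = float(np.log10(SPEED_THRESHOLD_DEG_S))


@dataclass
class SceneGenParams:
    """Generator parameters.  Defaults are the package's study conditions.

    Speed distributions are log10-normal, censored below the 0.5 deg/s
    motion-validity threshold.  Medians of ~20 deg/s (figures) and
    ~1 deg/s (moving ground), with ~70% of ground pixels static
    (sub-threshold), mirror the headline structure of outdoor scenes in
    which figures are people/vehicles/animals and ground motion is mostly
    wind-blown vegetation.
    """

    # canvas
    height: int = 256
    width: int = 256
    fov_deg: float = 42.0
    frame_rate: float = 120.0
    # figures
    n_figures: int = 2
    figure_radius_deg: tuple[float, float] = (3.0, 8.0)
    boundary_harmonics: int = 4
    boundary_amplitude: float = 0.25
    # speeds (deg/s; sigmas in log10 units).  Figures move rigidly: one
    # base speed per figure (between-figure spread figure_speed_sigma)
    # with small per-pixel log jitter; ground speeds are per-pixel.
    figure_speed_median: float = 20.0
    figure_speed_sigma: float = 0.35
    figure_speed_jitter: float = 0.05
    ground_speed_median: float = 1.0
    ground_speed_sigma: float = 0.45
    ground_static_fraction: float = 0.7
    figure_static_fraction: float = 0.5
    # moving ground pixels caused by unlabeled movers / shadows: drawn from
    # the figure speed distribution
    ground_fast_fraction: float = 0.15
    fg_logspeed_offset: float | None = None
    # directions (deg): two-lobe von Mises mixture at 0/180
    kappa_figure: float = 4.0
    kappa_ground: float = 1.0
    figure_direction_jitter_kappa: float = 50.0
    # depth (m)
    ground_depth: tuple[float, float] = (3.0, 50.0)
    figure_depth_offset: float = 0.5
    # layout
    sky_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self):
        if not (1 <= self.n_figures <= 3):
            raise ValueError("n_figures must be in 1..3")
        if not (0.0 <= self.sky_fraction <= 0.3):
            raise ValueError("sky_fraction must be in [0, 0.3]")
        for name in (
            "figure_speed_median", "figure_speed_sigma", "ground_speed_median",
            "ground_speed_sigma", "kappa_figure", "kappa_ground",
            "figure_direction_jitter_kappa", "frame_rate", "fov_deg",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.figure_depth_offset < 1.0):
            raise ValueError("figure_depth_offset must be in (0, 1)")
        if not (0.0 <= self.ground_static_fraction < 1.0):
            raise ValueError("ground_static_fraction must be in [0, 1)")
        if not (0.0 <= self.figure_static_fraction < 1.0):
            raise ValueError("figure_static_fraction must be in [0, 1)")
        if not (0.0 <= self.ground_fast_fraction < 1.0):
            raise ValueError("ground_fast_fraction must be in [0, 1)")

    @property
    def deg_per_pixel(self) -> float:
        return self.fov_deg / self.width

    def metadata(self) -> SceneMetadata:
        return SceneMetadata(
            deg_per_pixel=self.deg_per_pixel,
            frame_rate=self.frame_rate,
            height=self.height,
            width=self.width,
            site_tag="synthetic",
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneGenParams":
        d = dict(d)
        for key in ("figure_radius_deg", "ground_depth"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Truncated log-speed model
# ---------------------------------------------------------------------------

def _trunc_logspeed_mean(mu: float, sigma: float) -> float:
    """Mean of Normal(mu, sigma) truncated below at log10(threshold)."""
    a = (_LOG_THRESHOLD - mu) / sigma
    return float(truncnorm.mean(a, np.inf, loc=mu, scale=sigma))


def _solve_figure_mu(params: SceneGenParams) -> float:
    """Figure log-speed location parameter.

    If ``fg_logspeed_offset`` is configured, solve for mu_f such that the
    population mean log10 speed of valid (above-threshold) figure pixels
    exceeds that of valid ground pixels by exactly the offset; otherwise
    use log10 of the configured figure median.  Valid ground speeds are a
    mixture: weight ``1 - ground_fast_fraction`` from the truncated ground
    distribution and ``ground_fast_fraction`` from the truncated figure
    distribution (unlabeled movers), so the mixture mean is
    ``(1-w) tm_g + w tm_f`` and the condition ``tm_f - mix = offset``
    reduces to ``tm_f = tm_g + offset / (1 - w)``.
    """
    if params.fg_logspeed_offset is None:
        return float(np.log10(params.figure_speed_median))
    mu_g = float(np.log10(params.ground_speed_median))
    w = params.ground_fast_fraction
    target = (
        _trunc_logspeed_mean(mu_g, params.ground_speed_sigma)
        + params.fg_logspeed_offset / (1.0 - w)
    )
    sig_f = params.figure_speed_sigma

    def gap(mu):
        return _trunc_logspeed_mean(mu, sig_f) - target

    # truncated mean is strictly increasing in mu and >= max(mu, threshold)
    lo, hi = target - 6 * sig_f, target + 1.0
    return float(optimize.brentq(gap, lo, hi, xtol=1e-12))


def _draw_trunc_logspeed(mu, sigma, size, rng):
    a = (_LOG_THRESHOLD - mu) / sigma
    return truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=size, random_state=rng)


def _draw_bilobe_direction(kappa, size, rng):
    """Von Mises mixture with equal lobes at 0 and 180 deg, in [0, 360)."""
    lobe = rng.integers(0, 2, size=size) * np.pi
    ang = rng.vonmises(lobe, kappa, size=size)
    return np.rad2deg(ang) % 360.0


# ---------------------------------------------------------------------------
# Figure blobs
# ---------------------------------------------------------------------------

def _blob_mask(shape, center, radius_px, harmonics, amplitude, rng):
    """Smooth closed-contour blob via low-frequency radial perturbation."""
    h, w = shape
    coeffs_a = rng.normal(0.0, 1.0, harmonics) / np.arange(1, harmonics + 1)
    coeffs_b = rng.normal(0.0, 1.0, harmonics) / np.arange(1, harmonics + 1)
    rmax = int(np.ceil(radius_px * (1 + 2 * amplitude))) + 1
    r0, c0 = center
    rows = np.arange(max(0, r0 - rmax), min(h, r0 + rmax + 1))
    cols = np.arange(max(0, c0 - rmax), min(w, c0 + rmax + 1))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    dy, dx = rr - r0, cc - c0
    rho = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    pert = np.zeros_like(theta)
    for k in range(1, harmonics + 1):
        pert += coeffs_a[k - 1] * np.cos(k * theta) + coeffs_b[k - 1] * np.sin(k * theta)
    radius = radius_px * np.clip(1.0 + amplitude * pert, 0.3, None)
    mask = np.zeros(shape, dtype=bool)
    mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1] = rho <= radius
    # keep the component containing the center (guards against stray lobes)
    lab, n = ndimage.label(mask)
    if n > 1:
        mask = lab == lab[r0, c0]
    return mask


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def generate_scene(params: SceneGenParams, seed: int | None = None) -> SceneBundle:
    """Generate one scene bundle.  Deterministic given (params, seed)."""
    if seed is None:
        seed = params.seed if params.seed is not None else 0
    rng = np.random.default_rng(seed)
    h, w = params.height, params.width
    dpp = params.deg_per_pixel

    sky_rows = int(round(params.sky_fraction * h))
    label = np.full((h, w), GROUND, dtype=np.uint8)
    label[:sky_rows, :] = SKY

    # --- figures: contiguous blobs with irregular borders ----------------
    r_lo, r_hi = params.figure_radius_deg
    fig_rows_c = []
    for fid in range(1, params.n_figures + 1):
        placed = False
        for _ in range(50):
            radius_deg = rng.uniform(r_lo, r_hi)
            radius_px = radius_deg / dpp
            margin = int(np.ceil(radius_px * (1 + 2 * params.boundary_amplitude)))
            if 2 * margin >= min(h, w):
                continue
            r0 = int(rng.integers(max(margin, sky_rows), h - margin))
            c0 = int(rng.integers(margin, w - margin))
            mask = _blob_mask(
                (h, w), (r0, c0), radius_px,
                params.boundary_harmonics, params.boundary_amplitude, rng,
            )
            if mask.sum() < 9:
                continue
            # overlapping an earlier figure would split it; retry instead
            if np.any((label[mask] != GROUND) & (label[mask] != SKY)):
                continue
            label[mask] = fid
            fig_rows_c.append((fid, r0))
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place figure {fid}: radius range {params.figure_radius_deg} deg "
                f"too large for a {h}x{w} canvas at {dpp:.3f} deg/px"
            )

    sky = label == SKY
    ground = label == GROUND
    figure = ~sky & ~ground

    # --- speeds (deg/s) ---------------------------------------------------
    mu_g = float(np.log10(params.ground_speed_median))
    mu_f = _solve_figure_mu(params)
    speed = np.full((h, w), np.nan)
    n_ground = int(ground.sum())
    static = rng.random(n_ground) < params.ground_static_fraction
    g_speed = np.empty(n_ground)
    g_speed[static] = rng.uniform(0.0, SPEED_THRESHOLD_DEG_S, static.sum())
    n_move = int((~static).sum())
    fast = rng.random(n_move) < params.ground_fast_fraction
    moving = np.empty(n_move)
    moving[~fast] = 10.0 ** _draw_trunc_logspeed(
        mu_g, params.ground_speed_sigma, int((~fast).sum()), rng
    )
    moving[fast] = 10.0 ** _draw_trunc_logspeed(
        mu_f, params.figure_speed_sigma, int(fast.sum()), rng
    )
    g_speed[~static] = moving
    speed[ground] = g_speed
    # figures move as rigid objects: static-vs-moving and the base speed
    # are per figure, with small per-pixel log jitter on top
    for fid, _ in fig_rows_c:
        m = label == fid
        n = int(m.sum())
        if rng.random() < params.figure_static_fraction:
            speed[m] = rng.uniform(0.0, SPEED_THRESHOLD_DEG_S, n)
        else:
            base = _draw_trunc_logspeed(mu_f, params.figure_speed_sigma, 1, rng)[0]
            speed[m] = 10.0 ** (base + rng.normal(0.0, params.figure_speed_jitter, n))

    # --- directions (deg) -------------------------------------------------
    direction = np.full((h, w), np.nan)
    direction[ground] = _draw_bilobe_direction(params.kappa_ground, n_ground, rng)
    for fid, _ in fig_rows_c:
        m = label == fid
        base = _draw_bilobe_direction(params.kappa_figure, 1, rng)[0]
        jitter = np.rad2deg(
            rng.vonmises(0.0, params.figure_direction_jitter_kappa, int(m.sum()))
        )
        direction[m] = (base + jitter) % 360.0

    # --- distances (m): hyperbolic ground-plane ramp, figures nearer ------
    near, far = params.ground_depth
    distance = np.full((h, w), np.nan)
    rows = np.arange(h, dtype=float)
    horizon = max(sky_rows, 1)
    t = np.clip((rows - horizon) / max(h - 1 - horizon, 1), 0.0, 1.0)
    ramp = near * far / (near + (far - near) * t)  # far at horizon -> near at bottom
    ground_ramp = np.broadcast_to(ramp[:, None], (h, w))
    dist_noise = rng.normal(0.0, 0.02, (h, w))
    distance[ground] = ground_ramp[ground] * np.exp(dist_noise[ground])
    for fid, r0 in fig_rows_c:
        m = label == fid
        base_d = params.figure_depth_offset * float(ramp[min(max(r0, horizon), h - 1)])
        distance[m] = np.clip(base_d + rng.normal(0.0, 0.05, int(m.sum())), 0.5, None)

    # --- luminance + saliency stand-in ------------------------------------
    lum = 0.45 + ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), 8.0) * 0.8
    lum += rng.normal(0.0, 0.03, (h, w))
    for fid, _ in fig_rows_c:
        m = label == fid
        lum[m] = rng.uniform(0.6, 0.9) + rng.normal(0.0, 0.03, int(m.sum()))
    lum[sky] = 0.95 + rng.normal(0.0, 0.01, int(sky.sum()))
    saliency = stand_in_saliency(lum)

    return SceneBundle(
        speed_map=speed,
        direction_map=direction,
        distance_map=distance,
        label_map=label,
        saliency_map=saliency,
        luminance_map=lum,
        metadata=params.metadata(),
        scene_id=f"synthetic-{seed}",
    )


def generate_dataset(
    n_scenes: int,
    params: SceneGenParams,
    seed: int = 0,
    out_dir=None,
) -> tuple[list[SceneBundle], dict]:
    """Generate ``n_scenes`` independent scenes with derived child seeds.

    Returns the bundles plus a manifest (written to ``out_dir`` as JSON if
    given) listing the per-scene seeds for reproducibility.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    master = np.random.default_rng(seed)
    child_seeds = [int(s) for s in master.integers(0, 2**31 - 1, size=n_scenes)]
    bundles = [generate_scene(params, s) for s in child_seeds]
    manifest = {
        "master_seed": int(seed),
        "n_scenes": int(n_scenes),
        "child_seeds": child_seeds,
        "params": params.to_dict(),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundles, manifest


# ---------------------------------------------------------------------------
# Mean-speed time series (for motion-epoch selection)
# ---------------------------------------------------------------------------

def generate_mean_speed_series(
    duration_s: float,
    frame_rate: float,
    event_times: list[float],
    event_amps: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 0.2,
    event_sd_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean-speed series: baseline + Gaussian bump events + noise.

    Returns ``(series, event_frames)`` where ``event_frames`` are the
    ground-truth bump-center frame indices.  Events closer together than
    3 s are rejected (they could not be resolved as distinct epochs).
    """
    if len(event_times) != len(event_amps):
        raise ValueError("event_times and event_amps must have equal length")
    for t in event_times:
        if not (0.0 <= t <= duration_s):
            raise ValueError(f"event time {t} outside [0, {duration_s}]")
    times = sorted(event_times)
    for t0, t1 in zip(times, times[1:]):
        if t1 - t0 < 3.0:
            raise ValueError(f"events at {t0}s and {t1}s are closer than 3 s")
    n = int(round(duration_s * frame_rate))
    t = np.arange(n) / frame_rate
    series = np.full(n, baseline, dtype=float)
    for tc, amp in zip(event_times, event_amps):
        series += amp * np.exp(-0.5 * ((t - tc) / event_sd_s) ** 2)
    if noise_sd > 0:
        series += np.random.default_rng(seed).normal(0.0, noise_sd, n)
    event_frames = np.array([int(round(tc * frame_rate)) for tc in event_times])
    return series, event_frames
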