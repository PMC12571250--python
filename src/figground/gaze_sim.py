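"""Gaze simulation: fixation selection, smooth pursuit, and vergence.

The observer is modelled as fixating a salient scene point.  For motion,
perfect smooth pursuit of the fixated point is assumed: the motion vector
at fixation is subtracted from the motion of every other point, giving
retinal motion.  If the fixated point's world speed is at or below the
motion-validity threshold the fixation is treated as stationary (no
pursuit).  For distance, a vergence eye movement is assumed: both eyes
rotate to place the fixated point on their foveas, and the horizontal
binocular disparity of every other point follows from the two eyes'
viewing geometry.

Disparity geometry
------------------
Scene points are expressed in Cartesian coordinates ``P = [x y z]`` (m)
with the cyclopean origin at the range sensor and ``z`` the forward axis.
The eyes sit at ``x = +/- s/2`` (interocular separation ``s``, default
0.062 m).  In eye frames ``x_R = 0.5 s - x`` and ``x_L = -0.5 s - x``.
With the fixated point ``P_fix = [x* y* z*]``, the horizontal angular
eccentricity of a point in each eye is

    theta_{R,L} = atan(x*_{R,L} / z*) - atan(x_{R,L} / z)

and the horizontal disparity is ``d = theta_L - theta_R`` in degrees,
with crossed disparities (points nearer than fixation) positive and
uncrossed (farther) negative.  Relative disparity between any two points
is independent of the fixated point: the fixation terms cancel exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .scene_model import SKY, SPEED_THRESHOLD_DEG_S, SceneBundle

__all__ = [
    "INTEROCULAR_M",
    "GazeState",
    "stand_in_saliency",
    "fixation_candidates",
    "make_gaze_state",
    "retinal_motion",
    "point_coordinates",
    "binocular_disparity",
    "disparity_map",
]

#: Interpupillary separation in meters.
INTEROCULAR_M = 0.062


@dataclass(frozen=True)
class GazeState:
    """One simulated fixation.

    ``pursuit_active`` is False whenever the fixated point's world speed
    is at or below the detection threshold (0.5 deg/s) or missing, or
    when pursuit is globally disabled (stationary-eye control analysis).
    """

    fixation_pixel: tuple[int, int]
    fixation_world_motion: tuple[float, float]  # (vx, vy) deg/s, +x right +y up
    pursuit_active: bool
    fixation_distance: float  # m (NaN if unmeasured)
    interocular_s: float = INTEROCULAR_M

    def __post_init__(self):
        if self.interocular_s <= 0:
            raise ValueError("interocular separation must be > 0")
        vx, vy = self.fixation_world_motion
        speed = float(np.hypot(vx, vy)) if np.isfinite(vx) and np.isfinite(vy) else np.nan
        if self.pursuit_active and not (np.isfinite(speed) and speed > SPEED_THRESHOLD_DEG_S):
            raise ValueError("pursuit_active requires above-threshold fixation motion")


# ---------------------------------------------------------------------------
# Saliency and fixation candidates
# ---------------------------------------------------------------------------

def stand_in_saliency(luminance: np.ndarray, window: int = 7) -> np.ndarray:
    """Bottom-up saliency stand-in: local intensity variance.

    Per-pixel variance of the luminance over a ``window`` x ``window``
    neighbourhood.  Invariant to adding a constant to the image; only the
    induced median split into fixation candidates matters downstream.
    """
    lum = np.asarray(luminance, dtype=np.float64)
    mean = ndimage.uniform_filter(lum, size=window, mode="nearest")
    meansq = ndimage.uniform_filter(lum * lum, size=window, mode="nearest")
    return np.clip(meansq - mean * mean, 0.0, None)


def fixation_candidates(saliency: np.ndarray) -> np.ndarray:
    """Plausible fixation pixels: the upper half of a salience median split.

    True for pixels at or above the median salience.  With all-distinct
    values this selects ceil(N/2) pixels; ties can only enlarge the set.
    """
    sal = np.asarray(saliency, dtype=np.float64)
    if not np.all(np.isfinite(sal)):
        raise ValueError("saliency must be finite everywhere")
    return sal >= np.median(sal)


# ---------------------------------------------------------------------------
# Smooth pursuit (retinal motion)
# ---------------------------------------------------------------------------

def make_gaze_state(
    bundle: SceneBundle,
    fixation_pixel: tuple[int, int],
    pursuit_enabled: bool = True,
    interocular_s: float = INTEROCULAR_M,
) -> GazeState:
    """Build the gaze state for a fixation pixel of a scene bundle."""
    r, c = fixation_pixel
    if bundle.label_map[r, c] == SKY:
        raise ValueError(f"fixation pixel {fixation_pixel} lies on sky")
    speed = float(bundle.speed_map[r, c])
    direction = float(bundle.direction_map[r, c])
    if np.isfinite(speed) and np.isfinite(direction):
        vx = speed * np.cos(np.deg2rad(direction))
        vy = speed * np.sin(np.deg2rad(direction))
    else:
        speed, vx, vy = np.nan, 0.0, 0.0
    active = (
        pursuit_enabled
        and np.isfinite(speed)
        and speed > SPEED_THRESHOLD_DEG_S
    )
    return GazeState(
        fixation_pixel=(int(r), int(c)),
        fixation_world_motion=(float(vx), float(vy)),
        pursuit_active=bool(active),
        fixation_distance=float(bundle.distance_map[r, c]),
        interocular_s=interocular_s,
    )


def retinal_motion(bundle: SceneBundle, gaze: GazeState):
    """Retinal speed and direction rasters under smooth pursuit.

    Subtracts the fixated point's world motion vector from every pixel's
    motion when pursuit is active; with pursuit inactive (stationary eye)
    the world motion passes through unchanged.  Returns ``(speed_deg_s,
    direction_deg)`` with direction in [0, 360) and NaN wherever the
    world motion is missing.
    """
    speed = np.asarray(bundle.speed_map, dtype=np.float64)
    direction = np.asarray(bundle.direction_map, dtype=np.float64)
    if not gaze.pursuit_active:
        return speed.copy(), direction.copy()
    vfx, vfy = gaze.fixation_world_motion
    rad = np.deg2rad(direction)
    vx = speed * np.cos(rad) - vfx
    vy = speed * np.sin(rad) - vfy
    ret_speed = np.hypot(vx, vy)
    ret_dir = np.rad2deg(np.arctan2(vy, vx)) % 360.0
    missing = ~np.isfinite(speed)
    ret_speed[missing] = np.nan
    ret_dir[missing] = np.nan
    return ret_speed, ret_dir


# ---------------------------------------------------------------------------
# Vergence and binocular disparity
# ---------------------------------------------------------------------------

def point_coordinates(angular_xy_deg, distance_m):
    """Cartesian world coordinates [x y z] (m) of scene points.

    ``angular_xy_deg`` is an (..., 2) array of angular offsets from the
    optical axis (+x right, +y up, degrees); ``distance_m`` the radial
    distance from the cyclopean origin.  Azimuth/elevation convention:
    ``x = r cos(el) sin(az)``, ``y = r sin(el)``, ``z = r cos(el) cos(az)``;
    the on-axis point maps to [0, 0, r].
    """
    ang = np.asarray(angular_xy_deg, dtype=np.float64)
    r = np.asarray(distance_m, dtype=np.float64)
    if np.any(r[np.isfinite(r)] <= 0):
        raise ValueError("distances must be positive")
    az = np.deg2rad(ang[..., 0])
    el = np.deg2rad(ang[..., 1])
    x = r * np.cos(el) * np.sin(az)
    y = r * np.sin(el)
    z = r * np.cos(el) * np.cos(az)
    return np.stack([x, y, z], axis=-1)


def binocular_disparity(P, P_fix, s: float = INTEROCULAR_M):
    """Horizontal binocular disparity of points ``P`` while fixating ``P_fix``.

    Returns disparity in degrees, crossed (nearer than fixation) positive.
    ``P`` may be a single [x y z] or an (..., 3) array.
    """
    P = np.asarray(P, dtype=np.float64)
    F = np.asarray(P_fix, dtype=np.float64)
    if s <= 0:
        raise ValueError("interocular separation must be > 0")
    z = P[..., 2]
    zf = F[..., 2]
    if np.any(z[np.isfinite(z)] <= 0) or not np.all(zf > 0):
        raise ValueError("all points must lie in front of the eyes (z > 0)")
    x, xf = P[..., 0], F[..., 0]
    x_r, x_l = 0.5 * s - x, -0.5 * s - x
    xf_r, xf_l = 0.5 * s - xf, -0.5 * s - xf
    theta_r = np.arctan2(xf_r, zf) - np.arctan2(x_r, z)
    theta_l = np.arctan2(xf_l, zf) - np.arctan2(x_l, z)
    d = np.rad2deg(theta_l - theta_r)
    return float(d) if d.ndim == 0 else d


def disparity_map(bundle: SceneBundle, gaze: GazeState) -> np.ndarray:
    """Per-pixel horizontal disparity raster (deg) for a fixation.

    Missing (NaN) wherever the distance map is missing.  Raises if the
    fixated point itself has no distance measurement.
    """
    if not np.isfinite(gaze.fixation_distance) or gaze.fixation_distance <= 0:
        raise ValueError("fixation distance is missing or nonpositive")
    ax, ay = bundle.pixel_angles()
    dist = np.asarray(bundle.distance_map, dtype=np.float64)
    valid = np.isfinite(dist) & (dist > 0)
    ang = np.stack([ax[valid], ay[valid]], axis=-1)
    P = point_coordinates(ang, dist[valid])
    fr, fc = gaze.fixation_pixel
    P_fix = point_coordinates(
        np.array([ax[fr, fc], ay[fr, fc]]), gaze.fixation_distance
    )
    out = np.full(dist.shape, np.nan)
    out[valid] = binocular_disparity(P, P_fix, gaze.interocular_s)
    return out
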