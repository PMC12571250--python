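"""Placement and validation of simulated receptive fields (sRFs).

An sRF is a circular image aperture standing in for an MT neuron's
receptive field.  Four diameters are simulated (2.5, 5, 10, 15 deg) and,
since MT receptive-field sizes roughly match their eccentricities, each
sRF is paired with a fixation point whose distance from the sRF center
equals the diameter (within a +/-10% annulus tolerance).

Acceptance rules, applied in a fixed order so reject reasons are
reproducible:

1. at most 50% of aperture pixels may carry missing measurements
   (sky, sub-threshold motion, missing distance);
2. at least 25% of non-buffer aperture pixels must be figure;
3. at least 25% must be ground;
4. a salient fixation candidate must exist in the eccentricity annulus.

Sampling is repeated (rejection sampling over random scene, position and
fixation) until the requested number of samples per diameter is reached.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_sim import GazeState, fixation_candidates, make_gaze_state
from .scene_model import SKY, SceneBundle

__all__ = [
    "SRF_DIAMETERS_DEG",
    "SRFSample",
    "aperture_mask",
    "propose_srf",
    "assign_fixation",
    "validate_srf",
    "build_srf_set",
    "srf_table",
]

SRF_DIAMETERS_DEG = (2.5, 5.0, 10.0, 15.0)

#: Fixation eccentricity must lie within diameter * (1 +/- this tolerance).
ECCENTRICITY_TOL = 0.1


@dataclass
class SRFSample:
    """One accepted simulated receptive field."""

    scene_id: str
    scene_index: int
    center: tuple[int, int]
    diameter_deg: float
    eccentricity_deg: float
    gaze: GazeState
    figure_pixels: tuple[np.ndarray, np.ndarray]  # (rows, cols), non-buffer
    ground_pixels: tuple[np.ndarray, np.ndarray]
    figure_fraction: float
    ground_fraction: float
    invalid_fraction: float
    attempts: int = 0

    def __post_init__(self):
        if self.figure_fraction < 0.25 or self.ground_fraction < 0.25:
            raise ValueError("figure and ground fractions must each be >= 0.25")
        if self.invalid_fraction > 0.5:
            raise ValueError("invalid_fraction must be <= 0.5")


def aperture_mask(shape, center, radius_px: float) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the circular aperture."""
    h, w = shape
    r0, c0 = center
    lo_r, hi_r = max(0, int(r0 - radius_px) - 1), min(h, int(r0 + radius_px) + 2)
    lo_c, hi_c = max(0, int(c0 - radius_px) - 1), min(w, int(c0 + radius_px) + 2)
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    inside = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius_px**2
    mask = np.zeros(shape, dtype=bool)
    mask[lo_r:hi_r, lo_c:hi_c] = inside
    return mask


def propose_srf(scene: SceneBundle, diameter_deg: float, rng) -> tuple[int, int]:
    """Uniform random aperture center such that the full circle is in-bounds."""
    dpp = scene.metadata.deg_per_pixel
    radius_px = diameter_deg / 2.0 / dpp
    h, w = scene.label_map.shape
    margin = int(np.ceil(radius_px))
    if 2 * margin >= h or 2 * margin >= w:
        raise ValueError(
            f"sRF diameter {diameter_deg} deg does not fit in a "
            f"{h}x{w} raster at {dpp:.4f} deg/px"
        )
    r = int(rng.integers(margin, h - margin))
    c = int(rng.integers(margin, w - margin))
    return r, c


def assign_fixation(
    scene: SceneBundle,
    center: tuple[int, int],
    diameter_deg: float,
    candidates: np.ndarray,
    rng,
    tol: float = ECCENTRICITY_TOL,
    pursuit_enabled: bool = True,
) -> GazeState | None:
    """Pick a salient fixation in the eccentricity annulus, or reject (None).

    Candidates are non-sky salient pixels whose distance from the sRF
    center lies in ``diameter * [1 - tol, 1 + tol]``; one is chosen
    uniformly at random.
    """
    dpp = scene.metadata.deg_per_pixel
    h, w = scene.label_map.shape
    r0, c0 = center
    lo = diameter_deg * (1 - tol) / dpp
    hi = diameter_deg * (1 + tol) / dpp
    rows, cols = np.nonzero(candidates)
    dist = np.hypot(rows - r0, cols - c0)
    ok = (dist >= lo) & (dist <= hi)
    ok &= scene.label_map[rows, cols] != SKY
    ok &= np.isfinite(scene.distance_map[rows, cols])
    if not ok.any():
        return None
    idx = rng.integers(0, int(ok.sum()))
    fr, fc = rows[ok][idx], cols[ok][idx]
    return make_gaze_state(scene, (int(fr), int(fc)), pursuit_enabled=pursuit_enabled)


def validate_srf(scene: SceneBundle, center: tuple[int, int], diameter_deg: float):
    """Apply the aperture content rules; returns (accepted, reason, stats).

    ``stats`` carries the computed fractions and the non-buffer figure and
    ground pixel index sets, so an accepted proposal can be turned into an
    :class:`SRFSample` without recounting.
    """
    dpp = scene.metadata.deg_per_pixel
    radius_px = diameter_deg / 2.0 / dpp
    ap = aperture_mask(scene.label_map.shape, center, radius_px)
    n_ap = int(ap.sum())
    invalid = (
        (scene.label_map == SKY)
        | ~scene.valid_motion_mask
        | ~np.isfinite(scene.distance_map)
    )
    invalid_fraction = float(invalid[ap].mean())
    nonbuf = ap & ~scene.buffer_mask
    n_nonbuf = int(nonbuf.sum())
    stats = {
        "invalid_fraction": invalid_fraction,
        "figure_fraction": 0.0,
        "ground_fraction": 0.0,
        "n_aperture": n_ap,
        "n_nonbuffer": n_nonbuf,
    }
    if invalid_fraction > 0.5:
        return False, "invalid_fraction", stats
    if n_nonbuf == 0:
        return False, "figure_fraction", stats
    fig = nonbuf & scene.figure_mask
    grd = nonbuf & scene.ground_mask
    stats["figure_fraction"] = float(fig.sum() / n_nonbuf)
    stats["ground_fraction"] = float(grd.sum() / n_nonbuf)
    if stats["figure_fraction"] < 0.25:
        return False, "figure_fraction", stats
    if stats["ground_fraction"] < 0.25:
        return False, "ground_fraction", stats
    stats["figure_pixels"] = np.nonzero(fig)
    stats["ground_pixels"] = np.nonzero(grd)
    return True, "", stats


def build_srf_set(
    dataset: list[SceneBundle],
    n_per_size: int = 200,
    sizes=SRF_DIAMETERS_DEG,
    seed: int = 0,
    pursuit_enabled: bool = True,
    acceptance_floor: float = 5e-4,
    min_attempts: int = 4000,
) -> tuple[list[SRFSample], dict]:
    """Rejection-sample sRFs until ``n_per_size`` are accepted per diameter.

    Returns the samples plus a provenance dict with per-reason reject
    counts.  Aborts with diagnostics if the acceptance rate stays below
    ``acceptance_floor`` after ``min_attempts`` proposals for a size.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    rng = np.random.default_rng(seed)
    candidate_masks = [
        fixation_candidates(b.saliency_map) if b.saliency_map is not None
        else np.ones(b.label_map.shape, dtype=bool)
        for b in dataset
    ]
    samples: list[SRFSample] = []
    rejects: Counter = Counter()
    attempts_by_size = {}
    for diameter in sizes:
        accepted = 0
        attempts = 0
        while accepted < n_per_size:
            attempts += 1
            if attempts >= min_attempts and accepted / attempts < acceptance_floor:
                raise RuntimeError(
                    f"acceptance rate {accepted}/{attempts} below floor for "
                    f"diameter {diameter} deg; reject counts: {dict(rejects)}"
                )
            i = int(rng.integers(0, len(dataset)))
            scene = dataset[i]
            center = propose_srf(scene, diameter, rng)
            ok, reason, stats = validate_srf(scene, center, diameter)
            if not ok:
                rejects[reason] += 1
                continue
            gaze = assign_fixation(
                scene, center, diameter, candidate_masks[i], rng,
                pursuit_enabled=pursuit_enabled,
            )
            if gaze is None:
                rejects["fixation"] += 1
                continue
            dpp = scene.metadata.deg_per_pixel
            ecc = float(
                np.hypot(
                    gaze.fixation_pixel[0] - center[0],
                    gaze.fixation_pixel[1] - center[1],
                ) * dpp
            )
            samples.append(
                SRFSample(
                    scene_id=scene.scene_id,
                    scene_index=i,
                    center=center,
                    diameter_deg=float(diameter),
                    eccentricity_deg=ecc,
                    gaze=gaze,
                    figure_pixels=stats["figure_pixels"],
                    ground_pixels=stats["ground_pixels"],
                    figure_fraction=stats["figure_fraction"],
                    ground_fraction=stats["ground_fraction"],
                    invalid_fraction=stats["invalid_fraction"],
                    attempts=attempts,
                )
            )
            accepted += 1
        attempts_by_size[float(diameter)] = attempts
    provenance = {
        "seed": int(seed),
        "n_per_size": int(n_per_size),
        "sizes": [float(s) for s in sizes],
        "reject_counts": dict(rejects),
        "attempts_by_size": attempts_by_size,
        "fixation_on_figure_fraction": float(
            np.mean([
                dataset[s.scene_index].figure_mask[s.gaze.fixation_pixel]
                for s in samples
            ])
        ) if samples else float("nan"),
    }
    return samples, provenance


def srf_table(samples: list[SRFSample]) -> pd.DataFrame:
    """Tidy one-row-per-sample table of sRF placements and fractions."""
    return pd.DataFrame(
        {
            "scene_id": [s.scene_id for s in samples],
            "scene_index": [s.scene_index for s in samples],
            "center_row": [s.center[0] for s in samples],
            "center_col": [s.center[1] for s in samples],
            "diameter_deg": [s.diameter_deg for s in samples],
            "eccentricity_deg": [s.eccentricity_deg for s in samples],
            "fixation_row": [s.gaze.fixation_pixel[0] for s in samples],
            "fixation_col": [s.gaze.fixation_pixel[1] for s in samples],
            "pursuit_active": [s.gaze.pursuit_active for s in samples],
            "fixation_distance_m": [s.gaze.fixation_distance for s in samples],
            "figure_fraction": [s.figure_fraction for s in samples],
            "ground_fraction": [s.ground_fraction for s in samples],
            "invalid_fraction": [s.invalid_fraction for s in samples],
        }
    )
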