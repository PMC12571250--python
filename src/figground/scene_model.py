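"""Core raster data model for figure-ground scene analysis.

A *scene bundle* holds co-registered per-pixel maps of motion speed
(deg/s), motion direction (deg, 0 = rightward, 90 = upward), radial
distance (m) and figure/ground/sky labels, plus acquisition metadata.
All downstream stages (gaze simulation, receptive-field sampling,
statistics) consume this container.

Conventions
-----------
* Rasters are indexed ``(row, col)``, 0-based.  The angular position of a
  pixel relative to a reference pixel is
  ``((col - ref_col) * deg_per_pixel, (ref_row - row) * deg_per_pixel)``
  so +x is rightward and +y is upward, matching the direction convention.
* Missing values in floating rasters are ``NaN``; sky pixels are missing
  for motion and distance and are excluded from every analysis.
* Label codes: 0 = sky, 1..K = figure ids, 255 = ground.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image
from scipy import ndimage

__all__ = [
    "SKY",
    "GROUND",
    "SPEED_THRESHOLD_DEG_S",
    "BUFFER_PX",
    "SceneMetadata",
    "SceneBundle",
    "pxframe_to_degs",
    "fov_to_degperpixel",
    "boundary_buffer_mask",
    "speed_threshold_mask",
    "read_bundle",
    "write_bundle",
]

# Label codes used in the paletted label raster.
SKY = 0
GROUND = 255

#: Motion-validity threshold (deg/s).  Speeds at or below this value are
#: treated as unmeasurable (noise-floor censored) and excluded.
SPEED_THRESHOLD_DEG_S = 0.5

#: Default exclusion buffer (pixels, Chebyshev radius) around label borders.
BUFFER_PX = 5


@dataclass(frozen=True)
class SceneMetadata:
    """Acquisition metadata for one scene.

    Parameters
    ----------
    deg_per_pixel : float
        Angular resolution in degrees per pixel (> 0).
    frame_rate : float
        Capture rate in Hz (> 0).
    height, width : int
        Raster dimensions in pixels.
    field_of_view : tuple of float
        (horizontal, vertical) extent in degrees; must agree with
        ``dims * deg_per_pixel`` within 10%.
    site_tag : str
        Free-text provenance tag.
    """

    deg_per_pixel: float
    frame_rate: float
    height: int
    width: int
    field_of_view: tuple[float, float] = (0.0, 0.0)
    site_tag: str = ""

    def __post_init__(self):
        if self.deg_per_pixel <= 0:
            raise ValueError(f"deg_per_pixel must be > 0, got {self.deg_per_pixel}")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.height <= 0 or self.width <= 0:
            raise ValueError("raster dimensions must be positive")
        fov = self.field_of_view
        if fov == (0.0, 0.0):
            fov = (self.width * self.deg_per_pixel, self.height * self.deg_per_pixel)
            object.__setattr__(self, "field_of_view", fov)
        expected = (self.width * self.deg_per_pixel, self.height * self.deg_per_pixel)
        for got, exp in zip(fov, expected):
            if abs(got - exp) > 0.1 * exp:
                raise ValueError(
                    f"field_of_view {fov} inconsistent with dims x deg_per_pixel {expected}"
                )

    def to_dict(self) -> dict:
        return {
            "deg_per_pixel": self.deg_per_pixel,
            "frame_rate": self.frame_rate,
            "height": self.height,
            "width": self.width,
            "field_of_view": list(self.field_of_view),
            "site_tag": self.site_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneMetadata":
        return cls(
            deg_per_pixel=float(d["deg_per_pixel"]),
            frame_rate=float(d["frame_rate"]),
            height=int(d["height"]),
            width=int(d["width"]),
            field_of_view=tuple(d.get("field_of_view", (0.0, 0.0))),
            site_tag=d.get("site_tag", ""),
        )


@dataclass
class SceneBundle:
    """Co-registered rasters plus derived validity masks for one scene.

    ``buffer_mask`` (True = excluded near a label border) and
    ``valid_motion_mask`` (True = measurable, above-threshold motion on a
    non-sky pixel) are derived from the core rasters and recomputed via
    :meth:`finalize`.
    """

    speed_map: np.ndarray
    direction_map: np.ndarray
    distance_map: np.ndarray
    label_map: np.ndarray
    metadata: SceneMetadata
    saliency_map: np.ndarray | None = None
    luminance_map: np.ndarray | None = None
    scene_id: str = ""
    buffer_mask: np.ndarray = field(default=None, repr=False)
    valid_motion_mask: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        shape = self.label_map.shape
        for name in ("speed_map", "direction_map", "distance_map"):
            r = getattr(self, name)
            if r.shape != shape:
                raise ValueError(f"{name} shape {r.shape} != label_map shape {shape}")
        if self.saliency_map is not None and self.saliency_map.shape != shape:
            raise ValueError("saliency_map shape mismatch")
        if shape != (self.metadata.height, self.metadata.width):
            raise ValueError("raster shape disagrees with metadata dims")
        if self.buffer_mask is None or self.valid_motion_mask is None:
            self.finalize()

    def finalize(
        self,
        buffer_px: int = BUFFER_PX,
        speed_threshold: float = SPEED_THRESHOLD_DEG_S,
    ) -> "SceneBundle":
        """Recompute the derived masks in place and return self."""
        self.buffer_mask = boundary_buffer_mask(self.label_map, buffer_px)
        self.valid_motion_mask = speed_threshold_mask(
            self.speed_map, speed_threshold, label_map=self.label_map
        )
        return self

    # -- label helpers -------------------------------------------------
    @property
    def sky_mask(self) -> np.ndarray:
        return self.label_map == SKY

    @property
    def figure_mask(self) -> np.ndarray:
        return (self.label_map != SKY) & (self.label_map != GROUND)

    @property
    def ground_mask(self) -> np.ndarray:
        return self.label_map == GROUND

    @property
    def figure_ids(self) -> np.ndarray:
        ids = np.unique(self.label_map)
        return ids[(ids != SKY) & (ids != GROUND)]

    def valid_distance_mask(self) -> np.ndarray:
        return np.isfinite(self.distance_map) & ~self.sky_mask

    def pixel_angles(self, ref: tuple[int, int] | None = None):
        """Angular (x, y) position of every pixel, degrees, +x right / +y up.

        ``ref`` is the (row, col) taken as the angular origin; defaults to
        the raster center.
        """
        h, w = self.label_map.shape
        if ref is None:
            ref = ((h - 1) / 2.0, (w - 1) / 2.0)
        rows, cols = np.mgrid[0:h, 0:w]
        ax = (cols - ref[1]) * self.metadata.deg_per_pixel
        ay = (ref[0] - rows) * self.metadata.deg_per_pixel
        return ax, ay


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def pxframe_to_degs(v, meta: SceneMetadata):
    """Convert a pixels-per-frame displacement to an angular speed in deg/s.

    Linear in ``v``: ``v * deg_per_pixel * frame_rate``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("pixel/frame speed must be nonnegative")
    out = v * meta.deg_per_pixel * meta.frame_rate
    return float(out) if out.ndim == 0 else out


def fov_to_degperpixel(fov_deg: float, n_pixels: int) -> float:
    """Angular resolution (deg/pixel) from a field of view and pixel count."""
    if fov_deg <= 0:
        raise ValueError("field of view must be positive")
    if n_pixels <= 0:
        raise ValueError("pixel count must be positive")
    return fov_deg / n_pixels


# ---------------------------------------------------------------------------
# Validity masks
# ---------------------------------------------------------------------------

def boundary_buffer_mask(label_map: np.ndarray, buffer_px: int = BUFFER_PX) -> np.ndarray:
    """Exclusion mask around label borders.

    True for any pixel within ``buffer_px`` (Chebyshev distance, i.e. a
    square structuring element) of a pixel carrying a different label.
    Prevents cross-contamination of figure/ground statistics by pixels
    straddling an annotation boundary.
    """
    label_map = np.asarray(label_map)
    if buffer_px < 0:
        raise ValueError("buffer_px must be >= 0")
    if buffer_px == 0:
        return np.zeros(label_map.shape, dtype=bool)
    lab = label_map.astype(np.int64)
    size = 2 * buffer_px + 1
    # A pixel is within buffer_px of a differing label iff the local min and
    # max over the (2b+1)^2 Chebyshev neighbourhood disagree.
    lo = ndimage.minimum_filter(lab, size=size, mode="nearest")
    hi = ndimage.maximum_filter(lab, size=size, mode="nearest")
    return lo != hi


def speed_threshold_mask(
    speed_map: np.ndarray,
    threshold: float = SPEED_THRESHOLD_DEG_S,
    label_map: np.ndarray | None = None,
) -> np.ndarray:
    """Motion-validity mask: True where speed strictly exceeds ``threshold``.

    Speeds at or below the threshold sit within the noise floor of motion
    estimation and are censored.  Missing (NaN) speeds and sky pixels are
    always invalid.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    speed = np.asarray(speed_map, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = np.isfinite(speed) & (speed > threshold)
    if label_map is not None:
        mask &= np.asarray(label_map) != SKY
    return mask


# ---------------------------------------------------------------------------
# Container I/O: 32-bit float TIFF rasters, paletted PNG labels, JSON sidecar
# ---------------------------------------------------------------------------

_FLOAT_CHANNELS = ("speed", "direction", "distance")
_OPTIONAL_CHANNELS = ("saliency", "luminance")


def write_bundle(bundle: SceneBundle, path) -> Path:
    """Write a bundle to ``path`` (a directory) in standard formats.

    Floating rasters go to single-channel 32-bit TIFFs, labels to an 8-bit
    paletted PNG, metadata (including the declared figure ids) to a JSON
    sidecar.  Derived masks are not stored; they are recomputed on read.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {
        "speed": bundle.speed_map,
        "direction": bundle.direction_map,
        "distance": bundle.distance_map,
    }
    if bundle.saliency_map is not None:
        arrays["saliency"] = bundle.saliency_map
    if bundle.luminance_map is not None:
        arrays["luminance"] = bundle.luminance_map
    for name, arr in arrays.items():
        tifffile.imwrite(path / f"{name}.tif", np.asarray(arr, dtype=np.float32))
    lab = np.asarray(bundle.label_map, dtype=np.uint8)
    img = Image.fromarray(lab, mode="P")
    palette = np.zeros((256, 3), dtype=np.uint8)
    palette[GROUND] = (40, 90, 200)          # ground: blue
    palette[1:GROUND] = (200, 40, 40)        # figures: red
    palette[SKY] = (0, 0, 0)                 # sky: black
    img.putpalette(palette.flatten().tolist())
    img.save(path / "labels.png")
    sidecar = {
        "metadata": bundle.metadata.to_dict(),
        "scene_id": bundle.scene_id,
        "figure_ids": [int(i) for i in bundle.figure_ids],
        "channels": sorted(arrays),
    }
    (path / "metadata.json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_bundle(path) -> SceneBundle:
    """Read a bundle written by :func:`write_bundle`.

    ``read(write(b))`` reproduces every raster (bit-exact for labels, to
    float32 precision for floating rasters) and recomputes the derived
    masks.  Raises if a required channel is missing or if the label PNG
    contains a value not declared in the sidecar.
    """
    path = Path(path)
    sidecar_path = path / "metadata.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    meta = SceneMetadata.from_dict(sidecar["metadata"])

    rasters = {}
    for name in _FLOAT_CHANNELS:
        f = path / f"{name}.tif"
        if not f.exists():
            raise FileNotFoundError(f"bundle at {path} is missing channel '{name}'")
        rasters[name] = tifffile.imread(f).astype(np.float64)
    for name in _OPTIONAL_CHANNELS:
        f = path / f"{name}.tif"
        rasters[name] = tifffile.imread(f).astype(np.float64) if f.exists() else None

    lab = np.asarray(Image.open(path / "labels.png"), dtype=np.uint8)
    declared = set(sidecar["figure_ids"]) | {SKY, GROUND}
    present = set(np.unique(lab).tolist())
    unknown = present - declared
    if unknown:
        raise ValueError(f"label PNG contains undeclared palette values {sorted(unknown)}")

    return SceneBundle(
        speed_map=rasters["speed"],
        direction_map=rasters["direction"],
        distance_map=rasters["distance"],
        label_map=lab,
        saliency_map=rasters["saliency"],
        luminance_map=rasters["luminance"],
        metadata=meta,
        scene_id=sidecar.get("scene_id", ""),
    )
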