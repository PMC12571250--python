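"""Motion-epoch selection from a per-frame mean-speed time series.

Each recording contributes two *motion epochs*: the two highest local
maxima of the Gaussian-smoothed mean-speed series, separated by at least
3 s so that distinct motion events are captured.  Each epoch is described
by three frames — motion onset, motion peak, and motion offset — where
onset (offset) is the frame whose raw mean speed is closest to 50% of the
peak speed within the 2.5 s window before (after) the peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["EpochTriplet", "smooth_series", "select_epochs"]


@dataclass(frozen=True)
class EpochTriplet:
    peak_frame: int
    onset_frame: int
    offset_frame: int
    peak_speed: float

    def __post_init__(self):
        if not (self.onset_frame < self.peak_frame < self.offset_frame):
            raise ValueError("epoch frames must satisfy onset < peak < offset")

    def to_dict(self) -> dict:
        return {
            "peak_frame": self.peak_frame,
            "onset_frame": self.onset_frame,
            "offset_frame": self.offset_frame,
            "peak_speed": self.peak_speed,
        }


def smooth_series(series: np.ndarray, sigma_frames: float = 120.0) -> np.ndarray:
    """Gaussian smoothing, edge-truncated and renormalized.

    Near the series ends the kernel is truncated to the available samples
    and renormalized so a constant series passes through unchanged.
    """
    series = np.asarray(series, dtype=np.float64)
    if series.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(series) <= 6 * sigma_frames:
        raise ValueError(
            f"series of length {len(series)} too short for sigma={sigma_frames} "
            f"(need > {int(6 * sigma_frames)} frames)"
        )
    num = ndimage.gaussian_filter1d(series, sigma_frames, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter1d(
        np.ones_like(series), sigma_frames, mode="constant", cval=0.0
    )
    return num / den


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus contribute their center frame."""
    n = len(x)
    out = []
    i = 1
    while i < n - 1:
        if x[i] > x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(out, dtype=int)


def _half_height_frame(raw, peak, half, lo, hi):
    """Frame in [lo, hi] whose raw speed is closest to ``half``; ties toward peak."""
    window = np.arange(lo, hi + 1)
    err = np.abs(raw[window] - half)
    best = err.min()
    tied = window[err == best]
    return int(tied[np.argmin(np.abs(tied - peak))])


def select_epochs(
    smoothed: np.ndarray,
    raw: np.ndarray,
    frame_rate: float,
    min_separation_s: float = 3.0,
    window_s: float = 2.5,
) -> list[EpochTriplet]:
    """Select the two motion epochs of a recording.

    The two highest local maxima of ``smoothed`` at >= ``min_separation_s``
    apart are taken as peaks; onsets/offsets are matched at 50% of the raw
    peak speed within ``window_s`` before/after each peak.
    """
    smoothed = np.asarray(smoothed, dtype=np.float64)
    raw = np.asarray(raw, dtype=np.float64)
    if smoothed.shape != raw.shape:
        raise ValueError("smoothed and raw series must share length")
    n = len(raw)
    maxima = _local_maxima(smoothed)
    if len(maxima) == 0:
        raise ValueError("no local maxima in the smoothed series")
    order = maxima[np.argsort(smoothed[maxima])[::-1]]
    min_sep = min_separation_s * frame_rate
    peaks = [int(order[0])]
    for cand in order[1:]:
        if abs(cand - peaks[0]) >= min_sep:
            peaks.append(int(cand))
            break
    if len(peaks) < 2:
        raise ValueError("fewer than two local maxima separated by the minimum 3 s")

    win = int(round(window_s * frame_rate))
    epochs = []
    for pk in sorted(peaks):
        peak_speed = float(raw[pk])
        half = 0.5 * peak_speed
        lo_on, hi_on = max(0, pk - win), pk - 1
        lo_off, hi_off = pk + 1, min(n - 1, pk + win)
        if hi_on < lo_on or hi_off > n - 1 or lo_off > hi_off:
            raise ValueError(f"peak at frame {pk} too close to the series edge")
        onset = _half_height_frame(raw, pk, half, lo_on, hi_on)
        offset = _half_height_frame(raw, pk, half, lo_off, hi_off)
        epochs.append(EpochTriplet(pk, onset, offset, peak_speed))
    return epochs
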