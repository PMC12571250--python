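"""Figure-ground statistics: global distributions, per-sRF summaries,
hypothesis tests, and figure/ground probability-ratio curves.

Per sRF and per feature we summarize the figure region and the ground
region separately — mean log10 retinal speed (s_f, s_g), circular
variance of retinal motion direction as a coherence measure (v_f, v_g),
and mean horizontal disparity (d_f, d_g) — and analyze the figure-ground
differences (delta_s, delta_v, delta_d) across sRFs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gaze_sim import disparity_map, retinal_motion
from .scene_model import SceneBundle
from .srf_sampler import SRFSample

__all__ = [
    "LOG_SPEED_FLOOR",
    "RegionSummary",
    "TestResult",
    "RatioCurve",
    "circular_variance",
    "region_summary",
    "one_sample_t",
    "anova_eta",
    "tukey_pairs",
    "ranksum_r",
    "rayleigh_test",
    "kuiper_two",
    "binomial_ci",
    "global_distributions",
    "normalized_speed_values",
    "aligned_directions",
    "ratio_curve",
    "srf_differences",
    "difference_tests",
    "srf_ratio_curves",
]

#: Retinal speeds below this (deg/s) are floored before log10: perfect
#: pursuit can null figure motion exactly, and log10(0) is undefined.
LOG_SPEED_FLOOR = 0.01

N_HISTOGRAM_BINS = 50


@dataclass(frozen=True)
class RegionSummary:
    """Per-sRF figure/ground region summaries (NaN where undefined)."""

    s_f: float
    s_g: float
    v_f: float
    v_g: float
    d_f: float
    d_g: float
    n_f: int
    n_g: int


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    effect_size: float
    ci: tuple[float, float] | None = None
    df: float | None = None

    def __post_init__(self):
        if np.isfinite(self.p_value) and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class RatioCurve:
    """Figure/ground probability-ratio curve over 50 linear bins."""

    bin_edges: np.ndarray
    figure_density: np.ndarray
    ground_density: np.ndarray
    ratio: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_srfs: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "figure_density": self.figure_density,
                "ground_density": self.ground_density,
                "ratio": self.ratio,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
            }
        )


# ---------------------------------------------------------------------------
# Circular statistics
# ---------------------------------------------------------------------------

def circular_variance(directions_deg) -> float:
    """1 minus the mean resultant length of direction unit vectors.

    0 for perfectly coherent directions, 1 for fully dispersed ones.
    """
    d = np.deg2rad(np.asarray(directions_deg, dtype=np.float64))
    if d.size == 0:
        raise ValueError("need at least one direction")
    rbar = np.abs(np.mean(np.exp(1j * d)))
    return float(np.clip(1.0 - rbar, 0.0, 1.0))


def rayleigh_test(directions_deg) -> TestResult:
    """Rayleigh test of circular uniformity.

    z = n * Rbar^2, with the standard small-sample-corrected p-value
    approximation; rejects when directions are concentrated.
    """
    d = np.deg2rad(np.asarray(directions_deg, dtype=np.float64))
    n = d.size
    if n < 5:
        raise ValueError("Rayleigh test needs n >= 5")
    rbar = float(np.abs(np.mean(np.exp(1j * d))))
    z = n * rbar**2
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z**2) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n**2)
    )
    p = float(np.clip(p, 0.0, 1.0))
    return TestResult(statistic=float(z), p_value=p, effect_size=rbar)


def kuiper_two(directions_a, directions_b) -> TestResult:
    """Two-sample Kuiper test for a difference between circular distributions.

    V = D+ + D- (maximum positive plus maximum negative EDF difference),
    which is invariant to a common rotation of both samples; p-value from
    the asymptotic Kuiper distribution with Stephens' finite-sample
    correction.
    """
    a = np.sort(np.asarray(directions_a, dtype=np.float64) % 360.0)
    b = np.sort(np.asarray(directions_b, dtype=np.float64) % 360.0)
    n1, n2 = a.size, b.size
    if n1 < 5 or n2 < 5:
        raise ValueError("Kuiper test needs n >= 5 in both samples")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / n1
    fb = np.searchsorted(b, grid, side="right") / n2
    diff = fa - fb
    v = float(diff.max() - diff.min())
    ne = n1 * n2 / (n1 + n2)
    lam = (np.sqrt(ne) + 0.155 + 0.24 / np.sqrt(ne)) * v
    if lam < 0.4:
        p = 1.0
    else:
        k = np.arange(1, 101)
        p = float(np.sum(2.0 * (4.0 * k**2 * lam**2 - 1.0) * np.exp(-2.0 * k**2 * lam**2)))
    return TestResult(statistic=v, p_value=float(np.clip(p, 0.0, 1.0)), effect_size=v)


# ---------------------------------------------------------------------------
# Classical tests
# ---------------------------------------------------------------------------

def one_sample_t(values) -> TestResult:
    """Two-sided one-sample t-test against zero, with Cohen's D = mean/sd."""
    x = np.asarray(values, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance")
    res = sps.ttest_1samp(x, 0.0)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=float(x.mean() / sd),
        df=float(x.size - 1),
    )


def _group_arrays(values, groups):
    values = np.asarray(values, dtype=np.float64)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels = np.unique(groups)
    arrays = [values[groups == g] for g in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with n >= 2 each")
    return labels, arrays


def anova_eta(values, groups) -> TestResult:
    """One-way fixed-effects ANOVA with eta-squared effect size."""
    labels, arrays = _group_arrays(values, groups)
    res = sps.f_oneway(*arrays)
    allv = np.concatenate(arrays)
    grand = allv.mean()
    ss_total = float(((allv - grand) ** 2).sum())
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrays))
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    df = (len(arrays) - 1, allv.size - len(arrays))
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        effect_size=eta2,
        df=float(df[1]),
    )


def tukey_pairs(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise Tukey HSD comparisons.

    Returns one row per pair: mean difference (group1 - group2),
    studentized-range 95% CI and p-value, and pairwise Cohen's D
    (|mean diff| / pooled sd of the two groups).
    """
    labels, arrays = _group_arrays(values, groups)
    res = sps.tukey_hsd(*arrays)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            a, b = arrays[i], arrays[j]
            pooled = np.sqrt(
                ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
                / (a.size + b.size - 2)
            )
            diff = float(a.mean() - b.mean())
            rows.append(
                {
                    "group1": labels[i],
                    "group2": labels[j],
                    "mean_diff": diff,
                    "ci_lo": float(ci.low[i, j]),
                    "ci_hi": float(ci.high[i, j]),
                    "p_value": float(res.pvalue[i, j]),
                    "cohens_d": float(abs(diff) / pooled) if pooled > 0 else np.inf,
                }
            )
    return pd.DataFrame(rows)


def ranksum_r(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test with effect size r = |z| / sqrt(N)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.unique(np.concatenate([x, y])).size == 1:
        raise ValueError("all values tied")
    res = sps.ranksums(x, y)
    z = float(res.statistic)
    r = abs(z) / np.sqrt(x.size + y.size)
    return TestResult(statistic=z, p_value=float(res.pvalue), effect_size=float(r))


def binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson (exact) binomial confidence interval for a proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= successes <= n):
        raise ValueError("successes must be in [0, n]")
    alpha = 1.0 - level
    lo = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


# ---------------------------------------------------------------------------
# Global (whole-scene, pre-gaze) distributions
# ---------------------------------------------------------------------------

def global_distributions(dataset: list[SceneBundle], n_bins: int = N_HISTOGRAM_BINS) -> dict:
    """Pooled frequency tables of world speed, direction and distance.

    Computed on the world (pre-gaze) maps over all non-excluded pixels —
    above-threshold motion, non-sky, outside the border buffer — overall
    and split by figure/ground.  Returns ``{"tables": {...}, "medians":
    {...}, "counts": {...}}``.
    """
    pooled = {"speed": {}, "direction": {}, "distance": {}}
    for cls in ("all", "figure", "ground"):
        for feat in pooled:
            pooled[feat].setdefault(cls, [])
    for b in dataset:
        ok = ~b.buffer_mask
        motion_ok = b.valid_motion_mask & ok
        dist_ok = b.valid_distance_mask() & ok
        for cls, region in (("all", None), ("figure", b.figure_mask), ("ground", b.ground_mask)):
            m = motion_ok if region is None else motion_ok & region
            d = dist_ok if region is None else dist_ok & region
            pooled["speed"][cls].append(b.speed_map[m])
            pooled["direction"][cls].append(b.direction_map[m])
            pooled["distance"][cls].append(b.distance_map[d])
    tables, medians, counts = {}, {}, {}
    for feat in pooled:
        vals = {cls: np.concatenate(v) if v else np.array([]) for cls, v in pooled[feat].items()}
        ref = vals["all"]
        if feat == "direction":
            edges = np.linspace(0.0, 360.0, n_bins + 1)
        elif ref.size:
            edges = np.linspace(ref.min(), ref.max(), n_bins + 1)
        else:
            edges = np.linspace(0.0, 1.0, n_bins + 1)
        df = pd.DataFrame({"bin_lo": edges[:-1], "bin_hi": edges[1:]})
        for cls, v in vals.items():
            df[f"count_{cls}"] = np.histogram(v, bins=edges)[0]
            medians[f"{feat}_{cls}"] = float(np.median(v)) if v.size else np.nan
            counts[f"{feat}_{cls}"] = int(v.size)
        tables[feat] = df
    return {"tables": tables, "medians": medians, "counts": counts}


# ---------------------------------------------------------------------------
# Per-sRF feature normalization
# ---------------------------------------------------------------------------

def normalized_speed_values(speeds) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize sRF speeds to [0, 1] after a 1%-99% quantile trim.

    Returns ``(normalized, keep_mask)`` where ``keep_mask`` flags the
    surviving input entries.  Degenerate inputs (max == min after the
    trim) all map to 0.5.
    """
    v = np.asarray(speeds, dtype=np.float64)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        raise ValueError("need at least 3 valid speeds")
    q01, q99 = np.quantile(v[finite], [0.01, 0.99])
    keep = finite & (v >= q01) & (v <= q99)
    surv = v[keep]
    lo, hi = surv.min(), surv.max()
    if hi == lo:
        warnings.warn("degenerate speed range; mapping all values to 0.5")
        return np.full(surv.shape, 0.5), keep
    return (surv - lo) / (hi - lo), keep


def dominant_direction(directions_deg, n_bins: int = N_HISTOGRAM_BINS) -> float:
    """Mode of a 50-bin circular histogram (bin center; ties -> lower edge)."""
    d = np.asarray(directions_deg, dtype=np.float64) % 360.0
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts = np.histogram(d, bins=edges)[0]
    k = int(np.argmax(counts))  # argmax takes the first (lowest-edge) tie
    return float(0.5 * (edges[k] + edges[k + 1]))


def aligned_directions(directions_deg, n_bins: int = N_HISTOGRAM_BINS) -> np.ndarray:
    """Rotate directions so the sRF's dominant direction sits at 0 deg.

    Returns directions wrapped to [-180, 180).
    """
    d = np.asarray(directions_deg, dtype=np.float64)
    if d.size == 0:
        raise ValueError("need at least one direction")
    mode = dominant_direction(d, n_bins)
    return (d - mode + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# Ratio curves
# ---------------------------------------------------------------------------

def ratio_curve(
    figure_values_per_srf: list[np.ndarray],
    ground_values_per_srf: list[np.ndarray],
    bin_edges: np.ndarray,
    n_boot: int = 1000,
    rng=None,
) -> RatioCurve:
    """Figure/ground probability-ratio curve with bootstrap CIs.

    Per sRF, the feature values of the figure and ground regions are
    histogrammed on 50 shared linear bins and converted to relative
    frequencies; frequencies are averaged across sRFs, converted to
    probability densities, and the per-bin figure/ground ratio is formed.
    95% percentile-bootstrap CIs resample whole sRFs (the sRF is the
    resampling unit).  The ratio is NaN where the ground density is zero.
    """
    rng = np.random.default_rng(rng)
    pairs = [
        (f, g)
        for f, g in zip(figure_values_per_srf, ground_values_per_srf)
        if np.asarray(f).size > 0 and np.asarray(g).size > 0
    ]
    if len(pairs) < 10:
        raise ValueError("need >= 10 sRFs with both regions defined")
    edges = np.asarray(bin_edges, dtype=np.float64)
    width = edges[1] - edges[0]
    f_freq = np.stack([_rel_freq(f, edges) for f, _ in pairs])
    g_freq = np.stack([_rel_freq(g, edges) for _, g in pairs])
    n = len(pairs)

    def curve(idx):
        fd = f_freq[idx].mean(axis=0) / width
        gd = g_freq[idx].mean(axis=0) / width
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(gd > 0, fd / gd, np.nan)
        return fd, gd, r

    fd, gd, point = curve(np.arange(n))
    boots = np.empty((n_boot, len(edges) - 1))
    for i in range(n_boot):
        _, _, boots[i] = curve(rng.integers(0, n, size=n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        ci_lo = np.nanpercentile(boots, 2.5, axis=0)
        ci_hi = np.nanpercentile(boots, 97.5, axis=0)
    return RatioCurve(edges, fd, gd, point, ci_lo, ci_hi, n)


def _rel_freq(values, edges):
    counts = np.histogram(np.asarray(values, dtype=np.float64), bins=edges)[0].astype(float)
    total = counts.sum()
    return counts / total if total > 0 else counts


# ---------------------------------------------------------------------------
# Per-sRF summaries and the full differences table
# ---------------------------------------------------------------------------

def region_summary(
    srf: SRFSample,
    retinal_speed: np.ndarray,
    retinal_direction: np.ndarray,
    disparity: np.ndarray,
    valid_motion: np.ndarray,
    log_floor: float = LOG_SPEED_FLOOR,
) -> RegionSummary:
    """Summarize one sRF's figure and ground regions.

    Speed and coherence use motion-valid (above world-threshold) pixels;
    disparity uses pixels with a finite disparity.  A region with zero
    valid pixels yields NaN for the affected features.
    """
    out = {}
    for tag, (rows, cols) in (("f", srf.figure_pixels), ("g", srf.ground_pixels)):
        mv = valid_motion[rows, cols]
        sp = retinal_speed[rows, cols][mv]
        di = retinal_direction[rows, cols][mv]
        sp = sp[np.isfinite(sp)]
        di = di[np.isfinite(di)]
        out[f"s_{tag}"] = (
            float(np.mean(np.log10(np.maximum(sp, log_floor)))) if sp.size else np.nan
        )
        out[f"v_{tag}"] = circular_variance(di) if di.size else np.nan
        dsp = disparity[rows, cols]
        dsp = dsp[np.isfinite(dsp)]
        out[f"d_{tag}"] = float(dsp.mean()) if dsp.size else np.nan
        out[f"n_{tag}"] = int(sp.size)
    return RegionSummary(**out)


def srf_differences(
    dataset: list[SceneBundle],
    samples: list[SRFSample],
    log_floor: float = LOG_SPEED_FLOOR,
    with_disparity: bool = True,
) -> pd.DataFrame:
    """Per-sRF region summaries and figure-ground differences, tidy table."""
    rows = []
    cache: dict[tuple[int, tuple], tuple] = {}
    for s in samples:
        b = dataset[s.scene_index]
        key = (s.scene_index, s.gaze.fixation_pixel, s.gaze.pursuit_active)
        if key not in cache:
            rs, rd = retinal_motion(b, s.gaze)
            dm = (
                disparity_map(b, s.gaze)
                if with_disparity and np.isfinite(s.gaze.fixation_distance)
                else np.full(b.label_map.shape, np.nan)
            )
            cache[key] = (rs, rd, dm)
            if len(cache) > 64:
                cache.pop(next(iter(cache)))
        rs, rd, dm = cache[key]
        summ = region_summary(s, rs, rd, dm, b.valid_motion_mask, log_floor)
        rows.append(
            {
                "scene_index": s.scene_index,
                "diameter_deg": s.diameter_deg,
                "eccentricity_deg": s.eccentricity_deg,
                "pursuit_active": s.gaze.pursuit_active,
                "s_f": summ.s_f, "s_g": summ.s_g,
                "v_f": summ.v_f, "v_g": summ.v_g,
                "d_f": summ.d_f, "d_g": summ.d_g,
                "n_f": summ.n_f, "n_g": summ.n_g,
                "delta_s": summ.s_f - summ.s_g,
                "delta_v": summ.v_f - summ.v_g,
                "delta_d": summ.d_f - summ.d_g,
            }
        )
    return pd.DataFrame(rows)


def difference_tests(diff: pd.DataFrame) -> dict:
    """Headline tests over the per-sRF differences table.

    For each feature delta: one-sample t against zero with Cohen's D; the
    proportion of sRFs with the figure-favoring sign plus its exact 95%
    binomial CI; one-way ANOVA over the four eccentricity groups with
    eta-squared; and Tukey HSD pairwise comparisons.
    """
    out = {}
    for feat, favor_positive in (("delta_s", True), ("delta_v", False), ("delta_d", True)):
        vals = diff[feat].to_numpy()
        finite = np.isfinite(vals)
        vals_f = vals[finite]
        if vals_f.size < 2:
            # feature absent from this run (e.g. disparity in a motion-only
            # stationary-eye rerun)
            continue
        groups = diff["diameter_deg"].to_numpy()[finite]
        favored = int((vals_f > 0).sum()) if favor_positive else int((vals_f < 0).sum())
        n = int(vals_f.size)
        lo, hi = binomial_ci(favored, n)
        out[feat] = {
            "n": n,
            "mean": float(vals_f.mean()),
            "sem": float(vals_f.std(ddof=1) / np.sqrt(n)),
            "t_test": one_sample_t(vals_f),
            "proportion_favored": favored / n,
            "proportion_ci": (lo, hi),
            "anova": anova_eta(vals_f, groups),
            "tukey": tukey_pairs(vals_f, groups),
        }
    return out


def srf_ratio_curves(
    dataset: list[SceneBundle],
    samples: list[SRFSample],
    features=("rel_speed", "rel_direction", "disparity"),
    n_boot: int = 1000,
    seed: int = 0,
    log_floor: float = LOG_SPEED_FLOOR,
) -> dict[str, RatioCurve]:
    """Ratio curves for relative speed, relative direction and disparity.

    Relative speed: per-sRF speeds min-max normalized to [0, 1] after a
    1-99% quantile trim (bins on [0, 1]).  Relative direction: directions
    rotated so each sRF's dominant direction is 0 deg (bins on [-180,
    180)).  Disparity: raw degrees; shared bins span the pooled 1-99%
    range.
    """
    rng = np.random.default_rng(seed)
    per_srf: dict[str, tuple[list, list]] = {f: ([], []) for f in features}
    pooled_disp: list[np.ndarray] = []
    extracted = []
    cache: dict[tuple, tuple] = {}
    for s in samples:
        b = dataset[s.scene_index]
        key = (s.scene_index, s.gaze.fixation_pixel, s.gaze.pursuit_active)
        if key not in cache:
            rs, rd = retinal_motion(b, s.gaze)
            dm = (
                disparity_map(b, s.gaze)
                if np.isfinite(s.gaze.fixation_distance)
                else np.full(b.label_map.shape, np.nan)
            )
            cache[key] = (rs, rd, dm)
            if len(cache) > 64:
                cache.pop(next(iter(cache)))
        rs, rd, dm = cache[key]
        fr, fc = s.figure_pixels
        gr, gc = s.ground_pixels
        fm = b.valid_motion_mask[fr, fc]
        gm = b.valid_motion_mask[gr, gc]
        rec = {
            "speed_f": rs[fr, fc][fm], "speed_g": rs[gr, gc][gm],
            "dir_f": rd[fr, fc][fm], "dir_g": rd[gr, gc][gm],
            "disp_f": dm[fr, fc], "disp_g": dm[gr, gc],
        }
        extracted.append(rec)
        if "disparity" in features:
            pooled_disp.append(rec["disp_f"][np.isfinite(rec["disp_f"])])
            pooled_disp.append(rec["disp_g"][np.isfinite(rec["disp_g"])])

    for rec in extracted:
        if "rel_speed" in features:
            allsp = np.concatenate([rec["speed_f"], rec["speed_g"]])
            allsp = allsp[np.isfinite(allsp)]
            nf = rec["speed_f"].size
            if allsp.size >= 3:
                norm, keep = normalized_speed_values(
                    np.concatenate([rec["speed_f"], rec["speed_g"]])
                )
                kf, kg = keep[:nf], keep[nf:]
                per_srf["rel_speed"][0].append(norm[: int(kf.sum())])
                per_srf["rel_speed"][1].append(norm[int(kf.sum()):])
            else:
                per_srf["rel_speed"][0].append(np.array([]))
                per_srf["rel_speed"][1].append(np.array([]))
        if "rel_direction" in features:
            alld = np.concatenate([rec["dir_f"], rec["dir_g"]])
            alld = alld[np.isfinite(alld)]
            if alld.size:
                mode = dominant_direction(alld)
                rot_f = (rec["dir_f"] - mode + 180.0) % 360.0 - 180.0
                rot_g = (rec["dir_g"] - mode + 180.0) % 360.0 - 180.0
            else:
                rot_f = rot_g = np.array([])
            per_srf["rel_direction"][0].append(rot_f)
            per_srf["rel_direction"][1].append(rot_g)
        if "disparity" in features:
            per_srf["disparity"][0].append(rec["disp_f"][np.isfinite(rec["disp_f"])])
            per_srf["disparity"][1].append(rec["disp_g"][np.isfinite(rec["disp_g"])])

    edges = {
        "rel_speed": np.linspace(0.0, 1.0, N_HISTOGRAM_BINS + 1),
        "rel_direction": np.linspace(-180.0, 180.0, N_HISTOGRAM_BINS + 1),
    }
    if "disparity" in features:
        disp_all = np.concatenate(pooled_disp) if pooled_disp else np.array([0.0, 1.0])
        lo, hi = np.quantile(disp_all, [0.01, 0.99])
        if hi <= lo:
            lo, hi = lo - 0.5, hi + 0.5
        edges["disparity"] = np.linspace(lo, hi, N_HISTOGRAM_BINS + 1)

    curves = {}
    for f in features:
        fig_vals, gnd_vals = per_srf[f]
        curves[f] = ratio_curve(
            fig_vals, gnd_vals, edges[f], n_boot=n_boot,
            rng=rng.integers(0, 2**31 - 1),
        )
    return curves
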