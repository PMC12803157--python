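"""Manders colocalization for two-channel images, plus group statistics.

The Manders coefficients quantify, intensity-weighted, how much of one
channel's signal lies in pixels where the other channel is above
threshold.  M1 is the fraction of channel-1 intensity (over its own
above-threshold pixels) found where channel 2 is on; M2 is the
symmetric counterpart.  Thresholds default to per-channel Otsu.

Group comparisons mirror common microscopy practice: Welch's unequal-
variance t-test for two groups and one-way ANOVA with Tukey HSD for
several.
"""

from __future__ import annotations

from dataclasses import dataclass

from pathlib import Path

import numpy as np
import tifffile
from scipy import stats


class ImageError(ValueError):
    """Raised for unusable images or undefined coefficients."""


@dataclass(frozen=True)
class ColocResult:
    m1: float
    m2: float
    threshold1: float
    threshold2: float
    n_pixels: int


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float


@dataclass(frozen=True)
class AnovaTukeyResult:
    f: float
    df_between: int
    df_within: int
    p: float
    pairwise_p: np.ndarray  # symmetric matrix of Tukey-adjusted p values


def otsu_threshold(channel: np.ndarray) -> float:
    """Otsu's threshold on a 256-bin histogram of the channel.

    Maximises the between-class variance; when several cut points tie
    (e.g. an empty histogram gap between two well-separated modes) the
    tying bin centres are averaged, placing the threshold mid-gap
    rather than at the gap's lower edge.
    """
    ch = np.asarray(channel, dtype=float)
    if np.unique(ch).size < 2:
        raise ImageError("constant image: Otsu threshold undefined")
    counts, edges = np.histogram(ch.ravel(), bins=256)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = counts.astype(float)
    p = w / w.sum()
    omega1 = np.cumsum(p)[:-1]
    omega2 = 1.0 - omega1
    mu = np.cumsum(p * centers)
    mu_total = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu1 = mu[:-1] / omega1
        mu2 = (mu_total - mu[:-1]) / omega2
        sigma_b = omega1 * omega2 * (mu1 - mu2) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-np.inf)
    best = sigma_b.max()
    ties = np.nonzero(sigma_b >= best * (1.0 - 1e-12))[0]
    return float(centers[ties].mean())


def manders(
    ch1: np.ndarray,
    ch2: np.ndarray,
    thr1: float,
    thr2: float,
) -> ColocResult:
    """Intensity-weighted Manders overlap coefficients M1 and M2.

    M1 = Σ ch1 over pixels with ch2 > thr2 (restricted to pixels with
    ch1 > thr1), divided by Σ ch1 over pixels with ch1 > thr1; M2 is
    symmetric.  Scaling either channel by a positive constant leaves
    both coefficients unchanged provided the threshold scales with it.
    """
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ImageError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if thr1 < 0 or thr2 < 0:
        raise ImageError("thresholds must be non-negative")
    on1 = a > thr1
    on2 = b > thr2
    denom1 = a[on1].sum()
    denom2 = b[on2].sum()
    if denom1 == 0 or denom2 == 0:
        raise ImageError("no above-threshold signal; coefficients undefined")
    m1 = a[on1 & on2].sum() / denom1
    m2 = b[on1 & on2].sum() / denom2
    return ColocResult(
        m1=float(m1),
        m2=float(m2),
        threshold1=float(thr1),
        threshold2=float(thr2),
        n_pixels=int(a.size),
    )


def read_channel(path: str | Path) -> np.ndarray:
    """Load a single-plane channel image (TIFF) as a float array."""
    arr = np.asarray(tifffile.imread(path), dtype=float)
    if arr.ndim != 2:
        raise ImageError(f"{path}: expected a single 2-D plane, got shape {arr.shape}")
    return arr


def write_channel(path: str | Path, channel: np.ndarray) -> None:
    """Write a channel as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(channel, dtype=np.float32))


def manders_otsu(ch1: np.ndarray, ch2: np.ndarray) -> ColocResult:
    """Manders coefficients with per-channel Otsu thresholds."""
    return manders(ch1, ch2, otsu_threshold(ch1), otsu_threshold(ch2))


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance two-sided t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return WelchResult(t=0.0, df=float(a.size + b.size - 2), p=1.0)
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def anova_tukey(groups) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    n_total = sum(a.size for a in arrs)
    df_between = len(arrs) - 1
    df_within = n_total - len(arrs)
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        return AnovaTukeyResult(
            f=0.0,
            df_between=df_between,
            df_within=df_within,
            p=1.0,
            pairwise_p=np.ones((len(arrs), len(arrs))),
        )
    f_res = stats.f_oneway(*arrs)
    hsd = stats.tukey_hsd(*arrs)
    return AnovaTukeyResult(
        f=float(f_res.statistic),
        df_between=df_between,
        df_within=df_within,
        p=float(f_res.pvalue),
        pairwise_p=np.asarray(hsd.pvalue),
    )
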