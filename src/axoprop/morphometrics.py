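"""Morphometric computations for tail growth and growth-plate histology.

Vertebral diaphysis lengths are measured from 1D µCT intensity profiles
drawn along the tail axis: each ossified centrum appears as a supra-threshold
plateau, and its length is the distance between the half-height crossings of
the leading and trailing edges (with linear sub-pixel interpolation),
converted to µm with the effective pixel size ``voxel × resize``. The growth
plates and epiphyses are excluded by construction because only the
mineralized diaphysis rises above threshold.

Also implemented: body-length normalization and weekly growth-dynamics
matrices, calcein pulse-chase elongation rates, the EdU proliferative index,
hypertrophic-cell height summaries, and Welch's unequal-variances t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _defaults as dflt


@dataclass
class IntensityProfile:
    """A 1D intensity profile with its pixel geometry."""

    values: np.ndarray
    voxel: float = dflt.VOXEL_UM
    resize: int = dflt.RESIZE

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) < 10:
            raise ValueError("profile must have >= 10 samples")
        if self.voxel * self.resize <= 0:
            raise ValueError("effective pixel must be > 0")

    @property
    def pixel_um(self) -> float:
        return self.voxel * self.resize

    @classmethod
    def from_csv(cls, path, voxel: float = dflt.VOXEL_UM,
                 resize: int = dflt.RESIZE) -> "IntensityProfile":
        df = pd.read_csv(path)
        return cls(df["intensity"].to_numpy(dtype=float), voxel, resize)


# ---------------------------------------------------------------------------
# element segmentation
# ---------------------------------------------------------------------------

def _smooth3(values: np.ndarray) -> np.ndarray:
    """Centered 3-pixel moving average with edge replication."""
    padded = np.pad(values, 1, mode="edge")
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0


def segment_elements(profile: IntensityProfile | np.ndarray,
                     smooth: bool = False,
                     min_gap: int = 2) -> list[tuple[int, int]]:
    """Find vertebral elements as supra-threshold runs of the profile.

    The threshold is the half-range ``(min + max) / 2`` of the (optionally
    3-px smoothed) profile. Maximal runs strictly above threshold are
    reported as half-open pixel intervals ``[start, end)``, ordered cranial
    to caudal (TV1 first); runs separated by sub-threshold gaps shorter than
    ``min_gap`` pixels are merged.
    """
    values = (profile.values if isinstance(profile, IntensityProfile)
              else np.asarray(profile, dtype=float))
    work = _smooth3(values) if smooth else values
    thr = 0.5 * (work.min() + work.max())
    above = work > thr
    if not above.any():
        raise ValueError("no supra-threshold run: flat or empty profile")

    edges = np.flatnonzero(np.diff(above.astype(np.int8)))
    starts = list(edges[~above[edges]] + 1)
    ends = list(edges[above[edges]] + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(values))

    merged: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


# ---------------------------------------------------------------------------
# diaphysis length
# ---------------------------------------------------------------------------

def _cross_left(values: np.ndarray, start: int, thr: float,
                lo_bound: int) -> float:
    """Sub-pixel position where the rising edge crosses ``thr``."""
    i = start
    while i - 1 >= lo_bound and values[i - 1] > thr:
        i -= 1
    # walk outward to the first sample at or below threshold
    j = i - 1
    while j >= lo_bound and values[j] > thr:
        j -= 1
    if j < lo_bound:
        return float(lo_bound)
    if values[j] == thr:
        return float(j)
    return j + (thr - values[j]) / (values[j + 1] - values[j])


def _cross_right(values: np.ndarray, end: int, thr: float,
                 hi_bound: int) -> float:
    """Sub-pixel position where the falling edge crosses ``thr``."""
    j = end
    while j <= hi_bound and values[j] > thr:
        j += 1
    if j > hi_bound:
        return float(hi_bound)
    if values[j] == thr:
        return float(j)
    return j - 1 + (values[j - 1] - thr) / (values[j - 1] - values[j])


def measure_diaphysis_length(profile: IntensityProfile,
                             interval: tuple[int, int],
                             window: tuple[int, int] | None = None) -> float:
    """Length (µm) of one element by the half-height midpoint rule.

    A local minimum m and maximum M are taken over a window spanning the
    element plus its flanking gaps (to the neighboring elements or profile
    ends); the element begins at the interpolated crossing of ``(m + M)/2``
    on the leading rising edge and ends at the crossing on the trailing
    falling edge. Length is the crossing distance times the effective pixel.
    """
    values = profile.values
    start, end = interval
    if not (0 <= start < end <= len(values)):
        raise ValueError("interval outside profile")
    if window is None:
        glob_thr = 0.5 * (values.min() + values.max())
        w0 = start
        while w0 > 0 and values[w0 - 1] <= glob_thr:
            w0 -= 1
        w1 = end - 1
        while w1 < len(values) - 1 and values[w1 + 1] <= glob_thr:
            w1 += 1
    else:
        w0, w1 = window
    m = values[w0:w1 + 1].min()
    M = values[w0:w1 + 1].max()
    if M <= m:
        raise ValueError("no contrast in measurement window")
    thr = 0.5 * (m + M)
    left = _cross_left(values, start, thr, w0)
    right = _cross_right(values, end - 1, thr, w1)
    return (right - left) * profile.pixel_um


def measure_profile(profile: IntensityProfile, smooth: bool = False
                    ) -> pd.DataFrame:
    """Segment a profile and measure every element.

    Returns one row per element: ``vertebra`` (TV index, 1-based),
    ``start_px``, ``end_px``, ``length_um``.
    """
    intervals = segment_elements(profile, smooth=smooth)
    rows = []
    for k, iv in enumerate(intervals):
        rows.append({"vertebra": k + 1, "start_px": iv[0], "end_px": iv[1],
                     "length_um": measure_diaphysis_length(profile, iv)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proportions and growth dynamics
# ---------------------------------------------------------------------------

def normalize_to_body(lengths, naso_anal: float,
                      gaps=None) -> tuple[np.ndarray, float]:
    """Normalize vertebral lengths to the animal's naso-anal distance.

    Returns ``(per-vertebra proportions, tail:body ratio)``; the ratio sums
    the vertebral lengths (plus inter-vertebral gaps when provided) over the
    naso-anal length.
    """
    if naso_anal <= 0:
        raise ValueError("naso_anal must be > 0")
    lengths = np.asarray(lengths, dtype=float)
    props = lengths / naso_anal
    total = lengths.sum()
    if gaps is not None:
        total += np.asarray(gaps, dtype=float).sum()
    return props, float(total / naso_anal)


def tail_body_ratio(series: pd.DataFrame, time_days: float) -> float:
    """Mean tail:body ratio across animals at one timepoint of a tidy
    length series (columns ``animal, time_days, vertebra, length_um,
    naso_anal_um``)."""
    sub = series[series["time_days"] == time_days]
    if sub.empty:
        raise ValueError(f"no rows at time_days={time_days}")
    ratios = []
    for _, grp in sub.groupby("animal"):
        _, r = normalize_to_body(grp["length_um"].to_numpy(),
                                 float(grp["naso_anal_um"].iloc[0]))
        ratios.append(r)
    return float(np.mean(ratios))


def weekly_relative_change(series: pd.DataFrame,
                           rate: bool = False) -> pd.DataFrame:
    """Change matrix of normalized vertebral lengths between consecutive
    timepoints.

    Per-timepoint animal means of ``length/naso_anal`` are computed first;
    the matrix entry for vertebra i and interval (t_k, t_{k+1}) is
    ``mean_i(t_{k+1}) - mean_i(t_k)`` (divided by the interval length in
    weeks when ``rate=True``). Rows are vertebrae, columns are intervals
    labeled ``"t0-t1"``.
    """
    df = series.copy()
    df["norm"] = df["length_um"] / df["naso_anal_um"]
    mean = (df.groupby(["vertebra", "time_days"])["norm"].mean()
            .unstack("time_days").sort_index(axis=1))
    times = mean.columns.to_numpy(dtype=float)
    if len(times) < 2:
        raise ValueError("need >= 2 timepoints")
    if np.any(np.diff(times) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    out = {}
    for k in range(len(times) - 1):
        delta = mean.iloc[:, k + 1] - mean.iloc[:, k]
        if rate:
            delta = delta / ((times[k + 1] - times[k]) / 7.0)
        out[f"{times[k]:g}-{times[k + 1]:g}"] = delta
    return pd.DataFrame(out, index=mean.index)


def peak_vertebra(change_matrix: pd.DataFrame,
                  window=None) -> tuple[int, bool]:
    """Vertebra with the greatest summed change over a window of intervals.

    ``window`` selects columns (default: all). Ties are broken toward the
    smaller index and flagged. Returns ``(vertebra_index, tied)``.
    """
    cols = list(change_matrix.columns) if window is None else list(window)
    if not cols:
        raise ValueError("empty window")
    total = change_matrix[cols].sum(axis=1)
    best = total.max()
    tied_idx = total.index[total == best]
    return int(tied_idx.min()), bool(len(tied_idx) > 1)


# ---------------------------------------------------------------------------
# growth-plate quantities
# ---------------------------------------------------------------------------

def calcein_growth_rate(distance_um: float,
                        elapsed_hours: float = dflt.CALCEIN_HOURS) -> float:
    """Daily elongation rate from a calcein pulse-chase distance.

    ``rate = distance / (elapsed_hours / 24)`` µm/day; for the standard
    48-hour chase this is the labeled distance divided by two.
    """
    if elapsed_hours <= 0:
        raise ValueError("elapsed_hours must be > 0")
    if distance_um < 0:
        raise ValueError("distance must be >= 0")
    return distance_um / (elapsed_hours / 24.0)


def proliferative_index(table: pd.DataFrame) -> pd.Series:
    """Per-specimen EdU proliferative index.

    Each section contributes ``edu_positive / edu_total``; the specimen
    value is the mean across its sections (sections → specimen averaging
    order).
    """
    if (table["edu_total"] <= 0).any():
        raise ValueError("section with zero cells")
    frac = table["edu_positive"] / table["edu_total"]
    return frac.groupby(table["specimen"]).mean().rename("proliferative_index")


def max_hypertrophic_height(cells: pd.DataFrame, top: int = 3) -> pd.Series:
    """Per-specimen mean maximum hypertrophic cell height.

    Per section, the mean of the ``top`` largest cell heights; per specimen,
    the mean across sections. Requires >= ``top`` cells in every section.
    """
    def _section_top(heights: pd.Series) -> float:
        if len(heights) < top:
            raise ValueError(f"section with < {top} cells")
        return float(np.sort(heights.to_numpy())[-top:].mean())

    per_section = cells.groupby(["specimen", "section"])["cell_height_um"] \
        .apply(_section_top)
    return per_section.groupby("specimen").mean() \
        .rename("max_hypertrophic_height_um")


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch's unequal-variances t-test, two-tailed.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom.
    Undefined when both groups have zero variance and equal means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            raise ValueError("undefined t: zero variance and equal means")
        return (np.inf if a.mean() > b.mean() else -np.inf, float(
            len(a) + len(b) - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
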