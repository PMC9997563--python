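"""Group-level behavioral statistics.

Cohorts are compared on the two interval measures (distance traveled and
food-interaction fraction) with two-sided unpaired Mann-Whitney rank-sum
tests run in 10-minute windows of the session (defaults 15-25, 25-35,
35-45, 45-55 min, half-open), followed by Benjamini-Hochberg step-up
adjustment across the windows of one comparison.  Trend curves for
plotting are locally weighted regressions (lowess) with a default
smoothing span of 0.25.

The unit of analysis defaults to the fly: each fly's raw per-frame
measure is pooled into one per-fly mean per window before ranking, which
avoids pseudo-replicating thousands of correlated frames.  A per-frame
mode is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.nonparametric.smoothers_lowess import lowess

#: Default 10-min test windows in minutes, half-open [start, end).
DEFAULT_WINDOWS_MIN: tuple[tuple[float, float], ...] = (
    (15.0, 25.0),
    (25.0, 35.0),
    (35.0, 45.0),
    (45.0, 55.0),
)
DEFAULT_SPAN = 0.25
EXACT_MAX_N = 12  # exact null enumeration up to this combined sample size


@dataclass(frozen=True)
class TrendCurve:
    """Lowess-smoothed trend on a regular time grid."""

    time_min: np.ndarray
    value: np.ndarray
    span: float


def smooth_trend(
    time: Sequence[float],
    value: Sequence[float],
    span: float = DEFAULT_SPAN,
    grid_points: int = 200,
) -> TrendCurve:
    """Locally weighted linear regression of value on time.

    ``span`` is the fraction of the data used for each local fit
    (default 0.25).  The curve is evaluated on a regular grid spanning the
    observed time range.
    """
    t = np.asarray(time, dtype=np.float64)
    v = np.asarray(value, dtype=np.float64)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("time and value must be equal-length 1-D sequences")
    if len(t) < 10:
        raise ValueError(f"need >= 10 points for trend smoothing, got {len(t)}")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    grid = np.linspace(t.min(), t.max(), grid_points)
    fitted = lowess(v, t, frac=span, xvals=grid)
    return TrendCurve(grid, np.asarray(fitted, dtype=np.float64), span)


def rank_sum_test(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["auto", "exact", "approximate"] = "auto",
) -> tuple[float, float]:
    """Two-sided unpaired Mann-Whitney U test; returns (U of x, p).

    ``auto`` uses exact null enumeration when n1 + n2 <= 12 and the pooled
    sample has no ties, otherwise the normal approximation with tie and
    continuity corrections.  Identical constant samples give p = 1.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([xa, ya])
    has_ties = len(np.unique(pooled)) < pooled.size
    if mode == "exact" or (mode == "auto" and xa.size + ya.size <= EXACT_MAX_N and not has_ties):
        method = "exact"
    elif mode in ("approximate", "auto"):
        method = "asymptotic"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if has_ties and np.ptp(pooled) == 0:
        # all observations identical: no evidence of shift
        return float(xa.size * ya.size / 2.0), 1.0
    res = sps.mannwhitneyu(
        xa, ya, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    p_adj for the i-th smallest p is min over j >= i of (m/j) p_(j),
    capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass
class GroupedSeries:
    """Per-frame measures for one cohort of flies.

    ``per_fly`` maps a fly/well identifier to a 1-D array of its raw
    per-frame measure values; ``fps`` converts frame index to minutes.
    ``key`` carries the grouping metadata (sex, pretreatment, diet).
    """

    key: tuple
    per_fly: dict[str, np.ndarray]
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.per_fly = {k: np.asarray(v, dtype=np.float64) for k, v in self.per_fly.items()}
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    def window_values(
        self,
        start_min: float,
        end_min: float,
        unit: Literal["per_fly", "per_frame"] = "per_fly",
    ) -> np.ndarray:
        """Measure values falling in [start_min, end_min).

        ``per_fly`` returns one mean per fly over the window's frames
        (flies with no frames in the window are omitted); ``per_frame``
        pools the raw frames of all flies.
        """
        i0 = int(np.ceil(start_min * 60.0 * self.fps))
        i1 = int(np.ceil(end_min * 60.0 * self.fps))
        chunks = []
        for _, v in sorted(self.per_fly.items()):
            seg = v[i0:i1]
            if seg.size == 0:
                continue
            chunks.append(seg.mean() if unit == "per_fly" else seg)
        if not chunks:
            return np.zeros(0)
        return np.array(chunks) if unit == "per_fly" else np.concatenate(chunks)


@dataclass(frozen=True)
class WindowTestResult:
    window: tuple[float, float]
    n1: int
    n2: int
    statistic: Optional[float]
    p_raw: Optional[float]
    p_adj: Optional[float] = None
    missing: bool = False


def windowed_tests(
    a: GroupedSeries,
    b: GroupedSeries,
    windows: Sequence[tuple[float, float]] = DEFAULT_WINDOWS_MIN,
    unit: Literal["per_fly", "per_frame"] = "per_fly",
    mode: Literal["auto", "exact", "approximate"] = "auto",
) -> list[WindowTestResult]:
    """Mann-Whitney tests per window with BH adjustment across windows.

    A window where either group has no data is reported with
    ``missing=True`` (never silently dropped) and excluded from the BH
    family; the family is the tested windows of this one comparison.
    """
    results: list[WindowTestResult] = []
    for w in windows:
        xa = a.window_values(*w, unit=unit)
        xb = b.window_values(*w, unit=unit)
        if xa.size == 0 or xb.size == 0:
            results.append(WindowTestResult(tuple(w), xa.size, xb.size, None, None, missing=True))
            continue
        u, p = rank_sum_test(xa, xb, mode=mode)
        results.append(WindowTestResult(tuple(w), xa.size, xb.size, u, p))
    tested = [r for r in results if not r.missing]
    if tested:
        adj = bh_adjust([r.p_raw for r in tested])
        adj_iter = iter(adj)
        results = [
            r
            if r.missing
            else WindowTestResult(r.window, r.n1, r.n2, r.statistic, r.p_raw, float(next(adj_iter)))
            for r in results
        ]
    return results


def results_to_frame(
    results: Sequence[WindowTestResult],
    measure: str,
    comparison: str,
) -> pd.DataFrame:
    """CSV schema: measure,comparison,window_start_min,window_end_min,n1,n2,U,p_raw,p_adj."""
    rows = [
        {
            "measure": measure,
            "comparison": comparison,
            "window_start_min": r.window[0],
            "window_end_min": r.window[1],
            "n1": r.n1,
            "n2": r.n2,
            "U": r.statistic,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "measure", "comparison", "window_start_min", "window_end_min",
            "n1", "n2", "U", "p_raw", "p_adj",
        ],
    )
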