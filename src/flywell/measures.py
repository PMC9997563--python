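"""Per-frame behavioral measures and 2-minute interval summaries.

Two measures are computed from each fly silhouette and its centroid:

* **food-interaction flag** — 1 when the silhouette is fully enclosed in
  the food-circle region (every silhouette pixel within ``radius_px`` of
  the circle center, Euclidean), else 0;
* **inter-frame distance** — Euclidean distance (pixels) between the
  silhouette centroid in the current frame and in the previous frame.

Raw per-frame streams are aggregated into nonoverlapping 2-min intervals
aligned to frame 0: the food fraction (proportion of flagged frames) and
the cumulative inter-frame distance per interval.

Missing detections contribute flag 0 and distance 0 but stay in the
interval denominator, keeping n_frames comparable across wells; the gap
count is carried on the series for auditing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .arena import FoodCircle, PixelPoint
from .detect import Component, DetectionRecord

DEFAULT_INTERVAL_S = 120.0


def food_interaction_flag(
    silhouette: Optional[Component], circle: FoodCircle
) -> int:
    """1 iff every silhouette pixel lies within the food circle; 0 otherwise.

    Enclosure is strict per-pixel — a single pixel outside the radius means
    flag 0 — and an absent silhouette scores 0.
    """
    if silhouette is None:
        return 0
    cx, cy = circle.center.x, circle.center.y
    r2 = circle.radius_px * circle.radius_px
    for x, y in silhouette.pixel_set:
        if (x - cx) ** 2 + (y - cy) ** 2 > r2:
            return 0
    return 1


def interframe_distance(
    prev: Optional[PixelPoint], cur: Optional[PixelPoint]
) -> float:
    """Euclidean centroid displacement; 0.0 when either centroid is absent."""
    if prev is None or cur is None:
        return 0.0
    return math.hypot(cur.x - prev.x, cur.y - prev.y)


@dataclass
class WellTimeSeries:
    """Per-frame measure streams for one well, contiguous from frame 0."""

    well_id: str
    fps: float
    food_flag: np.ndarray  # int {0,1}, len n_frames
    distance_px: np.ndarray  # float >= 0, distance into each frame
    found: np.ndarray  # bool
    n_gaps: int = 0

    def __post_init__(self) -> None:
        self.food_flag = np.asarray(self.food_flag, dtype=np.int8)
        self.distance_px = np.asarray(self.distance_px, dtype=np.float64)
        self.found = np.asarray(self.found, dtype=bool)
        if not (len(self.food_flag) == len(self.distance_px) == len(self.found)):
            raise ValueError("measure streams must have equal length")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    def __len__(self) -> int:
        return len(self.food_flag)


def build_series(
    records: Sequence[DetectionRecord], circle: FoodCircle, fps: float
) -> WellTimeSeries:
    """Compute both per-frame measures from a contiguous detection stream.

    Records must be ordered by frame index starting at 0.  Frames around a
    lost detection contribute distance 0 (the gap is counted, not
    interpolated).
    """
    flags = np.zeros(len(records), dtype=np.int8)
    dists = np.zeros(len(records), dtype=np.float64)
    found = np.zeros(len(records), dtype=bool)
    n_gaps = 0
    prev: Optional[PixelPoint] = None
    for i, rec in enumerate(records):
        if rec.frame_index != i:
            raise ValueError(
                f"records must be contiguous from 0; frame {rec.frame_index} at position {i}"
            )
        if rec.found:
            sil = (
                Component(rec.pixel_set, rec.area_px, rec.centroid)
                if rec.pixel_set is not None
                else None
            )
            if sil is not None:
                flags[i] = food_interaction_flag(sil, circle)
            else:
                # pixel set not retained: fall back to centroid-distance test
                flags[i] = int(circle.encloses(rec.centroid))
            found[i] = True
            cur = rec.centroid
        else:
            cur = None
        if i > 0 and (prev is None or cur is None) and not (prev is None and cur is None):
            n_gaps += 1
        dists[i] = interframe_distance(prev, cur)
        prev = cur
    well_id = records[0].well_id if records else ""
    return WellTimeSeries(well_id, fps, flags, dists, found, n_gaps=n_gaps)


@dataclass(frozen=True)
class IntervalSummary:
    """One nonoverlapping aggregation interval (default 2 min)."""

    interval_index: int
    start_s: float
    n_frames: int
    food_fraction: float
    distance_px: float
    partial: bool = False


def summarize_intervals(
    series: WellTimeSeries, interval_s: float = DEFAULT_INTERVAL_S
) -> list[IntervalSummary]:
    """Aggregate per-frame measures into nonoverlapping intervals.

    Intervals are aligned to frame 0; a trailing interval shorter than
    ``interval_s`` is emitted with its true n_frames and ``partial=True``.
    The distance assigned to an interval is the sum of inter-frame
    distances whose *current* frame falls in the interval.
    """
    n = len(series)
    if n == 0:
        return []
    frames_per = int(round(interval_s * series.fps))
    if frames_per <= 0:
        raise ValueError("interval shorter than one frame")
    out: list[IntervalSummary] = []
    for k, start in enumerate(range(0, n, frames_per)):
        stop = min(start + frames_per, n)
        nf = stop - start
        out.append(
            IntervalSummary(
                interval_index=k,
                start_s=start / series.fps,
                n_frames=nf,
                food_fraction=float(series.food_flag[start:stop].mean()),
                distance_px=float(series.distance_px[start:stop].sum()),
                partial=nf < frames_per,
            )
        )
    return out


def summaries_to_frame(
    per_well: dict[str, list[IntervalSummary]]
) -> pd.DataFrame:
    """CSV schema: well,interval,start_s,n_frames,food_fraction,distance_px,partial."""
    rows = [
        {
            "well": wid,
            "interval": s.interval_index,
            "start_s": s.start_s,
            "n_frames": s.n_frames,
            "food_fraction": s.food_fraction,
            "distance_px": s.distance_px,
            "partial": s.partial,
        }
        for wid in sorted(per_well)
        for s in per_well[wid]
    ]
    return pd.DataFrame(
        rows,
        columns=["well", "interval", "start_s", "n_frames", "food_fraction", "distance_px", "partial"],
    )


def normalize_distances(
    per_fly: dict[str, Sequence[float]],
    scope: Literal["global", "per_fly"] = "global",
) -> dict[str, np.ndarray]:
    """Scale per-interval distances into relative units in [0, 1].

    ``global`` (default) divides every value by the maximum per-interval
    distance across the whole compared set, so exactly one interval maps
    to 1; ``per_fly`` normalizes each fly by its own maximum.  All-zero
    inputs are returned unchanged (no division).
    """
    arrays = {k: np.asarray(v, dtype=np.float64) for k, v in per_fly.items()}
    for k, a in arrays.items():
        if (a < 0).any():
            raise ValueError(f"negative distance for {k}")
    if scope == "global":
        gmax = max((a.max() for a in arrays.values() if a.size), default=0.0)
        if gmax == 0.0:
            return arrays
        return {k: a / gmax for k, a in arrays.items()}
    if scope == "per_fly":
        out = {}
        for k, a in arrays.items():
            m = a.max() if a.size else 0.0
            out[k] = a / m if m > 0 else a
        return out
    raise ValueError(f"unknown scope {scope!r}")
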