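"""Feeding-bout extraction: run-length encoding and flag denoising.

The per-frame food-interaction stream is noisy at the frame scale: a
feeding fly briefly breaks the enclosure test, and a passing fly briefly
satisfies it.  Fly feeding microstructure sets the denoising scale: a
starved fly takes about 7 sips per feeding burst at about 0.13 s per sip,
i.e. 0.91 s per burst, which at 30 fps is 27.3 frames.  Runs of flagged
frames shorter than 27 frames are therefore too short to be a feeding
burst, and gaps shorter than 10 frames are too short to be a real
departure from the food.

``denoise_flags`` applies two deterministic passes, once each:

1. **gap closing** — every 0-run shorter than ``min_off_frames`` lying
   between two 1-runs is flipped to 1 (bursts interrupted by a blink are
   rejoined first);
2. **short-run removal** — every remaining 1-run shorter than
   ``min_on_frames`` is flipped to 0.

A single application already leaves no interior 0-run below the off
threshold and no 1-run below the on threshold, so the operation is
idempotent.  Leading/trailing 0-runs are never flipped (no bracketing
1-run on one side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_FPS = 30.0
DEFAULT_SIPS_PER_BURST = 7
DEFAULT_SIP_DURATION_S = 0.13
DEFAULT_MIN_OFF_FRAMES = 10


def burst_frame_threshold(
    sips: float = DEFAULT_SIPS_PER_BURST,
    sip_s: float = DEFAULT_SIP_DURATION_S,
    fps: float = DEFAULT_FPS,
) -> float:
    """Frames spanned by one feeding burst: fps x sips x sip duration.

    With the defaults (7 sips x 0.13 s at 30 fps) this is 27.3 frames; the
    integer threshold used downstream is its floor, 27.
    """
    if sips < 0 or sip_s < 0 or fps < 0:
        raise ValueError("burst parameters must be nonnegative")
    return fps * sips * sip_s


@dataclass(frozen=True)
class BoutParams:
    """Thresholds for feeding-bout denoising.

    ``min_on_frames`` defaults to floor(fps x sips_per_burst x
    sip_duration_s) = 27 at the standard parameters; ``min_off_frames``
    defaults to 10.
    """

    sips_per_burst: float = DEFAULT_SIPS_PER_BURST
    sip_duration_s: float = DEFAULT_SIP_DURATION_S
    fps: float = DEFAULT_FPS
    min_on_frames: int = None  # type: ignore[assignment]
    min_off_frames: int = DEFAULT_MIN_OFF_FRAMES

    def __post_init__(self) -> None:
        if self.min_on_frames is None:
            object.__setattr__(
                self,
                "min_on_frames",
                int(math.floor(burst_frame_threshold(self.sips_per_burst, self.sip_duration_s, self.fps))),
            )
        if self.min_on_frames <= 0 or self.min_off_frames <= 0 or self.fps <= 0:
            raise ValueError("bout thresholds and fps must be positive")


@dataclass(frozen=True)
class Run:
    """A maximal run of identical flag values."""

    state: int
    start_frame: int
    length_frames: int

    def __post_init__(self) -> None:
        if self.state not in (0, 1):
            raise ValueError("run state must be 0 or 1")
        if self.length_frames < 1:
            raise ValueError("run length must be >= 1")


def _as_flags(series: Sequence[int] | np.ndarray) -> np.ndarray:
    a = np.asarray(series, dtype=np.int8)
    if a.ndim != 1:
        raise ValueError("flag series must be 1-D")
    if a.size and not np.isin(a, (0, 1)).all():
        raise ValueError("flags must be binary")
    return a


def run_length_encode(series: Sequence[int] | np.ndarray) -> list[Run]:
    """Maximal alternating runs covering the series; empty series -> []."""
    a = _as_flags(series)
    if a.size == 0:
        return []
    change = np.flatnonzero(np.diff(a)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [a.size]))
    return [Run(int(a[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def run_length_decode(runs: Sequence[Run]) -> np.ndarray:
    """Inverse of :func:`run_length_encode`."""
    if not runs:
        return np.zeros(0, dtype=np.int8)
    return np.concatenate([np.full(r.length_frames, r.state, dtype=np.int8) for r in runs])


def denoise_flags(
    series: Sequence[int] | np.ndarray, params: BoutParams | None = None
) -> np.ndarray:
    """Two-pass noise removal merging flags into feeding / non-feeding blocks.

    Pass 1 closes interior 0-gaps shorter than ``min_off_frames``; pass 2
    removes 1-runs shorter than ``min_on_frames``.  The output satisfies
    both run-length constraints and the operation is idempotent.
    """
    params = params or BoutParams()
    a = _as_flags(series).copy()
    if a.size == 0:
        return a
    # pass 1: gap closing (interior 0-runs only)
    runs = run_length_encode(a)
    for i, r in enumerate(runs):
        if (
            r.state == 0
            and r.length_frames < params.min_off_frames
            and 0 < i < len(runs) - 1
        ):
            a[r.start_frame : r.start_frame + r.length_frames] = 1
    # pass 2: short 1-run removal
    for r in run_length_encode(a):
        if r.state == 1 and r.length_frames < params.min_on_frames:
            a[r.start_frame : r.start_frame + r.length_frames] = 0
    return a


@dataclass(frozen=True)
class Bout:
    start_s: float
    duration_s: float


def bout_table(
    series: Sequence[int] | np.ndarray,
    params: BoutParams | None = None,
    well_id: str | None = None,
) -> pd.DataFrame:
    """Feeding bouts (one row per 1-run of the denoised series), in seconds.

    Columns: well, bout_index, start_s, duration_s.
    """
    params = params or BoutParams()
    den = denoise_flags(series, params)
    rows = []
    idx = 0
    for r in run_length_encode(den):
        if r.state == 1:
            rows.append(
                {
                    "well": well_id if well_id is not None else "",
                    "bout_index": idx,
                    "start_s": r.start_frame / params.fps,
                    "duration_s": r.length_frames / params.fps,
                }
            )
            idx += 1
    return pd.DataFrame(rows, columns=["well", "bout_index", "start_s", "duration_s"])
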