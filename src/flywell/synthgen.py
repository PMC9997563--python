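"""Synthetic well-plate video sessions with ground truth.

The generator emulates what the camera sees in a backlit well plate: one
dark fly blob per well on a bright, uniform near-infrared background,
plus occasional sub-fly-size speck noise (dust, condensation).  Behavior
is a two-state Markov chain per fly — ``roam`` (reflected random walk in
the well) and ``at_food`` (confined walk inside the food circle) — with
per-frame transition probabilities.  While at food the centroid stays far
enough inside the circle that the rendered blob is fully enclosed, and
while roaming it stays far enough outside, so the ground-truth state and
the per-pixel enclosure flag agree by construction.

An optional burst overlay chops each at-food period into feeding bursts
of ``sips_per_burst`` x ``sip_duration_s`` (7 x 0.13 s by default, 27
frames at 30 fps) separated by sub-threshold gaps, producing the raw
flag texture that the bout denoiser is designed to clean up.

Everything stochastic takes an explicit integer seed; identical seeds
give identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

from .arena import ArenaLayout, FoodCircle, PixelPoint, WellPolygon, WELL_IDS, save_layout
from .bouts import run_length_encode

ROAM, AT_FOOD = 0, 1


@dataclass(frozen=True)
class SimParams:
    """Scene, behavior, and noise parameters of one synthetic session.

    Defaults describe the desk-scale test condition: 8 wells of
    160 x 160 px, 2 minutes at 30 fps, a 5 x 3 px half-axis fly blob 80
    intensity levels darker than the 200-level backlight, and occasional
    1-4 px specks (all below the detector's 8 px minimum area).
    """

    n_wells: int = 8
    well_px: int = 160
    fly_semi_x: float = 5.0
    fly_semi_y: float = 3.0
    fly_darkness: float = 80.0
    background: float = 200.0
    food_radius_px: float = 22.0
    p_roam_to_food: float = 0.01
    p_food_to_roam: float = 0.005
    roam_step_px: float = 3.0
    food_step_px: float = 1.0
    fps: float = 30.0
    duration_s: float = 120.0
    speck_rate: float = 0.0  # probability of one speck per well per frame
    speck_max_area: int = 4
    burst_mode: bool = False
    sips_per_burst: int = 7
    sip_duration_s: float = 0.13
    burst_gap_frames: int = 5

    def __post_init__(self) -> None:
        for name in ("p_roam_to_food", "p_food_to_roam", "speck_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_wells < 1 or self.n_wells > 96:
            raise ValueError("n_wells must be in [1, 96]")
        if self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("fps and duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))

    @property
    def blob_margin(self) -> float:
        """Centroid-to-farthest-blob-pixel bound, plus 1 px rasterization slack."""
        return max(self.fly_semi_x, self.fly_semi_y) + 1.0


def make_layout(params: SimParams) -> ArenaLayout:
    """Square wells tiled in up to 4 columns, food circle at the bottom center."""
    margin = 2
    ncol = min(4, params.n_wells)
    nrow = math.ceil(params.n_wells / ncol)
    w = params.well_px
    frame_w = ncol * (w + margin) + margin
    frame_h = nrow * (w + margin) + margin
    if 2 * (params.fly_semi_x + 2) >= w or 2 * (params.fly_semi_y + 2) >= w:
        raise ValueError("fly blob larger than well")
    if 2 * params.food_radius_px + 2 * params.blob_margin >= w:
        raise ValueError("food circle plus blob margin larger than well")
    wells: dict[str, WellPolygon] = {}
    food: dict[str, FoodCircle] = {}
    for i in range(params.n_wells):
        wid = WELL_IDS[i]
        r, c = divmod(i, ncol)
        x0 = margin + c * (w + margin)
        y0 = margin + r * (w + margin)
        corners = (
            PixelPoint(x0, y0),
            PixelPoint(x0 + w - 1, y0),
            PixelPoint(x0 + w - 1, y0 + w - 1),
            PixelPoint(x0, y0 + w - 1),
        )
        wells[wid] = WellPolygon(wid, corners)
        cx = x0 + w / 2
        cy = y0 + w - 1 - params.food_radius_px - params.blob_margin - 2
        food[wid] = FoodCircle(wid, PixelPoint(cx, cy), params.food_radius_px)
    return ArenaLayout(wells, food, frame_w, frame_h, params.fps)


@dataclass
class GroundTruth:
    """Per-frame truth for every simulated well."""

    states: dict[str, np.ndarray]  # int8, ROAM/AT_FOOD per frame
    centroids: dict[str, np.ndarray]  # (n_frames, 2) float (x, y)
    fps: float

    def bout_list(self, well_id: str) -> list[tuple[float, float]]:
        """(start_s, duration_s) of every at-food run."""
        return [
            (r.start_frame / self.fps, r.length_frames / self.fps)
            for r in run_length_encode(self.states[well_id])
            if r.state == AT_FOOD
        ]

    def flag_series(self, well_id: str) -> np.ndarray:
        return (self.states[well_id] == AT_FOOD).astype(np.int8)


def _reflect(v: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by mirror reflection."""
    if hi <= lo:
        return lo
    span = hi - lo
    t = (v - lo) % (2 * span)
    return lo + (t if t <= span else 2 * span - t)


def _simulate_well(
    params: SimParams,
    well: WellPolygon,
    circle: FoodCircle,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    xs = [p.x for p in well.corners]
    ys = [p.y for p in well.corners]
    lo_x, hi_x = min(xs) + params.blob_margin, max(xs) - params.blob_margin
    lo_y, hi_y = min(ys) + params.blob_margin, max(ys) - params.blob_margin
    cx, cy = circle.center.x, circle.center.y
    r_in = circle.radius_px - params.blob_margin  # blob fully inside
    r_out = circle.radius_px + params.blob_margin  # blob fully outside
    n = params.n_frames
    states = np.empty(n, dtype=np.int8)
    pos = np.empty((n, 2), dtype=np.float64)
    state = ROAM
    # start roaming at the well center (outside the exclusion zone by layout)
    x, y = (lo_x + hi_x) / 2, (lo_y + hi_y) / 2
    for i in range(n):
        u = rng.random()
        if state == ROAM and u < params.p_roam_to_food:
            state = AT_FOOD
            # land somewhere well inside the food circle
            ang = rng.random() * 2 * math.pi
            rad = math.sqrt(rng.random()) * max(r_in - 1.0, 0.0)
            x, y = cx + rad * math.cos(ang), cy + rad * math.sin(ang)
        elif state == AT_FOOD and u < params.p_food_to_roam:
            state = ROAM
            x, y = (lo_x + hi_x) / 2, lo_y + 0.25 * (hi_y - lo_y)
        elif state == ROAM:
            x = _reflect(x + rng.normal(0, params.roam_step_px), lo_x, hi_x)
            y = _reflect(y + rng.normal(0, params.roam_step_px), lo_y, hi_y)
            d = math.hypot(x - cx, y - cy)
            if d < r_out:  # keep the blob fully outside the food circle
                scale = (r_out + 0.5) / max(d, 1e-9)
                x = _reflect(cx + (x - cx) * scale, lo_x, hi_x)
                y = _reflect(cy + (y - cy) * scale, lo_y, hi_y)
                if math.hypot(x - cx, y - cy) < r_out:
                    x, y = (lo_x + hi_x) / 2, lo_y + 0.25 * (hi_y - lo_y)
        else:  # AT_FOOD: confined walk
            x += rng.normal(0, params.food_step_px)
            y += rng.normal(0, params.food_step_px)
            d = math.hypot(x - cx, y - cy)
            if d > r_in:
                scale = max(r_in - 0.5, 0.0) / max(d, 1e-9)
                x, y = cx + (x - cx) * scale, cy + (y - cy) * scale
        states[i] = state
        pos[i] = (x, y)
    return states, pos


def simulate_behavior(params: SimParams, seed: int) -> GroundTruth:
    """Two-state Markov trajectories for every well; seed-deterministic."""
    layout = make_layout(params)
    rng = np.random.default_rng(seed)
    states: dict[str, np.ndarray] = {}
    cents: dict[str, np.ndarray] = {}
    for wid in sorted(layout.wells):
        s, p = _simulate_well(params, layout.wells[wid], layout.food[wid], rng)
        states[wid] = s
        cents[wid] = p
    return GroundTruth(states, cents, params.fps)


def render_frame(
    layout: ArenaLayout,
    truth: GroundTruth,
    params: SimParams,
    frame_index: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """One uint8 grayscale frame: dark ellipses on a flat background."""
    img = np.full((layout.frame_height, layout.frame_width), params.background, dtype=np.float64)
    fly_level = params.background - params.fly_darkness
    for wid in sorted(layout.wells):
        x, y = truth.centroids[wid][frame_index]
        rr, cc = draw_ellipse(y, x, params.fly_semi_y, params.fly_semi_x, shape=img.shape)
        img[rr, cc] = fly_level
        if rng is not None and params.speck_rate > 0 and rng.random() < params.speck_rate:
            poly = layout.wells[wid]
            xs = [p.x for p in poly.corners]
            ys = [p.y for p in poly.corners]
            n_px = int(rng.integers(1, params.speck_max_area + 1))
            sx = rng.uniform(min(xs) + 2, max(xs) - 2)
            sy = rng.uniform(min(ys) + 2, max(ys) - 2)
            for k in range(n_px):  # compact cluster of dark pixels
                px = int(round(sx)) + (k % 2)
                py = int(round(sy)) + (k // 2)
                if 0 <= py < img.shape[0] and 0 <= px < img.shape[1]:
                    img[py, px] = fly_level
    return np.clip(img, 0, 255).astype(np.uint8)


@dataclass
class Session:
    frames: list[np.ndarray]
    layout: ArenaLayout
    truth: GroundTruth
    params: SimParams


def generate_session(params: SimParams, seed: int) -> Session:
    """Simulate behavior and render every frame (speck noise included)."""
    layout = make_layout(params)
    truth = simulate_behavior(params, seed)
    # independent stream for rendering noise so behavior is unchanged by speck settings
    noise_rng = np.random.default_rng((seed, 1))
    frames = [
        render_frame(layout, truth, params, i, rng=noise_rng)
        for i in range(params.n_frames)
    ]
    return Session(frames, layout, truth, params)


def burst_overlay(
    states: np.ndarray, params: SimParams
) -> np.ndarray:
    """Chop at-food runs into sip bursts separated by sub-threshold gaps.

    Each at-food run becomes alternating on-blocks of
    round(sips_per_burst x sip_duration_s x fps) frames and off-gaps of
    ``burst_gap_frames`` frames (shorter than the denoiser's minimum gap),
    so denoising reconstructs the original run.
    """
    on_len = int(round(params.sips_per_burst * params.sip_duration_s * params.fps))
    gap = params.burst_gap_frames
    flags = np.zeros(len(states), dtype=np.int8)
    for r in run_length_encode((np.asarray(states) == AT_FOOD).astype(np.int8)):
        if r.state != 1:
            continue
        i = r.start_frame
        end = r.start_frame + r.length_frames
        while i < end:
            j = min(i + on_len, end)
            flags[i:j] = 1
            i = j + gap
    return flags


def flip_noise(flags: np.ndarray, rate: float, seed: int) -> np.ndarray:
    """Flip each frame's flag independently with the given probability."""
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    a = np.asarray(flags, dtype=np.int8).copy()
    flips = rng.random(a.shape) < rate
    a[flips] = 1 - a[flips]
    return a


def simulate_state_matrix(
    n_flies: int,
    n_frames: int,
    p_roam_to_food: float,
    p_food_to_roam: float,
    seed: int,
) -> np.ndarray:
    """(n_flies, n_frames) two-state chains, vectorized over flies.

    Initial states are drawn from the stationary distribution
    p_rf / (p_rf + p_fr), so the occupancy is stationary from frame 0.
    """
    rng = np.random.default_rng(seed)
    denom = p_roam_to_food + p_food_to_roam
    pi_food = p_roam_to_food / denom if denom > 0 else 0.0
    states = np.empty((n_flies, n_frames), dtype=np.int8)
    cur = (rng.random(n_flies) < pi_food).astype(np.int8)
    states[:, 0] = cur
    u = rng.random((n_flies, n_frames - 1)) if n_frames > 1 else None
    for t in range(1, n_frames):
        go_food = (cur == ROAM) & (u[:, t - 1] < p_roam_to_food)
        go_roam = (cur == AT_FOOD) & (u[:, t - 1] < p_food_to_roam)
        cur = np.where(go_food, AT_FOOD, np.where(go_roam, ROAM, cur)).astype(np.int8)
        states[:, t] = cur
    return states


def occupancy_chain(
    occupancy: float, mean_food_dwell_s: float = 10.0, fps: float = 30.0
) -> tuple[float, float]:
    """Transition probabilities (p_roam_to_food, p_food_to_roam) giving a
    target stationary at-food occupancy with the stated mean dwell time."""
    if not (0.0 < occupancy < 1.0):
        raise ValueError("occupancy must be in (0, 1)")
    p_fr = 1.0 / (mean_food_dwell_s * fps)
    p_rf = p_fr * occupancy / (1.0 - occupancy)
    return p_rf, p_fr


def write_session(session: Session, out_dir: str | Path) -> None:
    """Persist a session: PNG frame sequence, layout JSON, plate map CSV,
    and ground-truth CSVs (per-frame states/centroids, bout list)."""
    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    ndigits = max(6, len(str(len(session.frames))))
    for i, f in enumerate(session.frames):
        iio.imwrite(frames_dir / f"frame_{i:0{ndigits}d}.png", f)
    save_layout(session.layout, out / "layout.json")
    wids = sorted(session.layout.wells)
    pd.DataFrame(
        {
            "well": wids,
            "sex": ["male" if i % 2 else "female" for i in range(len(wids))],
            "pretreatment": ["fed"] * len(wids),
            "diet_kcal": [100.0] * len(wids),
            "flies_per_well": [1] * len(wids),
            "alive": [True] * len(wids),
        }
    ).to_csv(out / "platemap.csv", index=False)
    rows = []
    for wid in wids:
        st = session.truth.states[wid]
        ce = session.truth.centroids[wid]
        for i in range(len(st)):
            rows.append((i, wid, int(st[i]), ce[i, 0], ce[i, 1]))
    pd.DataFrame(rows, columns=["frame", "well", "state", "cx", "cy"]).to_csv(
        out / "truth_states.csv", index=False
    )
    bout_rows = [
        (wid, k, s, d)
        for wid in wids
        for k, (s, d) in enumerate(session.truth.bout_list(wid))
    ]
    pd.DataFrame(bout_rows, columns=["well", "bout_index", "start_s", "duration_s"]).to_csv(
        out / "truth_bouts.csv", index=False
    )
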