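"""Per-frame, per-well fly silhouette detection.

Flies appear as dark blobs on a bright near-infrared backlight.  Detection
runs independently per well region:

1. a per-well background model (per-pixel temporal median over sampled
   frames, restricted to the well's bounding box);
2. binarization: a pixel is foreground iff it lies inside the well polygon
   and is darker than background by more than ``delta``;
3. connected-component labeling (8-connectivity by default);
4. size filtering: keep the single largest component, provided it reaches
   ``min_area`` pixels — the retained component is the fly silhouette.

The background-subtraction threshold with a per-well temporal-median model
is this package's own choice of binarization; it is robust to static
shading from the backlight diffuser and to brightness differences between
cameras.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import measure
from skimage.draw import polygon as draw_polygon

from .arena import ArenaLayout, PixelPoint, WellPolygon

DEFAULT_DELTA = 25.0
DEFAULT_MIN_AREA = 8
DEFAULT_CONNECTIVITY = 8


@dataclass(frozen=True)
class Component:
    """One connected foreground component.

    ``pixel_set`` holds (x, y) integer pixel positions in full-frame
    coordinates; the centroid is the arithmetic mean of those positions.
    """

    pixel_set: frozenset[tuple[int, int]]
    area_px: int
    centroid: PixelPoint

    @classmethod
    def from_pixels(cls, pixels: Iterable[tuple[int, int]]) -> "Component":
        pset = frozenset(pixels)
        if not pset:
            raise ValueError("component must contain at least one pixel")
        xs = [p[0] for p in pset]
        ys = [p[1] for p in pset]
        return cls(pset, len(pset), PixelPoint(float(np.mean(xs)), float(np.mean(ys))))


@dataclass(frozen=True)
class DetectionRecord:
    """Detection outcome for one well in one frame."""

    frame_index: int
    well_id: str
    found: bool
    centroid: Optional[PixelPoint] = None
    area_px: Optional[int] = None
    pixel_set: Optional[frozenset[tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if not self.found and (self.centroid is not None or self.area_px is not None):
            raise ValueError("found=False record must not carry centroid/area")


def _well_bbox(well: WellPolygon, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    """Integer bounding box (x0, y0, x1, y1), half-open, clipped to frame."""
    xs = [p.x for p in well.corners]
    ys = [p.y for p in well.corners]
    h, w = shape
    x0 = max(0, int(np.floor(min(xs))))
    y0 = max(0, int(np.floor(min(ys))))
    x1 = min(w, int(np.ceil(max(xs))) + 1)
    y1 = min(h, int(np.ceil(max(ys))) + 1)
    return x0, y0, x1, y1


def well_mask(well: WellPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the well polygon,
    restricted to (and shaped like) the well's bounding box."""
    x0, y0, x1, y1 = _well_bbox(well, shape)
    rr, cc = draw_polygon(
        [p.y - y0 for p in well.corners],
        [p.x - x0 for p in well.corners],
        shape=(y1 - y0, x1 - x0),
    )
    m = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    m[rr, cc] = True
    return m


def estimate_background(
    frames: Sequence[np.ndarray], well: WellPolygon
) -> np.ndarray:
    """Per-pixel temporal median of sampled frames over the well bounding box.

    The median is robust to the fly: any pixel the blob occupies in fewer
    than half the sampled frames recovers its unoccluded backlight value.
    """
    if len(frames) < 3:
        raise ValueError(f"need >= 3 sampled frames for background, got {len(frames)}")
    x0, y0, x1, y1 = _well_bbox(well, frames[0].shape)
    stack = np.stack([np.asarray(f)[y0:y1, x0:x1].astype(np.float64) for f in frames])
    return np.median(stack, axis=0)


def binarize_well(
    frame: np.ndarray,
    well: WellPolygon,
    background: np.ndarray,
    delta: float = DEFAULT_DELTA,
    region_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Binary fly-pixel mask over the well's bounding box.

    Foreground iff the pixel center is inside the well polygon AND
    ``intensity < background - delta`` (strict: a pixel at exactly
    background - delta stays background).  ``region_mask`` lets callers
    reuse a precomputed :func:`well_mask` across frames.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    x0, y0, x1, y1 = _well_bbox(well, frame.shape)
    crop = np.asarray(frame)[y0:y1, x0:x1].astype(np.float64)
    if background.shape != crop.shape:
        raise ValueError(
            f"background shape {background.shape} does not cover well bbox {crop.shape}"
        )
    if region_mask is None:
        region_mask = well_mask(well, frame.shape)
    return (crop < background - delta) & region_mask


def label_components(
    mask: np.ndarray,
    connectivity: int = DEFAULT_CONNECTIVITY,
    origin: tuple[int, int] = (0, 0),
) -> list[Component]:
    """Connected components of a binary mask.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge- or corner-adjacent).
    ``origin`` = (x0, y0) offsets pixel coordinates back into the full
    frame when the mask is a bounding-box crop.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = measure.label(np.asarray(mask, dtype=bool), connectivity=1 if connectivity == 4 else 2)
    x0, y0 = origin
    out: list[Component] = []
    for region in measure.regionprops(lab):
        pixels = frozenset((int(c + x0), int(r + y0)) for r, c in region.coords)
        cy, cx = region.centroid
        out.append(
            Component(pixels, int(region.area), PixelPoint(cx + x0, cy + y0))
        )
    return out


def select_fly(
    components: Sequence[Component], min_area: int = DEFAULT_MIN_AREA
) -> Optional[Component]:
    """Largest component if it reaches ``min_area``, else None.

    Area ties break deterministically toward the component whose
    top-left-most pixel comes first in row-major (y, then x) order.
    """
    if not components:
        return None
    best = max(
        components,
        key=lambda c: (c.area_px, tuple(-v for v in min((y, x) for x, y in c.pixel_set))),
    )
    return best if best.area_px >= min_area else None


@dataclass
class DetectorParams:
    delta: float = DEFAULT_DELTA
    min_area: int = DEFAULT_MIN_AREA
    connectivity: int = DEFAULT_CONNECTIVITY
    background_samples: int = 11


class WellDetector:
    """Stateful per-well detector: fixed background, repeated frames."""

    def __init__(
        self,
        well: WellPolygon,
        background: np.ndarray,
        params: DetectorParams | None = None,
    ) -> None:
        self.well = well
        self.background = background
        self.params = params or DetectorParams()
        self._region_mask: Optional[np.ndarray] = None

    def detect(
        self, frame: np.ndarray, frame_index: int, keep_pixels: bool = True
    ) -> DetectionRecord:
        if self._region_mask is None:
            self._region_mask = well_mask(self.well, frame.shape)
        mask = binarize_well(
            frame, self.well, self.background, self.params.delta, self._region_mask
        )
        x0, y0, _, _ = _well_bbox(self.well, frame.shape)
        comps = label_components(mask, self.params.connectivity, origin=(x0, y0))
        fly = select_fly(comps, self.params.min_area)
        if fly is None:
            return DetectionRecord(frame_index, self.well.well_id, False)
        return DetectionRecord(
            frame_index,
            self.well.well_id,
            True,
            centroid=fly.centroid,
            area_px=fly.area_px,
            pixel_set=fly.pixel_set if keep_pixels else None,
        )


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an image array to float grayscale by luminance."""
    a = np.asarray(img)
    if a.ndim == 2:
        return a.astype(np.float64)
    # ITU-R BT.601 luma weights
    return a[..., :3].astype(np.float64) @ np.array([0.299, 0.587, 0.114])


def iter_frames(source: str | Path) -> Iterator[np.ndarray]:
    """Yield grayscale frames from an image-sequence directory or a video file.

    A directory is read as an image sequence in lexicographic file order
    (PNG/TIFF/...).  Anything else is handed to imageio, which decodes
    common containers where a plugin is available.
    """
    src = Path(source)
    if src.is_dir():
        files = sorted(
            p for p in src.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")
        )
        if not files:
            raise FileNotFoundError(f"no image files in {src}")
        for f in files:
            yield to_grayscale(iio.imread(f))
    else:
        if not src.exists():
            raise FileNotFoundError(src)
        for frame in iio.imiter(src):
            yield to_grayscale(frame)


def detect_session(
    frames: Iterable[np.ndarray] | str | Path,
    layout: ArenaLayout,
    params: DetectorParams | None = None,
    wells: Optional[Sequence[str]] = None,
    keep_pixels: bool = True,
) -> dict[str, list[DetectionRecord]]:
    """Run detection for every frame and well of a session.

    Background is the per-well temporal median of up to
    ``params.background_samples`` frames sampled evenly across the session,
    so the whole frame stream is materialized once as a list.
    """
    params = params or DetectorParams()
    if isinstance(frames, (str, Path)):
        frame_list = list(iter_frames(frames))
    else:
        # keep native dtype (uint8 for rendered/loaded frames): binarize
        # converts per-well crops, and a float copy of a long session
        # would not fit comfortably in memory
        frame_list = [np.asarray(f) for f in frames]
    if not frame_list:
        return {}
    wells = list(wells) if wells is not None else sorted(layout.wells)
    n_bg = min(len(frame_list), max(3, params.background_samples))
    sample_idx = np.unique(np.linspace(0, len(frame_list) - 1, n_bg).astype(int))
    if len(sample_idx) < 3:
        sample_idx = np.arange(len(frame_list))
    samples = [frame_list[i] for i in sample_idx]
    out: dict[str, list[DetectionRecord]] = {}
    for wid in wells:
        poly = layout.wells[wid]
        det = WellDetector(poly, estimate_background(samples, poly), params)
        out[wid] = [
            det.detect(f, i, keep_pixels=keep_pixels) for i, f in enumerate(frame_list)
        ]
    return out


def detections_to_frame(records: dict[str, list[DetectionRecord]]) -> pd.DataFrame:
    """Flatten detection records to the CSV schema frame,well,found,cx,cy,area."""
    rows = []
    for wid in sorted(records):
        for r in records[wid]:
            rows.append(
                {
                    "frame": r.frame_index,
                    "well": wid,
                    "found": r.found,
                    "cx": r.centroid.x if r.found else np.nan,
                    "cy": r.centroid.y if r.found else np.nan,
                    "area": r.area_px if r.found else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["frame", "well", "found", "cx", "cy", "area"])
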