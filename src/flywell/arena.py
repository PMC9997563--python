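"""Arena geometry and plate metadata for 96-well behavioral assays.

The imaging arena is a 96-well plate viewed from above.  Two manual
annotation products define its geometry in image coordinates:

* a four-corner polygon outlining each well, and
* a circle (center + radius) marking the food-port region of each well.

This module holds those annotations as validated dataclasses, persists
them to a versioned JSON schema, assigns image points to wells, and
loads the plate map (per-well sex / pretreatment / diet metadata) from
CSV.

Coordinate convention: 0-based pixel centers, origin at the top-left of
the frame, x rightward, y downward.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from shapely.geometry import Point, Polygon

LAYOUT_SCHEMA_VERSION = 1

#: Plate coordinates A1..H12 in row-major order.
WELL_IDS: tuple[str, ...] = tuple(
    f"{row}{col}" for row in "ABCDEFGH" for col in range(1, 13)
)

SEXES = frozenset({"female", "male"})
PRETREATMENTS = frozenset({"fed", "starved"})


@dataclass(frozen=True)
class PixelPoint:
    """A point in image coordinates (pixels, origin top-left)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite pixel coordinate ({self.x}, {self.y})")

    def distance_to(self, other: "PixelPoint") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


def _signed_area(corners: Sequence[PixelPoint]) -> float:
    """Shoelace signed area; positive = counter-clockwise in a y-down frame
    means negative screen-area, so clockwise corners give positive area here."""
    s = 0.0
    n = len(corners)
    for i in range(n):
        p, q = corners[i], corners[(i + 1) % n]
        s += p.x * q.y - q.x * p.y
    return 0.5 * s


@dataclass(frozen=True)
class WellPolygon:
    """Four-corner outline of one well, stored clockwise (screen sense)."""

    well_id: str
    corners: tuple[PixelPoint, PixelPoint, PixelPoint, PixelPoint]

    def __post_init__(self) -> None:
        if len(self.corners) != 4:
            raise ValueError(
                f"well {self.well_id}: expected 4 corners, got {len(self.corners)}"
            )
        area = _signed_area(self.corners)
        if area == 0.0:
            raise ValueError(f"well {self.well_id}: degenerate polygon (zero area)")
        if area < 0.0:
            # stored counter-clockwise; reorder to the clockwise convention
            object.__setattr__(self, "corners", tuple(reversed(self.corners)))

    @property
    def area(self) -> float:
        return abs(_signed_area(self.corners))

    def as_shapely(self) -> Polygon:
        return Polygon([(p.x, p.y) for p in self.corners])

    def centroid(self) -> PixelPoint:
        c = self.as_shapely().centroid
        return PixelPoint(c.x, c.y)

    def contains(self, p: PixelPoint) -> bool:
        """True if the point is inside or exactly on the boundary."""
        return self.as_shapely().covers(Point(p.x, p.y))


@dataclass(frozen=True)
class FoodCircle:
    """Image-plane circle covering the food cylinder of one well."""

    well_id: str
    center: PixelPoint
    radius_px: float

    def __post_init__(self) -> None:
        if not (self.radius_px > 0):
            raise ValueError(f"well {self.well_id}: radius_px must be > 0")

    def encloses(self, p: PixelPoint) -> bool:
        return self.center.distance_to(p) <= self.radius_px


@dataclass
class ArenaLayout:
    """Complete arena annotation: well polygons, food circles, frame geometry.

    A full plate has 96 wells (A1..H12); partial layouts (a subset of wells,
    e.g. for a cropped camera view or a synthetic session) are allowed as
    long as ids are unique and each food circle has a matching polygon.
    `require_full_plate` in :func:`validate_layout` restores the strict
    96-well check.
    """

    wells: dict[str, WellPolygon]
    food: dict[str, FoodCircle]
    frame_width: int
    frame_height: int
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def well_ids(self) -> list[str]:
        return sorted(self.wells)

    def well_of_point(self, p: PixelPoint) -> Optional[str]:
        """Return the well whose polygon contains ``p`` (boundary inclusive).

        Wells are scanned in lexicographic id order, so a point lying on an
        edge shared by two wells is deterministically assigned to the
        lexicographically smaller id.
        """
        for wid in sorted(self.wells):
            if self.wells[wid].contains(p):
                return wid
        return None


def well_of_point(p: PixelPoint, layout: ArenaLayout) -> Optional[str]:
    """Functional alias for :meth:`ArenaLayout.well_of_point`."""
    return layout.well_of_point(p)


@dataclass(frozen=True)
class LayoutViolation:
    well_id: str  # "" for layout-level problems
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        prefix = f"[{self.well_id}] " if self.well_id else ""
        return f"{prefix}{self.rule}: {self.message}"


def validate_layout(
    layout: ArenaLayout, *, require_full_plate: bool = True
) -> list[LayoutViolation]:
    """Check layout invariants; returns violations instead of raising.

    Checks: well-id completeness/pairing, corners within frame bounds,
    positive food radius, food center inside its well, and pairwise polygon
    overlap.  Overlap and a food circle poking outside its well are reported
    with rule names ``polygon_overlap`` and ``food_circle_outside`` so
    callers can choose to treat them as warnings (shared walls and
    annotation jitter around the bottom-center feeding port are expected in
    real images).
    """
    out: list[LayoutViolation] = []
    if require_full_plate:
        missing = [w for w in WELL_IDS if w not in layout.wells]
        if missing:
            out.append(
                LayoutViolation("", "missing_wells", f"missing wells: {missing}")
            )
    for wid in sorted(layout.wells):
        if wid not in WELL_IDS:
            out.append(LayoutViolation(wid, "unknown_well_id", "not in A1..H12"))
    for wid, poly in sorted(layout.wells.items()):
        for p in poly.corners:
            if not (0 <= p.x <= layout.frame_width - 1 and 0 <= p.y <= layout.frame_height - 1):
                out.append(
                    LayoutViolation(
                        wid, "corner_out_of_frame", f"corner ({p.x}, {p.y}) outside frame"
                    )
                )
                break
    for wid, circ in sorted(layout.food.items()):
        if wid not in layout.wells:
            out.append(LayoutViolation(wid, "orphan_food_circle", "no matching well polygon"))
            continue
        if circ.radius_px <= 0:
            out.append(LayoutViolation(wid, "nonpositive_radius", f"radius {circ.radius_px}"))
        if not layout.wells[wid].contains(circ.center):
            out.append(
                LayoutViolation(wid, "food_center_outside", "food center outside well polygon")
            )
        else:
            # full-circle containment is a warning-grade rule
            shp = layout.wells[wid].as_shapely()
            if not shp.buffer(1e-9).contains(Point(circ.center.x, circ.center.y).buffer(circ.radius_px)):
                out.append(
                    LayoutViolation(
                        wid, "food_circle_outside", "food circle extends beyond well polygon"
                    )
                )
    for wid in sorted(layout.wells):
        if wid not in layout.food:
            out.append(LayoutViolation(wid, "missing_food_circle", "no food circle"))
    wids = sorted(layout.wells)
    polys = {w: layout.wells[w].as_shapely() for w in wids}
    for i, a in enumerate(wids):
        for b in wids[i + 1 :]:
            inter = polys[a].intersection(polys[b])
            if inter.area > 1e-9:
                out.append(
                    LayoutViolation(
                        a, "polygon_overlap", f"wells {a} and {b} overlap (area {inter.area:.3g})"
                    )
                )
    return out


WARNING_RULES = frozenset({"food_circle_outside", "polygon_overlap"})


class LayoutSchemaError(ValueError):
    """Raised when a layout file does not satisfy the schema."""


def save_layout(layout: ArenaLayout, path: str | Path) -> None:
    """Write the layout to the versioned JSON schema.

    Coordinates are serialized via ``repr(float)`` (shortest round-trip
    representation), so save→load is numerically exact.
    """
    doc = {
        "schema": "flywell-arena-layout",
        "version": LAYOUT_SCHEMA_VERSION,
        "frame_width": layout.frame_width,
        "frame_height": layout.frame_height,
        "fps": layout.fps,
        "wells": [
            {
                "well_id": wid,
                "corners": [[p.x, p.y] for p in layout.wells[wid].corners],
            }
            for wid in sorted(layout.wells)
        ],
        "food": [
            {
                "well_id": wid,
                "center": [layout.food[wid].center.x, layout.food[wid].center.y],
                "radius_px": layout.food[wid].radius_px,
            }
            for wid in sorted(layout.food)
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_layout(path: str | Path, *, require_full_plate: bool = False) -> ArenaLayout:
    """Load and validate a layout JSON file.

    Raises :class:`LayoutSchemaError` naming the offending well on schema
    problems (duplicate/missing ids, wrong corner count, nonpositive
    radius).  Hard geometric invariants are re-validated; warning-grade
    rules (circle poking out of the well, overlapping shared walls) do not
    raise.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    try:
        doc = json.loads(p.read_text())
    except json.JSONDecodeError as e:
        raise LayoutSchemaError(f"{p}: not valid JSON: {e}") from e
    if doc.get("schema") != "flywell-arena-layout":
        raise LayoutSchemaError(f"{p}: unrecognized schema tag {doc.get('schema')!r}")
    wells: dict[str, WellPolygon] = {}
    for w in doc.get("wells", []):
        wid = w.get("well_id")
        if wid in wells:
            raise LayoutSchemaError(f"duplicate well id {wid!r}")
        corners = w.get("corners", [])
        if len(corners) != 4:
            raise LayoutSchemaError(f"well {wid}: expected 4 corners, got {len(corners)}")
        try:
            wells[wid] = WellPolygon(
                wid, tuple(PixelPoint(float(x), float(y)) for x, y in corners)
            )
        except ValueError as e:
            raise LayoutSchemaError(str(e)) from e
    food: dict[str, FoodCircle] = {}
    for f in doc.get("food", []):
        wid = f.get("well_id")
        if wid in food:
            raise LayoutSchemaError(f"duplicate food circle for well {wid!r}")
        try:
            food[wid] = FoodCircle(
                wid,
                PixelPoint(float(f["center"][0]), float(f["center"][1])),
                float(f["radius_px"]),
            )
        except (ValueError, KeyError, IndexError) as e:
            raise LayoutSchemaError(f"well {wid}: bad food circle: {e}") from e
    layout = ArenaLayout(
        wells=wells,
        food=food,
        frame_width=int(doc["frame_width"]),
        frame_height=int(doc["frame_height"]),
        fps=float(doc.get("fps", 30.0)),
    )
    violations = [
        v
        for v in validate_layout(layout, require_full_plate=require_full_plate)
        if v.rule not in WARNING_RULES
    ]
    if violations:
        raise LayoutSchemaError("; ".join(str(v) for v in violations))
    return layout


@dataclass
class PlateMap:
    """Per-well experimental metadata.

    Columns: sex (female/male), pretreatment (fed/starved), diet_kcal
    (kcal/L of the offered diet), flies_per_well (1-3), alive (bool).
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("well", "sex", "pretreatment", "diet_kcal", "flies_per_well", "alive")

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"plate map missing columns: {missing}")
        if df["well"].duplicated().any():
            dups = df.loc[df["well"].duplicated(), "well"].tolist()
            raise ValueError(f"duplicate wells in plate map: {dups}")
        bad_sex = set(df["sex"]) - SEXES
        if bad_sex:
            raise ValueError(f"unknown sex values: {sorted(bad_sex)}")
        bad_pre = set(df["pretreatment"]) - PRETREATMENTS
        if bad_pre:
            raise ValueError(f"unknown pretreatment values: {sorted(bad_pre)}")
        n = df["flies_per_well"].astype(int)
        if ((n < 1) | (n > 3)).any():
            bad = df.loc[(n < 1) | (n > 3), "well"].tolist()
            raise ValueError(f"flies_per_well outside [1, 3] for wells: {bad}")
        unknown = [w for w in df["well"] if w not in WELL_IDS]
        if unknown:
            raise ValueError(f"unknown well ids in plate map: {unknown}")
        self.table = df.set_index("well", drop=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlateMap":
        df = pd.read_csv(path)
        if "alive" in df.columns:
            df["alive"] = df["alive"].map(
                lambda v: str(v).strip().lower() in ("1", "true", "yes")
            )
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def check_against_layout(self, layout: ArenaLayout) -> None:
        missing = [w for w in self.table["well"] if w not in layout.wells]
        if missing:
            raise ValueError(f"plate map wells absent from layout: {missing}")

    def group_key(self, well: str) -> tuple[str, str, float]:
        row = self.table.loc[well]
        return (str(row["sex"]), str(row["pretreatment"]), float(row["diet_kcal"]))
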