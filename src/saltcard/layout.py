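"""Card geometry: fiducial marks, reaction zones, colour standards.

Everything on the card is described in a single reference frame:
millimetres, origin at the top-left card corner, x rightward, y downward.
Rendered and rectified images use pixel coordinates with the same
handedness, so a point at (x, y) mm appears at (x*scale, y*scale) px in a
rectified image.

A layout is pure configuration (loaded from YAML) so that card redesigns --
different zone ladders, control assignments, patch colours -- need no code
changes.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from shapely.geometry import Point, box

__all__ = [
    "FiducialMark",
    "ReactionZone",
    "ColorStandardPatch",
    "CardLayout",
    "LayoutError",
    "load_layout",
    "save_layout",
    "validate_layout",
    "default_layout",
]

ROLES = ("measurement", "positive_control", "negative_control")

#: coordinates are serialized at this precision (mm)
COORD_PRECISION = 0.01

#: the measurement ladders must jointly cover this span of ppm iodine,
#: with at least this many zones overlapping every point of it
REQUIRED_SPAN = (0.0, 35.0)
REQUIRED_MULTIPLICITY = 3


class LayoutError(ValueError):
    """Raised when a layout file cannot be parsed or violates an invariant."""


@dataclass(frozen=True)
class FiducialMark:
    """A printed registration disk whose detected centroid anchors the
    geometric correction."""

    id: int
    center: tuple[float, float]  # mm
    radius: float  # mm


@dataclass(frozen=True)
class ReactionZone:
    """One wax-bounded reaction square with its central indicator circle.

    ``quant_range`` is the span of ppm iodine (in solid salt) that this
    zone's threshold-titration chemistry resolves; outside it the zone sits
    on its background or saturation plateau.
    """

    id: int
    square: tuple[float, float, float, float]  # x, y, w, h in mm
    roi_center: tuple[float, float]  # mm
    roi_radius: float  # mm
    role: str
    quant_range: tuple[float, float]  # ppm iodine

    @property
    def is_measurement(self) -> bool:
        return self.role == "measurement"


@dataclass(frozen=True)
class ColorStandardPatch:
    id: int
    bounds: tuple[float, float, float, float]  # x, y, w, h in mm
    nominal_color: tuple[float, float, float]  # RGB in [0, 1]

    @property
    def is_neutral(self) -> bool:
        r, g, b = self.nominal_color
        return abs(r - g) < 1e-9 and abs(g - b) < 1e-9


@dataclass(frozen=True)
class CardLayout:
    card_size: tuple[float, float]  # width, height in mm
    fiducials: tuple[FiducialMark, ...]
    zones: tuple[ReactionZone, ...]
    color_standards: tuple[ColorStandardPatch, ...]
    qr_region: tuple[float, float, float, float]  # opaque; never decoded

    @property
    def measurement_zones(self) -> tuple[ReactionZone, ...]:
        return tuple(z for z in self.zones if z.is_measurement)

    @property
    def control_zones(self) -> tuple[ReactionZone, ...]:
        return tuple(z for z in self.zones if not z.is_measurement)

    def zone(self, zone_id: int) -> ReactionZone:
        for z in self.zones:
            if z.id == zone_id:
                return z
        raise KeyError(f"no zone with id {zone_id}")

    def neutral_patches(self) -> tuple[ColorStandardPatch, ...]:
        """Neutral patches, brightest first (the white-balance candidates)."""
        patches = [p for p in self.color_standards if p.is_neutral]
        patches.sort(key=lambda p: -sum(p.nominal_color))
        return tuple(patches)


# ---------------------------------------------------------------------------
# validation

def _max_collinear(points: Sequence[tuple[float, float]], tol: float = 1e-6) -> int:
    best = min(2, len(points))
    for a, b in itertools.combinations(range(len(points)), 2):
        ax, ay = points[a]
        bx, by = points[b]
        norm = math.hypot(bx - ax, by - ay)
        if norm < tol:
            continue
        n = 0
        for px, py in points:
            cross = abs((bx - ax) * (py - ay) - (by - ay) * (px - ax)) / norm
            if cross < tol:
                n += 1
        best = max(best, n)
    return best


def _footprints(layout: CardLayout) -> list[tuple[str, object]]:
    shapes: list[tuple[str, object]] = []
    for f in layout.fiducials:
        shapes.append((f"fiducial {f.id}", Point(f.center).buffer(f.radius, quad_segs=32)))
    for z in layout.zones:
        x, y, w, h = z.square
        shapes.append((f"zone {z.id}", box(x, y, x + w, y + h)))
    for p in layout.color_standards:
        x, y, w, h = p.bounds
        shapes.append((f"color standard {p.id}", box(x, y, x + w, y + h)))
    x, y, w, h = layout.qr_region
    shapes.append(("qr region", box(x, y, x + w, y + h)))
    return shapes


def _coverage_violations(zones: Iterable[ReactionZone]) -> list[str]:
    ranges = sorted(z.quant_range for z in zones if z.is_measurement)
    out: list[str] = []
    if not ranges:
        return ["no measurement zones: cannot cover the required ppm span"]
    lo_req, hi_req = REQUIRED_SPAN
    # sweep over interval breakpoints; check multiplicity at every midpoint
    edges = sorted({e for r in ranges for e in r} | {lo_req, hi_req})
    probes = [lo_req, hi_req]
    for a, b in zip(edges, edges[1:]):
        if b > lo_req and a < hi_req:
            probes.append(max(a, lo_req) / 2 + min(b, hi_req) / 2)
    for p in probes:
        n = sum(1 for lo, hi in ranges if lo <= p <= hi)
        if n < REQUIRED_MULTIPLICITY:
            out.append(
                f"measurement coverage at {p:.2f} ppm is {n}-fold; "
                f"{REQUIRED_MULTIPLICITY}-fold coverage of "
                f"{lo_req:g}-{hi_req:g} ppm is required"
            )
            break
    # contiguity of the union
    reach = ranges[0][0]
    if reach > lo_req:
        out.append(f"measurement ranges start at {reach:g} ppm, above {lo_req:g}")
    for lo, hi in ranges:
        if lo > reach:
            out.append(f"gap in measurement coverage between {reach:g} and {lo:g} ppm")
            break
        reach = max(reach, hi)
    if reach < hi_req:
        out.append(f"measurement ranges end at {reach:g} ppm, below {hi_req:g}")
    return out


def validate_layout(layout: CardLayout) -> list[str]:
    """Check every layout invariant; return a description of each violation.

    An empty list means the layout is valid. Violations are returned rather
    than raised so that a layout editor can show all problems at once.
    """
    v: list[str] = []
    w, h = layout.card_size
    if w <= 0 or h <= 0:
        v.append("card_size must be positive")
        return v

    # --- fiducials
    if len(layout.fiducials) != 6:
        v.append(f"exactly 6 fiducial marks required, found {len(layout.fiducials)}")
    centers = [f.center for f in layout.fiducials]
    for (i, a), (j, b) in itertools.combinations(enumerate(layout.fiducials), 2):
        if math.dist(a.center, b.center) < 1e-9:
            v.append(f"fiducials {a.id} and {b.id} have coincident centers")
    if len(centers) >= 4 and _max_collinear(centers) > len(centers) - 2:
        v.append("at least 4 fiducial marks must be non-collinear")

    # --- zones
    if len(layout.zones) != 12:
        v.append(f"exactly 12 reaction zones required, found {len(layout.zones)}")
    ids = [z.id for z in layout.zones]
    if len(set(ids)) != len(ids):
        v.append("zone ids must be unique")
    for z in layout.zones:
        x, y, zw, zh = z.square
        cx, cy = z.roi_center
        if not (
            x < cx - z.roi_radius
            and cx + z.roi_radius < x + zw
            and y < cy - z.roi_radius
            and cy + z.roi_radius < y + zh
        ):
            v.append(f"zone {z.id}: ROI circle not strictly inside its square")
        if z.role not in ROLES:
            v.append(f"zone {z.id}: unknown role {z.role!r}")
        lo, hi = z.quant_range
        if not lo < hi:
            v.append(f"zone {z.id}: quant_range lower bound must be below upper")
    if not any(z.role == "positive_control" for z in layout.zones):
        v.append("at least one positive_control zone required")
    if not any(z.role == "negative_control" for z in layout.zones):
        v.append("at least one negative_control zone required")
    v.extend(_coverage_violations(layout.zones))

    # --- colour standards
    if not any(p.is_neutral for p in layout.color_standards):
        v.append("at least one neutral (equal-RGB) colour standard required")
    for p in layout.color_standards:
        if not all(0.0 <= c <= 1.0 for c in p.nominal_color):
            v.append(f"color standard {p.id}: nominal_color outside [0, 1]")

    # --- containment and overlap
    card = box(0, 0, w, h)
    shapes = _footprints(layout)
    for name, shape in shapes:
        if not card.contains(shape):
            v.append(f"{name} extends outside the card bounds")
    for (na, sa), (nb, sb) in itertools.combinations(shapes, 2):
        if sa.intersection(sb).area > 1e-9:
            v.append(f"footprints of {na} and {nb} overlap")
    return v


# ---------------------------------------------------------------------------
# serialization

def _parse(doc: dict) -> CardLayout:
    try:
        fiducials = tuple(
            FiducialMark(int(f["id"]), tuple(map(float, f["center"])), float(f["radius"]))
            for f in doc["fiducials"]
        )
        zones = tuple(
            ReactionZone(
                int(z["id"]),
                tuple(map(float, z["square"])),
                tuple(map(float, z["roi_center"])),
                float(z["roi_radius"]),
                str(z["role"]),
                tuple(map(float, z["quant_range"])),
            )
            for z in doc["zones"]
        )
        patches = tuple(
            ColorStandardPatch(
                int(p["id"]),
                tuple(map(float, p["bounds"])),
                tuple(map(float, p["nominal_color"])),
            )
            for p in doc["color_standards"]
        )
        return CardLayout(
            card_size=tuple(map(float, doc["card_size"])),
            fiducials=fiducials,
            zones=zones,
            color_standards=patches,
            qr_region=tuple(map(float, doc["qr_region"])),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise LayoutError(f"malformed layout document: {exc}") from exc


def load_layout(path: str | Path) -> CardLayout:
    """Load a layout YAML file and enforce every invariant.

    Raises :class:`LayoutError` on parse failure or on the first validation
    pass, with the message naming each violated invariant.
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise LayoutError(f"cannot parse layout file {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise LayoutError(f"layout file {path} is not a mapping")
    layout = _parse(doc)
    violations = validate_layout(layout)
    if violations:
        raise LayoutError("invalid layout:\n" + "\n".join(f"- {s}" for s in violations))
    return layout


def _r(x: float) -> float:
    return round(float(x) / COORD_PRECISION) * COORD_PRECISION


def save_layout(layout: CardLayout, path: str | Path) -> None:
    """Write a layout as YAML, rounding lengths to the declared 0.01 mm."""
    doc = {
        "card_size": [_r(c) for c in layout.card_size],
        "fiducials": [
            {"id": f.id, "center": [_r(c) for c in f.center], "radius": _r(f.radius)}
            for f in layout.fiducials
        ],
        "zones": [
            {
                "id": z.id,
                "square": [_r(c) for c in z.square],
                "roi_center": [_r(c) for c in z.roi_center],
                "roi_radius": _r(z.roi_radius),
                "role": z.role,
                "quant_range": [_r(c) for c in z.quant_range],
            }
            for z in layout.zones
        ],
        "color_standards": [
            {
                "id": p.id,
                "bounds": [_r(c) for c in p.bounds],
                "nominal_color": [round(float(c), 6) for c in p.nominal_color],
            }
            for p in layout.color_standards
        ],
        "qr_region": [_r(c) for c in layout.qr_region],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_layout() -> CardLayout:
    """The bundled reference card design (12 zones, 6 fiducials)."""
    ref = resources.files("saltcard.data").joinpath("default_layout.yaml")
    with resources.as_file(ref) as path:
        return load_layout(path)
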