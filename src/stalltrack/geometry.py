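"""Stall geometry: the image rectangle, named regions and static distractors.

The camera views the box stall obliquely; all geometry lives directly in the
2.7K image plane (2704 x 1520 px by default) because every downstream
analysis consumes pixel coordinates only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import Point, Polygon
from shapely.prepared import prep

from .tracks import TrackValidationError


@dataclass
class StallGeometry:
    """Image dimensions plus named stall regions and distractor points.

    Regions are simple polygons in pixel coordinates (e.g. "front" near the
    door, "sidewall", "feeding" around the trough).  Distractors are static
    objects a detector may latch onto (automatic waterer, manure pile,
    shoes) and serve as teleport targets for injected mislabels.
    """

    width_px: int = 2704
    height_px: int = 1520
    regions: dict[str, Polygon] = field(default_factory=dict)
    distractors: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise TrackValidationError("image dimensions must be positive")
        image = Polygon(
            [(0, 0), (self.width_px, 0), (self.width_px, self.height_px), (0, self.height_px)]
        )
        clean: dict[str, Polygon] = {}
        for name, poly in self.regions.items():
            if not isinstance(poly, Polygon):
                poly = Polygon(poly)
            if not poly.is_valid or poly.is_empty:
                raise TrackValidationError(f"region '{name}' is not a simple polygon")
            if not image.covers(poly):
                raise TrackValidationError(
                    f"region '{name}' has vertices outside the image rectangle"
                )
            clean[name] = poly
        self.regions = clean
        for name, (px, py) in self.distractors.items():
            if not (0 <= px <= self.width_px and 0 <= py <= self.height_px):
                raise TrackValidationError(f"distractor '{name}' outside the image")
        self._prepared = {name: prep(poly) for name, poly in self.regions.items()}

    @property
    def diagonal_px(self) -> float:
        return float((self.width_px**2 + self.height_px**2) ** 0.5)

    def region_centroid(self, name: str) -> tuple[float, float]:
        c = self.regions[name].centroid
        return (c.x, c.y)

    def contains(self, name: str, x: float, y: float) -> bool:
        """Boundary-inclusive containment of a point in a named region."""
        return bool(self.regions[name].covers(Point(x, y)))


def default_geometry() -> StallGeometry:
    """The reference 2.7K box-stall layout used by the simulator.

    The door sits in the upper-left corner; "front" is the door half of the
    stall, "sidewall" the far wall, "feeding" the trough corner low in the
    image.  Regions are disjoint rectangles (they share edges only), so the
    occupancy partition front/sidewall/feeding/elsewhere is exhaustive.
    """
    return StallGeometry(
        width_px=2704,
        height_px=1520,
        regions={
            "front": Polygon([(0, 0), (1300, 0), (1300, 800), (0, 800)]),
            "sidewall": Polygon([(1300, 0), (2704, 0), (2704, 800), (1300, 800)]),
            "feeding": Polygon([(1300, 1000), (2704, 1000), (2704, 1520), (1300, 1520)]),
        },
        distractors={
            "waterer": (2600.0, 150.0),
            "manure_pile": (700.0, 1400.0),
            "shoes": (100.0, 1450.0),
        },
    )


#: Pixel position of the stall door in the default layout (upper-left wall);
#: used by the tail-occlusion schedule ("horse faces the door").
DEFAULT_DOOR_XY = (80.0, 300.0)
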