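"""Wintering-region geometry.

Eight ecologically distinct wintering regions are modelled as disjoint
lon/lat rectangles spanning roughly 24.5-36.5 degrees N, 105-89 degrees W, so
great-circle distances between them are realistic for the south-central USA
and northern Mexico.  Region codes follow the capture-history convention:

    1  South Texas Brushlands
    2  Mississippi Alluvial Valley (MAV)
    3  Chenier Plain
    4  Texas Mid-coast
    5  Other
    6  Mexico
    7  Lower Texas Coast
    8  Rolling/High Plains

Code 9 is reserved for "not observed" and never has a polygon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon, mapping, shape

REGION_NAMES = {
    1: "South Texas Brushlands",
    2: "MAV",
    3: "Chenier Plain",
    4: "Texas Mid-coast",
    5: "Other",
    6: "Mexico",
    7: "Lower Texas Coast",
    8: "Rolling/High Plains",
}

NOT_OBSERVED = 9

# (lon_min, lat_min, lon_max, lat_max) base rectangles; gaps of >= 0.3 deg
# between neighbours so a small seed jitter cannot create overlap.
_BASE_BOXES = {
    1: (-100.4, 27.0, -98.9, 28.8),
    2: (-92.0, 32.0, -89.8, 35.5),
    3: (-94.5, 29.3, -91.5, 30.3),
    4: (-97.3, 28.2, -95.0, 29.2),
    5: (-97.5, 33.0, -94.5, 35.0),
    6: (-104.0, 24.5, -99.8, 26.2),
    7: (-98.6, 26.4, -97.2, 27.8),
    8: (-102.5, 34.0, -99.5, 36.5),
}

_MAX_JITTER = 0.10  # deg; strictly less than half the minimum inter-box gap


@dataclass
class RegionMap:
    """Ordered set of the eight wintering-region polygons."""

    polygons: dict[int, Polygon] = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = sorted(self.polygons)
        if codes != list(range(1, 9)):
            raise ValueError(f"expected region codes 1-8 exactly once, got {codes}")

    def locate(self, lon: float, lat: float) -> int:
        """Region code containing the point; 5 ("Other") if outside all.

        A point exactly on a shared boundary resolves to the lowest code.
        """
        pt = Point(lon, lat)
        for code in range(1, 9):
            poly = self.polygons[code]
            if poly.contains(pt) or poly.touches(pt):
                return code
        return 5

    def locate_many(self, lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
        """Vector ``locate`` using rectangle bounds (fast path for rectangles)."""
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        out = np.full(lons.shape, 5, dtype=int)
        unset = np.ones(lons.shape, dtype=bool)
        for code in range(1, 9):
            x0, y0, x1, y1 = self.polygons[code].bounds
            inside = (lons >= x0) & (lons <= x1) & (lats >= y0) & (lats <= y1)
            out[inside & unset] = code
            unset &= ~inside
        return out

    def bounds(self, code: int) -> tuple[float, float, float, float]:
        return self.polygons[code].bounds

    def to_geojson(self) -> dict:
        features = []
        for code in range(1, 9):
            features.append(
                {
                    "type": "Feature",
                    "properties": {"code": code, "name": REGION_NAMES[code]},
                    "geometry": mapping(self.polygons[code]),
                }
            )
        return {"type": "FeatureCollection", "features": features}

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_geojson(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RegionMap":
        with open(path) as fh:
            gj = json.load(fh)
        polys = {
            int(f["properties"]["code"]): shape(f["geometry"])
            for f in gj["features"]
        }
        return cls(polys)


def simulate_regions(layout_seed: int = 0) -> RegionMap:
    """Build the eight-region map, jittering rectangle corners by the seed.

    The jitter is bounded well below half the smallest gap between base
    rectangles, so the polygons are pairwise disjoint by construction for
    every seed, and the same seed always yields identical geometry.
    """
    rng = np.random.default_rng(layout_seed)
    polys: dict[int, Polygon] = {}
    for code in range(1, 9):
        x0, y0, x1, y1 = _BASE_BOXES[code]
        jit = rng.uniform(-_MAX_JITTER, _MAX_JITTER, size=4)
        x0, y0, x1, y1 = x0 + jit[0], y0 + jit[1], x1 + jit[2], y1 + jit[3]
        polys[code] = Polygon(
            [(x0, y0), (x1, y0), (x1, y1), (x0, y1), (x0, y0)]
        )
    return RegionMap(polys)
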