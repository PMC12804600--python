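"""Maze and arena geometry.

The Y-maze has three 30-cm arms joined by a central hub. Arms 1 and 2 carry
waterspouts at their distal ends (alternating reward); arm 3 is the empty arm.
Coordinates are in cm, origin at the maze centroid, y-up. Region polygons are
pairwise interior-disjoint and their union is the maze footprint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

# Arm axis angles (degrees, CCW from +x). Arms 1/2 are the reward arms.
ARM_ANGLES = {"arm1": 150.0, "arm2": 30.0, "arm3": 270.0}

REGION_NAMES = ("arm1", "arm2", "arm3", "center")
ZONE5_NAMES = ("reward1", "arm1_path", "hub", "arm2_path", "reward2")
PHASE_NAMES = ("starting", "central", "terminal")

GEOMETRY_FORMAT_VERSION = 1


def _unit(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([np.cos(a), np.sin(a)])


@dataclass
class MazeGeometry:
    """Planar region decomposition of the Y-maze.

    Attributes
    ----------
    regions : dict
        4-region division {arm1, arm2, arm3, center} used for position tuning.
    zones5 : dict
        5-zone division {reward1, arm1_path, hub, arm2_path, reward2} used by
        the zone classifier.
    reward_zones : dict
        Polygons at the distal ends of arm1/arm2 where water is delivered.
    spouts : dict
        Waterspout (x, y) per reward arm.
    arm_length : float
        Arm length in cm (nominally 30).
    """

    regions: dict[str, Polygon]
    zones5: dict[str, Polygon]
    reward_zones: dict[str, Polygon]
    spouts: dict[str, tuple[float, float]]
    arm_length: float = 30.0
    arm_half_width: float = 3.0
    hub_radius: float = 4.0
    meta: dict = field(default_factory=dict)

    def assign(self, x: np.ndarray, y: np.ndarray, zones: bool = False) -> np.ndarray:
        """Assign each (x, y) point to a region (or 5-zone) label.

        Boundary points go to the first-listed region containing them
        (deterministic tie-break); points outside every region get ``'none'``.
        """
        names = ZONE5_NAMES if zones else REGION_NAMES
        polys = self.zones5 if zones else self.regions
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.full(x.shape, "none", dtype=object)
        unassigned = np.ones(x.shape, dtype=bool)
        for name in names:
            hit = unassigned & shapely.intersects_xy(polys[name], x, y)
            out[hit] = name
            unassigned &= ~hit
        return out.astype("U10")

    def in_reward_zone(self, x, y, arm: str) -> np.ndarray:
        return shapely.intersects_xy(self.reward_zones[arm], np.asarray(x, float), np.asarray(y, float))

    def arm_axis(self, arm: str) -> np.ndarray:
        return _unit(ARM_ANGLES[arm])

    def centerline_point(self, arm: str, dist_from_origin: float) -> np.ndarray:
        """Point on the arm centerline at a given radial distance from origin."""
        return self.arm_axis(arm) * dist_from_origin

    def validate(self) -> None:
        for group in (self.regions, self.zones5):
            names = list(group)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    inter = group[a].intersection(group[b])
                    if inter.area > 1e-6:
                        raise ValueError(f"regions {a} and {b} overlap (area {inter.area:.3g})")
        for arm, rz in self.reward_zones.items():
            if not self.regions[arm].buffer(1e-9).contains(rz):
                raise ValueError(f"reward zone of {arm} is not inside {arm}")
        cover4 = unary_union(list(self.regions.values()))
        cover5 = unary_union(list(self.zones5.values()))
        if abs(cover4.area - cover5.area) > 1e-6:
            raise ValueError("4-region and 5-zone divisions cover different footprints")

    # ------------------------------------------------------------------ io
    def to_json(self, path) -> None:
        def coords(p: Polygon):
            return [[float(a), float(b)] for a, b in np.asarray(p.exterior.coords)]

        payload = {
            "format_version": GEOMETRY_FORMAT_VERSION,
            "arm_length": self.arm_length,
            "arm_half_width": self.arm_half_width,
            "hub_radius": self.hub_radius,
            "regions": {k: coords(v) for k, v in self.regions.items()},
            "zones5": {k: coords(v) for k, v in self.zones5.items()},
            "reward_zones": {k: coords(v) for k, v in self.reward_zones.items()},
            "spouts": {k: list(map(float, v)) for k, v in self.spouts.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "MazeGeometry":
        with open(path) as fh:
            payload = json.load(fh)
        version = payload.get("format_version")
        if version != GEOMETRY_FORMAT_VERSION:
            raise ValueError(
                f"geometry format version mismatch: file has {version!r}, "
                f"expected {GEOMETRY_FORMAT_VERSION}"
            )
        return cls(
            regions={k: Polygon(v) for k, v in payload["regions"].items()},
            zones5={k: Polygon(v) for k, v in payload["zones5"].items()},
            reward_zones={k: Polygon(v) for k, v in payload["reward_zones"].items()},
            spouts={k: tuple(v) for k, v in payload["spouts"].items()},
            arm_length=payload["arm_length"],
            arm_half_width=payload["arm_half_width"],
            hub_radius=payload["hub_radius"],
        )


def ymaze_geometry(
    arm_length: float = 30.0,
    arm_half_width: float = 3.0,
    hub_radius: float = 4.0,
    reward_zone_length: float = 6.0,
    reward_zone_5z_length: float = 10.0,
) -> MazeGeometry:
    """Build the canonical Y-maze geometry.

    Each arm is a rectangle of length ``arm_length`` starting ``hub_radius`` cm
    from the origin along its axis; the central hub is the hexagon spanned by
    the arms' inner edges.
    """
    arms: dict[str, Polygon] = {}
    inner_corners = []
    for name, ang in ARM_ANGLES.items():
        u = _unit(ang)
        v = np.array([-u[1], u[0]])
        p0 = hub_radius * u + arm_half_width * v
        p1 = hub_radius * u - arm_half_width * v
        p2 = (hub_radius + arm_length) * u - arm_half_width * v
        p3 = (hub_radius + arm_length) * u + arm_half_width * v
        arms[name] = Polygon([p0, p1, p2, p3])
        inner_corners.extend([p0, p1])
    # hub = convex hull of the six inner arm corners
    center = Polygon(inner_corners).convex_hull

    def distal(arm: str, length: float) -> Polygon:
        u = _unit(ARM_ANGLES[arm])
        v = np.array([-u[1], u[0]])
        a = hub_radius + arm_length - length
        b = hub_radius + arm_length
        return Polygon(
            [a * u + arm_half_width * v, a * u - arm_half_width * v,
             b * u - arm_half_width * v, b * u + arm_half_width * v]
        )

    regions = {"arm1": arms["arm1"], "arm2": arms["arm2"], "arm3": arms["arm3"], "center": center}
    reward_zones = {"arm1": distal("arm1", reward_zone_length), "arm2": distal("arm2", reward_zone_length)}
    zones5 = {
        "reward1": distal("arm1", reward_zone_5z_length),
        "arm1_path": arms["arm1"].difference(distal("arm1", reward_zone_5z_length)),
        "hub": unary_union([center, arms["arm3"]]),
        "arm2_path": arms["arm2"].difference(distal("arm2", reward_zone_5z_length)),
        "reward2": distal("arm2", reward_zone_5z_length),
    }
    spout_dist = hub_radius + arm_length - 1.0
    spouts = {arm: tuple(_unit(ARM_ANGLES[arm]) * spout_dist) for arm in ("arm1", "arm2")}
    geom = MazeGeometry(
        regions=regions, zones5=zones5, reward_zones=reward_zones, spouts=spouts,
        arm_length=arm_length, arm_half_width=arm_half_width, hub_radius=hub_radius,
    )
    geom.validate()
    return geom


def openfield_geometry(side: float = 40.0, center_fraction: float = 0.5) -> dict:
    """Open-field arena: a ``side`` x ``side`` square with a central zone.

    The anxiety-related center zone is the central square with half the linear
    dimension (20x20 cm for a 40-cm arena) by convention.
    """
    half = side / 2.0
    c = side * center_fraction / 2.0
    return {
        "side": side,
        "bounds": Polygon([(-half, -half), (half, -half), (half, half), (-half, half)]),
        "center": Polygon([(-c, -c), (c, -c), (c, c), (-c, c)]),
    }
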