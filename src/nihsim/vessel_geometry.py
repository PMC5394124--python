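"""Discretized graft geometry and growth-to-geometry bookkeeping.

A graft is an acyclic tree of named segments; each segment is an ordered
list of axial stations carrying a lumen radius, an axial extent, tags
(anastomosis, bifurcation, inlet/outlet, ...) and, once a simulation is
initialized, a biochemical wall patch.  Intimal volume produced by the
wall kinetics is laid down as an axisymmetric inward ring over the
station length, shrinking the lumen; occlusion and restenosis metrics
compare cross-sectional areas against the post-surgery baseline.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "Station",
    "VesselTree",
    "apply_growth",
    "occlusion_percentage",
    "detect_restenosis",
    "DEFAULT_RADIUS_FLOOR",
]

#: default lumen-radius floor [m] below which a station counts as occluded
DEFAULT_RADIUS_FLOOR = 1e-4  # 0.1 mm


@dataclass
class Station:
    """One axial station of a vessel segment (the model's "node")."""

    id: str
    z: float                 # axial position [m]
    radius: float            # lumen radius [m]
    length: float            # axial extent [m]
    tags: tuple = ()
    wall: object = None      # WallState once initialized
    capacity: object = None  # LayerCapacity once initialized
    occluded: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"station {self.id}: radius must be > 0")
        if self.length <= 0:
            raise ValueError(f"station {self.id}: length must be > 0")
        self.tags = tuple(self.tags)

    @property
    def cross_section(self) -> float:
        """Lumen cross-sectional area [m^2]."""
        return float(np.pi * self.radius ** 2)

    @property
    def lateral_area(self) -> float:
        """Lumen lateral (wall) surface area [m^2]."""
        return float(2.0 * np.pi * self.radius * self.length)


@dataclass
class VesselTree:
    """Segments + connectivity of a discretized graft.

    ``segments`` maps segment name to its ordered station list;
    ``connectivity`` maps parent segment to child segments.  Terminal
    segments are the outlets; their names double as outlet ids for the
    Windkessel network.
    """

    segments: dict[str, list[Station]]
    connectivity: dict[str, list[str]] = field(default_factory=dict)
    inlet: str | None = None

    def __post_init__(self) -> None:
        if self.inlet is None and self.segments:
            children = {c for cs in self.connectivity.values() for c in cs}
            roots = [s for s in self.segments if s not in children]
            if len(roots) == 1:
                self.inlet = roots[0]
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        if not self.segments:
            raise ValueError("tree has no segments")
        children = [c for cs in self.connectivity.values() for c in cs]
        if len(children) != len(set(children)):
            raise ValueError("a segment has more than one parent")
        for parent, cs in self.connectivity.items():
            if parent not in self.segments:
                raise ValueError(f"unknown parent segment {parent!r}")
            for c in cs:
                if c not in self.segments:
                    raise ValueError(f"unknown child segment {c!r}")
        roots = [s for s in self.segments if s not in set(children)]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one inlet segment, found {roots}")
        if self.inlet != roots[0]:
            raise ValueError("declared inlet does not match tree root")
        # acyclicity: walk from root, every segment must be reached once
        seen: list[str] = []
        stack = [self.inlet]
        while stack:
            s = stack.pop()
            if s in seen:
                raise ValueError(f"cycle detected at segment {s!r}")
            seen.append(s)
            stack.extend(self.connectivity.get(s, []))
        if set(seen) != set(self.segments):
            raise ValueError("disconnected segments present")
        if not self.outlet_ids:
            raise ValueError("tree has no outlets")
        ids = [st.id for st in self.stations()]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate station ids")

    @property
    def outlet_ids(self) -> list[str]:
        """Terminal segment names, in deterministic order."""
        return [s for s in self.segments if not self.connectivity.get(s)]

    @property
    def inlet_radius(self) -> float:
        return self.segments[self.inlet][0].radius

    def stations(self) -> Iterator[Station]:
        for stations in self.segments.values():
            yield from stations

    def station(self, station_id: str) -> Station:
        for st in self.stations():
            if st.id == station_id:
                return st
        raise KeyError(station_id)

    def segment_flow_fractions(self, outlet_fractions: Mapping[str, float]) -> dict[str, float]:
        """Fraction of the inlet flow carried by each segment: the sum of
        the outlet fractions reachable downstream (mass conservation at
        every bifurcation)."""
        frac: dict[str, float] = {}

        def walk(seg: str) -> float:
            kids = self.connectivity.get(seg, [])
            f = sum(walk(k) for k in kids) if kids else outlet_fractions[seg]
            frac[seg] = f
            return f

        walk(self.inlet)
        return frac

    def copy(self) -> "VesselTree":
        return copy.deepcopy(self)


def apply_growth(station: Station, dV_i: float,
                 floor: float = DEFAULT_RADIUS_FLOOR) -> Station:
    """Shrink a station's lumen by laying ``dV_i`` m^3 of new intimal
    tissue as an axisymmetric inward ring over the station length.

    ``r' = sqrt(r^2 - dV_i/(pi*length))``; the ring volume
    ``pi*(r^2 - r'^2)*length`` equals ``dV_i`` exactly.  A radius that
    would fall below ``floor`` is clamped there and the station flagged
    occluded (negative increments up to the current lumen volume are
    allowed, widening the lumen).
    """
    lumen_volume = np.pi * station.radius ** 2 * station.length
    if dV_i < -lumen_volume:
        raise ValueError(f"station {station.id}: negative growth exceeds lumen volume")
    if dV_i == 0.0:
        return station
    r_sq = station.radius ** 2 - dV_i / (np.pi * station.length)
    if r_sq <= floor ** 2:
        station.radius = floor
        station.occluded = True
    else:
        station.radius = float(np.sqrt(r_sq))
    return station


def occlusion_percentage(initial_area: float, final_area: float) -> float:
    """Percent lumen occlusion,
    ``100 * (initial area - final area) / initial area``."""
    if initial_area <= 0:
        raise ValueError("initial cross-sectional area must be > 0")
    if final_area < 0:
        raise ValueError("final cross-sectional area must be >= 0")
    if final_area > initial_area * (1 + 1e-12):
        raise ValueError("final area exceeds initial area (negative growth?)")
    return 100.0 * (initial_area - final_area) / initial_area


def detect_restenosis(tree0: VesselTree, tree: VesselTree,
                      threshold: float = 50.0) -> list[tuple[str, float]]:
    """Stations whose cross-sectional area loss meets the restenosis
    threshold (default 50% luminal narrowing).

    Returns ``(station id, occlusion %)`` pairs; the two trees must
    share topology and station ids.
    """
    st0 = list(tree0.stations())
    st1 = list(tree.stations())
    if len(st0) != len(st1) or any(a.id != b.id for a, b in zip(st0, st1)):
        raise ValueError("trees differ in topology or station ids")
    hits = []
    for a, b in zip(st0, st1):
        occ = occlusion_percentage(a.cross_section, min(b.cross_section, a.cross_section))
        if occ >= threshold:
            hits.append((a.id, occ))
    return hits
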