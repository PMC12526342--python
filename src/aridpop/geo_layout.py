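"""Flower-expansion layout for overlapping per-sample map markers.

Samples collected at identical or near-identical GPS coordinates would
plot on top of each other; this layout groups points whose pairwise
distance is within a small epsilon (by transitive closure), then displaces
each group's members onto a circle ("petals") around the group centroid,
keeping the centroid exactly at the mean of the original positions.
Displacements are tiny relative to a degree, so plain Euclidean geometry
on decimal degrees is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .io_core import SampleMeta, ValidationError


@dataclass
class LayoutPoint:
    sample_id: str
    lat: float
    lon: float
    display_lat: float
    display_lon: float
    cluster_center: bool = False  # member of a displaced (multi-point) group


def flower_expand(points: list[SampleMeta], epsilon_deg: float = 1e-4,
                  petal_radius_deg: float = 5e-3) -> list[LayoutPoint]:
    """Displace co-located points onto circles around their group centroids.

    Groups are connected components of the "within epsilon" graph. A group
    of size m >= 2 is placed at angles 2*pi*k/m (k ordered by sample_id,
    angle 0 pointing north, proceeding clockwise) on a circle whose radius
    grows as petal_radius * (1 + (m - 7)/14) once m exceeds 7, so petals
    never collide. Singletons keep their original position. Output order
    follows input order regardless of grouping.
    """
    if epsilon_deg <= 0 or petal_radius_deg <= 0:
        raise ValidationError("epsilon and petal radius must be positive")
    pts = [(m.sample_id, m.latitude, m.longitude) for m in points]
    for sid, lat, lon in pts:
        if lat is None or lon is None:
            raise ValidationError(f"sample {sid!r} lacks coordinates")
    g = nx.Graph()
    g.add_nodes_from(sid for sid, _, _ in pts)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.hypot(pts[i][1] - pts[j][1], pts[i][2] - pts[j][2])
            if d <= epsilon_deg:
                g.add_edge(pts[i][0], pts[j][0])

    coords = {sid: (lat, lon) for sid, lat, lon in pts}
    display: dict[str, tuple[float, float, bool]] = {}
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) == 1:
            sid = members[0]
            lat, lon = coords[sid]
            display[sid] = (lat, lon, False)
            continue
        m = len(members)
        clat = sum(coords[s][0] for s in members) / m
        clon = sum(coords[s][1] for s in members) / m
        radius = petal_radius_deg
        if m > 7:
            radius *= 1.0 + (m - 7) / 14.0
        for k, sid in enumerate(members):
            theta = 2.0 * math.pi * k / m
            # angle 0 = north (+lat), clockwise => east (+lon) at pi/2
            display[sid] = (clat + radius * math.cos(theta),
                            clon + radius * math.sin(theta), True)
    return [
        LayoutPoint(sid, lat, lon, *display[sid])
        for sid, lat, lon in pts
    ]
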