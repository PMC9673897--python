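"""Street-block spatial units from linear and boundary features.

Roads, railways, waterways, land-use outlines and the extent boundary are
noded and polygonised into faces; oversized faces on the urban fringe are
further subdivided with residential-area outlines; sub-hectare faces are
merged into neighbours; and extents that end up with fewer than 30 units
are discarded as not meaningfully urban.

All functions here assume planar metric coordinates (metres).  The pipeline
projects geographic inputs into a per-extent local plane before calling in,
and unprojects the finished units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import shapely
from shapely.geometry import LineString, MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import polygonize, unary_union
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

DEFAULT_FRINGE_AREA_M2 = 100_000.0
DEFAULT_MIN_UNIT_AREA_M2 = 10_000.0  # 1 hectare
DEFAULT_MIN_UNITS_PER_EXTENT = 30

#: Settlement-extent classes whose boundaries mark the urban fringe.
FRINGE_SETTLEMENT_TYPES = ("BUA", "SSA")


@dataclass
class FeatureSet:
    """Linear and boundary features used to cut street blocks."""

    lines: List[BaseGeometry] = field(default_factory=list)
    boundary_polygons: List[BaseGeometry] = field(default_factory=list)
    residential_polygons: List[BaseGeometry] = field(default_factory=list)


@dataclass
class SettlementExtent:
    geometry: BaseGeometry
    stype: str  # "BUA", "SSA" or "hamlet"

    def __post_init__(self) -> None:
        if self.stype not in ("BUA", "SSA", "hamlet"):
            raise ValueError(f"unknown settlement type {self.stype!r}")


@dataclass
class SpatialUnit:
    uext_ID: str
    unit_id: int
    geometry: BaseGeometry
    unit_area: float  # m²


def _faces_from_edges(edges: BaseGeometry, clip: BaseGeometry) -> List[Polygon]:
    """Polygonise noded edges and keep faces inside *clip*, fixing islands.

    ``polygonize`` emits nested rings (a land-use island floating inside a
    block) as overlapping full polygons; contained faces are punched out of
    their host so the result is a true partition.
    """
    faces = [f for f in polygonize(edges) if clip.contains(f.representative_point())]
    if len(faces) > 1:
        tree = STRtree(faces)
        adjusted: List[Polygon] = []
        for i, face in enumerate(faces):
            inner = [
                faces[j]
                for j in tree.query(face, predicate="contains_properly")
                if j != i
            ]
            if inner:
                face = face.difference(unary_union(inner))
            adjusted.append(face)
        faces = adjusted
    out: List[Polygon] = []
    for face in faces:
        if face.is_empty:
            continue
        if isinstance(face, MultiPolygon):
            out.extend(face.geoms)
        else:
            out.append(face)
    return out


def polygonize_features(features: FeatureSet, extent: BaseGeometry) -> List[Polygon]:
    """Node all features with the extent boundary and cut it into faces.

    The faces partition the extent exactly: the extent boundary is part of
    the noded arrangement, and a face belongs to the extent iff its
    representative point does.  Boundary land-use polygons contribute their
    outlines, so e.g. an airport becomes its own face.
    """
    edges = [extent.boundary]
    edges.extend(g for g in features.lines if not g.is_empty)
    edges.extend(g.boundary for g in features.boundary_polygons if not g.is_empty)
    noded = unary_union(edges)  # unions also node crossing lines
    return _faces_from_edges(noded, extent)


def flag_fringe_polygons(
    polygons: Sequence[Polygon],
    settlements: Sequence[SettlementExtent],
    min_area_m2: float = DEFAULT_FRINGE_AREA_M2,
) -> List[int]:
    """Indices of faces on the urban fringe needing further subdivision.

    A face qualifies if it is larger than ``min_area_m2`` AND its geometry
    crosses the boundary curve of a built-up or small settled area (hamlets
    are ignored).  A large face strictly inside a settlement does not
    qualify: only the boundary crossing marks the fringe.
    """
    boundaries = [
        s.geometry.boundary for s in settlements if s.stype in FRINGE_SETTLEMENT_TYPES
    ]
    if not boundaries:
        return []
    boundary_union = unary_union(boundaries)
    return [
        i
        for i, p in enumerate(polygons)
        if p.area > min_area_m2 and p.intersects(boundary_union)
    ]


def subdivide_with_residential(
    polygon: Polygon,
    residential_polygons: Sequence[BaseGeometry],
) -> List[Polygon]:
    """Re-cut a fringe face with residential-area outlines as extra edges.

    Residential data is optional; when no residential polygon intersects
    the face it is returned unchanged.
    """
    relevant = [r for r in residential_polygons if r.intersects(polygon)]
    if not relevant:
        return [polygon]
    edges = [polygon.boundary] + [r.boundary for r in relevant]
    return _faces_from_edges(unary_union(edges), polygon)


def merge_small_units(
    polygons: Sequence[Polygon],
    min_area_m2: float = DEFAULT_MIN_UNIT_AREA_M2,
) -> List[Polygon]:
    """Iteratively dissolve sub-threshold faces into neighbours.

    The smallest face under the threshold is merged into the neighbour
    sharing the longest common boundary (ties: larger neighbour area, then
    lowest stable id), repeating until every face meets the minimum area or
    a single face remains.  Total area is conserved.  A sub-threshold face
    with no line-sharing neighbour is kept with a warning.
    """
    work: Dict[int, Polygon] = {i: p for i, p in enumerate(polygons)}
    stranded: set[int] = set()
    while len(work) > 1:
        candidates = [
            (p.area, i)
            for i, p in work.items()
            if p.area < min_area_m2 and i not in stranded
        ]
        if not candidates:
            break
        _, small_id = min(candidates)
        small = work[small_id]
        best: Optional[Tuple[float, float, int]] = None
        for j, q in work.items():
            if j == small_id:
                continue
            shared = small.intersection(q).length
            if shared <= 0:
                continue
            key = (shared, q.area, -j)  # longest boundary, then larger, then low id
            if best is None or key > best:
                best = key
        if best is None:
            logger.warning(
                "sub-threshold face %d (%.1f m²) has no neighbour; keeping it",
                small_id,
                small.area,
            )
            stranded.add(small_id)
            continue
        target_id = -best[2]
        work[target_id] = unary_union([work[target_id], small])
        del work[small_id]
    return [work[i] for i in sorted(work)]


def filter_small_extents(
    units_by_extent: Dict[str, List[Polygon]],
    min_units: int = DEFAULT_MIN_UNITS_PER_EXTENT,
) -> Dict[str, List[Polygon]]:
    """Drop extents with fewer than *min_units* spatial units."""
    kept: Dict[str, List[Polygon]] = {}
    for uext_id, units in units_by_extent.items():
        if len(units) < min_units:
            logger.info(
                "excluding urban extent %s: %d units < %d", uext_id, len(units), min_units
            )
            continue
        kept[uext_id] = units
    return kept


def build_units_for_extent(
    extent: BaseGeometry,
    features: FeatureSet,
    settlements: Sequence[SettlementExtent],
    fringe_area_m2: float = DEFAULT_FRINGE_AREA_M2,
    min_unit_area_m2: float = DEFAULT_MIN_UNIT_AREA_M2,
) -> List[Polygon]:
    """Polygonise, subdivide fringe faces, and enforce the area minimum."""
    faces = polygonize_features(features, extent)
    fringe = set(flag_fringe_polygons(faces, settlements, fringe_area_m2))
    expanded: List[Polygon] = []
    for i, face in enumerate(faces):
        if i in fringe:
            expanded.extend(
                subdivide_with_residential(face, features.residential_polygons)
            )
        else:
            expanded.append(face)
    return merge_small_units(expanded, min_unit_area_m2)
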