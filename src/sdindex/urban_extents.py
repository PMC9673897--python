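"""Urban-extent delineation from a settlement-model raster and urban centres.

The settlement-model grid (~1 km cells) classifies cells as water (10),
rural (11–13), peri-urban/urban cluster (21–23) or urban centre (30).
Extents are built by: keeping quality-flagged urban centres, reclassifying
classes 21–30 to a binary urban mask, taking 8-connected components of
urban cells that touch a centre polygon, buffering each component by 3 km,
wrapping it in a convex hull, merging overlapping hulls to a fixpoint and
clipping to the national land polygon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import Point, Polygon, box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .errors import InputError
from .projection import LocalProjector
from .raster import Raster

logger = logging.getLogger(__name__)

#: Settlement-model classes reclassified to "urban" (peri-urban .. urban centre).
URBAN_CLASS_RANGE = (21, 30)
DEFAULT_BUFFER_M = 3000.0


@dataclass
class UrbanCentre:
    """An urban-centre record with its quality flag and footprint polygon."""

    point: Point
    polygon: Polygon
    qa_flag: Optional[int]
    name: str
    country_iso3: str


@dataclass
class UrbanExtent:
    uext_ID: str
    adm0_ISO3: str
    geometry: BaseGeometry


def select_centres(centres: Sequence[UrbanCentre]) -> List[UrbanCentre]:
    """Keep only centres flagged as true positives (quality flag == 1)."""
    for c in centres:
        if c.qa_flag is None:
            raise InputError(f"urban centre {c.name!r} has no quality flag")
    return [c for c in centres if c.qa_flag == 1]


def reclassify_urban(grid: Raster) -> np.ndarray:
    """Binary mask of urban cells: settlement class in [21, 30]; nodata -> 0."""
    lo, hi = URBAN_CLASS_RANGE
    values = grid.values
    mask = (values >= lo) & (values <= hi) & grid.mask()
    return mask.astype(np.uint8)


def contiguous_urban_components(
    urban: np.ndarray,
    grid: Raster,
    centres: Sequence[UrbanCentre],
) -> List[Tuple[np.ndarray, List[UrbanCentre]]]:
    """8-connected components of urban cells that touch >=1 centre polygon.

    Returns ``(component_mask, touching_centres)`` pairs, ordered by first
    touching centre then component label for a stable, deterministic output.
    Components touching no centre are dropped.
    """
    structure = np.ones((3, 3), dtype=int)  # queen contiguity
    labels, n = ndimage.label(np.asarray(urban, dtype=np.uint8), structure=structure)
    if n == 0:
        return []
    touched: dict[int, List[UrbanCentre]] = {}
    order: List[int] = []
    for centre in centres:
        poly = centre.polygon
        xmin, ymin, xmax, ymax = poly.bounds
        r0, c0 = grid.index(xmin, ymax)
        r1, c1 = grid.index(xmax, ymin)
        r0, r1 = max(r0, 0), min(r1, grid.height - 1)
        c0, c1 = max(c0, 0), min(c1, grid.width - 1)
        for r in range(r0, r1 + 1):
            for c in range(c0, c1 + 1):
                lbl = labels[r, c]
                if lbl == 0:
                    continue
                if poly.intersects(box(*grid.cell_bounds(r, c))):
                    if lbl not in touched:
                        touched[lbl] = []
                        order.append(lbl)
                    if centre not in touched[lbl]:
                        touched[lbl].append(centre)
    return [(labels == lbl, touched[lbl]) for lbl in order]


def component_polygon(component: np.ndarray, grid: Raster) -> BaseGeometry:
    """Dissolve a component's cells into a polygon in the grid's CRS."""
    rows, cols = np.nonzero(component)
    cells = [box(*grid.cell_bounds(r, c)) for r, c in zip(rows, cols)]
    return unary_union(cells)


def buffer_and_hull(
    component_poly: BaseGeometry,
    crs: str,
    buffer_m: float = DEFAULT_BUFFER_M,
) -> BaseGeometry:
    """Buffer a component polygon by a metric distance, then take its hull.

    Buffering is done in a local azimuthal-equidistant plane centred on the
    component centroid when the CRS is geographic; the hull is returned in
    the world CRS.
    """
    if buffer_m < 0:
        raise ValueError(f"buffer must be non-negative, got {buffer_m}")
    if component_poly.is_empty:
        raise InputError("cannot buffer an empty component")
    proj = LocalProjector.for_geometry(component_poly, crs)
    local = proj.to_local(component_poly)
    hull = local.buffer(buffer_m).convex_hull
    return proj.to_world(hull)


def merge_overlapping_hulls(hulls: Sequence[BaseGeometry]) -> List[BaseGeometry]:
    """Merge hulls whose interiors overlap, iterating to a fixpoint.

    Overlap groups are closed transitively (union-find semantics) and each
    group is replaced by the convex hull of its union; because a merged hull
    can grow to overlap others, the pass repeats until all outputs are
    pairwise interior-disjoint.
    """
    current = [h for h in hulls if not h.is_empty]
    while True:
        n = len(current)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        merged_any = False
        for i in range(n):
            for j in range(i + 1, n):
                inter = current[i].intersection(current[j])
                if inter.area > 0:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
                        merged_any = True
        if not merged_any:
            return current
        groups: dict[int, List[BaseGeometry]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(current[i])
        current = [
            unary_union(members).convex_hull if len(members) > 1 else members[0]
            for _, members in sorted(groups.items())
        ]


def clip_extents(
    hulls: Sequence[BaseGeometry],
    admin_boundary: BaseGeometry,
    water: Optional[BaseGeometry] = None,
) -> List[BaseGeometry]:
    """Clip hulls to the national land polygon (admin minus water mask).

    The coastline enters as a pre-polygonised water mask subtracted from the
    administrative polygon.  Empty (fully offshore) results are dropped;
    invalid intersections are repaired with ``make_valid``.
    """
    if not admin_boundary.is_valid:
        admin_boundary = shapely.make_valid(admin_boundary)
    land = admin_boundary if water is None else admin_boundary.difference(water)
    out: List[BaseGeometry] = []
    for hull in hulls:
        clipped = hull.intersection(land)
        if not clipped.is_valid:
            logger.warning("repairing invalid geometry produced by clipping")
            clipped = shapely.make_valid(clipped)
        if clipped.is_empty or clipped.area == 0:
            logger.info("dropping extent fully outside the land polygon")
            continue
        out.append(clipped)
    return out


def assign_extent_ids(
    geometries: Sequence[BaseGeometry], iso3: str
) -> List[UrbanExtent]:
    """Wrap geometries as UrbanExtents with stable IDs.

    IDs are ``{ISO3}{nnnn}`` assigned in (latitude, longitude) order of the
    extent centroid so reruns on identical inputs number identically.
    """
    order = sorted(
        range(len(geometries)),
        key=lambda i: (geometries[i].centroid.y, geometries[i].centroid.x),
    )
    extents = [None] * len(geometries)
    for seq, i in enumerate(order, start=1):
        extents[i] = UrbanExtent(f"{iso3}{seq:04d}", iso3, geometries[i])
    return list(extents)


def delineate_urban_extents(
    grid: Raster,
    centres: Sequence[UrbanCentre],
    admin_boundary: BaseGeometry,
    water: Optional[BaseGeometry] = None,
    buffer_m: float = DEFAULT_BUFFER_M,
    iso3: str = "XXX",
) -> List[UrbanExtent]:
    """Full extent-delineation stage; see module docstring for the steps."""
    selected = select_centres(centres)
    if not selected:
        return []
    urban = reclassify_urban(grid)
    components = contiguous_urban_components(urban, grid, selected)
    hulls = [
        buffer_and_hull(component_polygon(mask, grid), grid.crs, buffer_m)
        for mask, _ in components
    ]
    merged = merge_overlapping_hulls(hulls)
    clipped = clip_extents(merged, admin_boundary, water)
    return assign_extent_ids(clipped, iso3)
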