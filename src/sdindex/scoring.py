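"""Per-unit metrics, scores and the ease-of-social-distancing index.

For each street-block unit the pipeline computes the fraction of its area
covered by building footprints (built score, 0–10 in 10% bins) and the mean
population density over grid cells whose centroids fall inside it
(population score, 0–10 against the hexagonal-spacing thresholds).  The
index is the mean of the two scores; −99 marks units where population data
is missing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .errors import InputError
from .projection import LocalProjector
from .raster import Raster
from .spatial_units import SpatialUnit
from .thresholds import SpacingThresholdTable, build_threshold_table

logger = logging.getLogger(__name__)

NODATA = -99
_BIN_EPS = 1e-12  # guards 10*prop float noise at exact bin edges


@dataclass
class ScoreRecord:
    """One output row per spatial unit; field names follow the published schema."""

    uext_ID: str
    adm0_ISO3: str
    UNIT_AREA: float   # m²
    BUILT_AREA: float  # m²
    BUILT_PROP: float
    NBUILTPROP: float
    POP_DENS: float    # people/km², or -99
    BUILTscore: int
    POPscore: int      # 0-10, or -99
    INDEXvalue: float  # multiple of 0.5 in [0, 10], or -99
    geometry: Optional[BaseGeometry] = None
    unit_id: int = 0

    def to_attributes(self) -> dict:
        return {
            "uext_ID": self.uext_ID,
            "adm0_ISO3": self.adm0_ISO3,
            "UNIT_AREA": self.UNIT_AREA,
            "BUILT_AREA": self.BUILT_AREA,
            "BUILT_PROP": self.BUILT_PROP,
            "NBUILTPROP": self.NBUILTPROP,
            "POP_DENS": self.POP_DENS,
            "BUILTscore": self.BUILTscore,
            "POPscore": self.POPscore,
            "INDEXvalue": self.INDEXvalue,
        }


def density_raster(pop: Raster, area: Raster) -> Raster:
    """People/km² per cell: count raster divided by cell surface area (km²).

    Resolution is unchanged; nodata cells propagate.
    """
    if not pop.aligned_with(area):
        raise InputError("population and surface-area rasters are not aligned")
    counts = np.asarray(pop.values, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = counts / np.asarray(area.values, dtype=float)
    nodata = float(pop.nodata) if pop.nodata is not None else float(NODATA)
    dens = np.where(pop.mask() & area.mask(), dens, nodata)
    return Raster(dens, pop.transform, pop.crs, nodata)


def _bilinear_fallback(x: float, y: float, density: Raster) -> float:
    """Interpolated density at a point, from the 4 surrounding cell centres.

    Nodata neighbours are dropped with weight renormalisation.  Points in
    the outer half-cell margin clamp to the edge cells; points outside the
    raster footprint (or with all-nodata neighbours) return −99.
    """
    xmin, ymin, xmax, ymax = density.bounds
    if not (xmin <= x <= xmax and ymin <= y <= ymax):
        return NODATA
    xs, ys = density.cell_centroids()
    a, _, _, _, e, _ = density.transform
    fx = np.clip((x - xs[0]) / a, 0.0, len(xs) - 1.0)
    fy = np.clip((y - ys[0]) / e, 0.0, len(ys) - 1.0)  # e < 0; ys decreasing
    c0, r0 = int(math.floor(fx)), int(math.floor(fy))
    c1, r1 = min(c0 + 1, len(xs) - 1), min(r0 + 1, len(ys) - 1)
    tx, ty = fx - c0, fy - r0
    corners = ((r0, c0, (1 - tx) * (1 - ty)), (r0, c1, tx * (1 - ty)),
               (r1, c0, (1 - tx) * ty), (r1, c1, tx * ty))
    valid = density.mask()
    total_w = value = 0.0
    for r, c, w in corners:
        if w > 0 and valid[r, c]:
            total_w += w
            value += w * float(density.values[r, c])
    if total_w == 0.0:
        return NODATA
    return value / total_w


def zonal_mean_density(unit: BaseGeometry, density: Raster) -> float:
    """Mean density over cells whose centroid falls inside the unit.

    Units too small or thin to contain any cell centroid fall back to
    bilinear interpolation at the unit centroid; −99 when even the fallback
    has no data (unit outside the raster, or all neighbours nodata).
    """
    xs, ys = density.cell_centroids()
    xmin, ymin, xmax, ymax = unit.bounds
    ci = np.nonzero((xs >= xmin) & (xs <= xmax))[0]
    ri = np.nonzero((ys >= ymin) & (ys <= ymax))[0]
    if len(ci) and len(ri):
        gx, gy = np.meshgrid(xs[ci], ys[ri])
        inside = shapely.contains_xy(unit, gx.ravel(), gy.ravel()).reshape(gx.shape)
        if inside.any():
            window = density.values[np.ix_(ri, ci)]
            valid = density.mask()[np.ix_(ri, ci)] & inside
            if not valid.any():
                return NODATA
            return float(np.mean(window[valid]))
    centroid = unit.centroid
    return _bilinear_fallback(centroid.x, centroid.y, density)


def dissolve_footprints(footprints: Sequence[BaseGeometry]) -> BaseGeometry:
    """Union footprints so overlapping buildings are not double-counted."""
    cleaned = []
    for g in footprints:
        if g.is_empty:
            continue
        if not g.is_valid:
            g = shapely.make_valid(g)
            if g.is_empty:
                logger.warning("skipping unrepairable footprint")
                continue
        cleaned.append(g)
    return unary_union(cleaned) if cleaned else shapely.Polygon()


def built_metrics(
    unit: BaseGeometry,
    footprints: Sequence[BaseGeometry] | BaseGeometry,
    unit_area: Optional[float] = None,
):
    """(BUILT_AREA m², BUILT_PROP) for one unit.

    Footprints straddling the unit boundary contribute exactly their clipped
    share, so summing BUILT_AREA across adjacent units conserves building
    area.  Accepts a pre-dissolved footprint union to avoid rework.
    """
    union = (
        footprints
        if isinstance(footprints, BaseGeometry)
        else dissolve_footprints(footprints)
    )
    built = union.intersection(unit).area
    area = unit.area if unit_area is None else unit_area
    prop = 0.0 if area == 0 else min(built / area, 1.0)
    return built, prop


def classify_built(prop: float) -> int:
    """Built score 0–10 from the built-area fraction.

    0 for no buildings; otherwise decile bins with upper edges inclusive:
    (0, 0.10] → 1, (0.10, 0.20] → 2, …, (0.90, 1.0] → 10.
    """
    if not 0.0 <= prop <= 1.0 + _BIN_EPS:
        raise ValueError(f"built proportion must lie in [0, 1], got {prop}")
    if prop == 0.0:
        return 0
    return min(10, max(1, math.ceil(prop * 10.0 - _BIN_EPS)))


def classify_pop(
    density: float, table: Optional[SpacingThresholdTable] = None
) -> int:
    """Population score from mean density and the spacing-threshold table.

    −99 passes through; zero density scores 0; density at or above the
    densest threshold T(d_min) scores 10; bands [T(d), T(d−1)) take the
    score of apothem d; non-zero density below T(d_max) scores 1.
    Comparisons use unrounded thresholds.
    """
    if density == NODATA:
        return NODATA
    if density < 0:
        raise ValueError(f"density must be non-negative, got {density}")
    if table is None:
        table = build_threshold_table()
    if density == 0.0:
        return 0
    for row in table.rows:  # ascending apothem == descending density
        if density >= row.max_density:
            return row.pop_score
    return 1


def compute_index(built_score: int, pop_score: int) -> float:
    """Index value: mean of the two scores; −99 when population is missing."""
    if not 0 <= built_score <= 10:
        raise ValueError(f"built score out of range: {built_score}")
    if pop_score == NODATA:
        return float(NODATA)
    if not 0 <= pop_score <= 10:
        raise ValueError(f"population score out of range: {pop_score}")
    return (built_score + pop_score) / 2.0


def score_units(
    units: Sequence[SpatialUnit],
    footprints: Sequence[BaseGeometry],
    pop: Raster,
    area: Raster,
    table: Optional[SpacingThresholdTable] = None,
    iso3: str = "XXX",
    crs: str = "metric",
) -> List[ScoreRecord]:
    """Score every unit; deterministic ordering by (uext_ID, unit_id).

    Geometries and rasters share the world CRS; areas are measured in a
    local azimuthal-equidistant plane when that CRS is geographic.
    """
    if table is None:
        table = build_threshold_table()
    dens = density_raster(pop, area)
    union = dissolve_footprints(footprints)
    parts = [
        p
        for p in (union.geoms if union.geom_type.startswith("Multi") else [union])
        if not p.is_empty
    ]
    tree = STRtree(parts) if parts else None
    records: List[ScoreRecord] = []
    for unit in sorted(units, key=lambda u: (u.uext_ID, u.unit_id)):
        proj = LocalProjector.for_geometry(unit.geometry, crs)
        local_unit = proj.to_local(unit.geometry)
        unit_area = local_unit.area
        hits = (
            tree.query(unit.geometry, predicate="intersects")
            if tree is not None
            else []
        )
        built_area = sum(
            proj.to_local(parts[i].intersection(unit.geometry)).area for i in hits
        )
        prop = 0.0 if unit_area == 0 else min(built_area / unit_area, 1.0)
        pop_dens = zonal_mean_density(unit.geometry, dens)
        built_score = classify_built(prop)
        pop_score = classify_pop(pop_dens, table)
        records.append(
            ScoreRecord(
                uext_ID=unit.uext_ID,
                adm0_ISO3=iso3,
                UNIT_AREA=unit_area,
                BUILT_AREA=built_area,
                BUILT_PROP=prop,
                NBUILTPROP=1.0 - prop,
                POP_DENS=pop_dens,
                BUILTscore=built_score,
                POPscore=pop_score,
                INDEXvalue=compute_index(built_score, pop_score),
                geometry=unit.geometry,
                unit_id=unit.unit_id,
            )
        )
    return records
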