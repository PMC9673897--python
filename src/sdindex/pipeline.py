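"""End-to-end orchestration: extents → units → scores → output bundle.

Stages run in the published order: (1) delineate urban extents, (2) cut
street-block units inside each extent (in a per-extent local metric plane
when inputs are geographic), (3–4) compute built and population-density
metrics and scores, (5) combine them into index values.  A run report
collects per-stage counts so reruns can be compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from shapely.geometry.base import BaseGeometry

from .config import PipelineConfig
from .errors import InputError, StageError
from .io_formats import OutputBundle, read_raster, read_vector
from .projection import LocalProjector
from .raster import Raster
from .scoring import ScoreRecord, score_units
from .spatial_units import (
    FeatureSet,
    SettlementExtent,
    SpatialUnit,
    build_units_for_extent,
    filter_small_extents,
)
from .thresholds import SpacingModel, build_threshold_table
from .urban_extents import UrbanCentre, UrbanExtent, delineate_urban_extents

logger = logging.getLogger(__name__)


def build_units_stage(
    grid: Raster,
    centres: Sequence[UrbanCentre],
    features: FeatureSet,
    settlements: Sequence[SettlementExtent],
    admin_boundary: BaseGeometry,
    water: Optional[BaseGeometry] = None,
    config: PipelineConfig = PipelineConfig(),
) -> Tuple[List[UrbanExtent], List[SpatialUnit], Dict[str, object]]:
    """Stages 1–2: delineate extents and cut their spatial units.

    Returns the kept extents, their units (world CRS) and a partial report.
    """
    crs = grid.crs
    report: Dict[str, object] = {"crs": crs, "iso3": config.iso3}

    try:
        extents = delineate_urban_extents(
            grid,
            centres,
            admin_boundary,
            water=water,
            buffer_m=config.buffer_m,
            iso3=config.iso3,
        )
    except InputError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"urban-extent delineation failed: {exc}") from exc
    report["extents_delineated"] = len(extents)

    units_by_extent: Dict[str, List] = {}
    projectors: Dict[str, LocalProjector] = {}
    for extent in extents:
        proj = LocalProjector.for_geometry(extent.geometry, crs)
        projectors[extent.uext_ID] = proj
        local_extent = proj.to_local(extent.geometry)
        local_features = FeatureSet(
            lines=[proj.to_local(g) for g in features.lines],
            boundary_polygons=[proj.to_local(g) for g in features.boundary_polygons],
            residential_polygons=[
                proj.to_local(g) for g in features.residential_polygons
            ],
        )
        local_settlements = [
            SettlementExtent(proj.to_local(s.geometry), s.stype) for s in settlements
        ]
        try:
            local_units = build_units_for_extent(
                local_extent,
                local_features,
                local_settlements,
                fringe_area_m2=config.fringe_area_m2,
                min_unit_area_m2=config.min_unit_area_m2,
            )
        except Exception as exc:
            raise StageError(
                f"unit construction failed for extent {extent.uext_ID}: {exc}"
            ) from exc
        units_by_extent[extent.uext_ID] = local_units
    report["units_created"] = {k: len(v) for k, v in units_by_extent.items()}

    kept = filter_small_extents(units_by_extent, config.min_units_per_extent)
    report["extents_filtered_out"] = sorted(set(units_by_extent) - set(kept))
    extents = [e for e in extents if e.uext_ID in kept]

    units: List[SpatialUnit] = []
    for extent in extents:
        proj = projectors[extent.uext_ID]
        for i, local_poly in enumerate(kept[extent.uext_ID]):
            units.append(
                SpatialUnit(
                    uext_ID=extent.uext_ID,
                    unit_id=i,
                    geometry=proj.to_world(local_poly),
                    unit_area=local_poly.area,
                )
            )
    report["units_total"] = len(units)
    return extents, units, report


def run_on_inputs(
    grid: Raster,
    centres: Sequence[UrbanCentre],
    features: FeatureSet,
    settlements: Sequence[SettlementExtent],
    footprints: Sequence[BaseGeometry],
    population: Raster,
    surface_area: Raster,
    admin_boundary: BaseGeometry,
    water: Optional[BaseGeometry] = None,
    config: PipelineConfig = PipelineConfig(),
) -> Tuple[OutputBundle, Dict[str, object]]:
    """Run all stages on in-memory inputs; returns (bundle, run report)."""
    crs = grid.crs
    extents, units, report = build_units_stage(
        grid, centres, features, settlements, admin_boundary, water, config
    )

    model = SpacingModel(config.apothem_min_m, config.apothem_max_m, config.apothem_step_m)
    table = build_threshold_table(model)
    try:
        records = score_units(
            units,
            footprints,
            population,
            surface_area,
            table=table,
            iso3=config.iso3,
            crs=crs,
        )
    except InputError:
        raise
    except Exception as exc:
        raise StageError(f"scoring failed: {exc}") from exc
    report["units_nodata"] = sum(1 for r in records if r.POPscore == config.nodata)

    points: List[dict] = []
    for centre in centres:
        if centre.qa_flag != config.qa_required:
            continue
        host = next(
            (e for e in extents if e.geometry.intersects(centre.polygon)), None
        )
        if host is None:
            continue
        points.append(
            {
                "PNT_LAT": centre.point.y,
                "PNT_LON": centre.point.x,
                "adm0_NAME": config.adm0_name or config.iso3,
                "adm0_ISO3": config.iso3,
                "urb_NAME": centre.name,
                "uext_ID": host.uext_ID,
            }
        )
    report["urban_points"] = len(points)

    bundle = OutputBundle(
        index_records=records, extents=extents, points=points, crs=crs
    )
    return bundle, report


def run_on_bundle(
    bundle, config: Optional[PipelineConfig] = None
) -> Tuple[OutputBundle, Dict[str, object]]:
    """Run the pipeline on a synthetic city bundle."""
    if config is None:
        config = PipelineConfig(iso3=bundle.iso3)
    return run_on_inputs(
        bundle.settlement_grid,
        bundle.centres,
        bundle.features,
        bundle.settlement_extents,
        bundle.footprints,
        bundle.population,
        bundle.surface_area,
        bundle.admin_boundary,
        water=bundle.water,
        config=config,
    )


def _load_centres(path) -> List[UrbanCentre]:
    from shapely.geometry import Point

    fc = read_vector(path)
    centres = []
    for geom, props in zip(fc.geometries, fc.properties):
        if "qa_flag" not in props:
            raise InputError(f"urban-centre layer {path} lacks a qa_flag field")
        point = (
            Point(props["PNT_LON"], props["PNT_LAT"])
            if "PNT_LON" in props and "PNT_LAT" in props
            else geom.centroid
        )
        centres.append(
            UrbanCentre(
                point=point,
                polygon=geom,
                qa_flag=props.get("qa_flag"),
                name=props.get("name", ""),
                country_iso3=props.get("country_iso3", ""),
            )
        )
    return centres


def load_inputs(
    config: PipelineConfig, require_rasters: bool = True
) -> Dict[str, object]:
    """Read every configured input file into pipeline objects.

    ``require_rasters=False`` lets the extent/unit stages run without the
    population and surface-area rasters.
    """
    required = {
        "smod_path": config.smod_path,
        "centres_path": config.centres_path,
        "admin_path": config.admin_path,
    }
    if require_rasters:
        required["population_path"] = config.population_path
        required["surface_area_path"] = config.surface_area_path
    missing = [k for k, v in required.items() if not v]
    if missing:
        raise InputError(f"missing required input paths: {missing}")

    admin_fc = read_vector(config.admin_path)
    if not len(admin_fc):
        raise InputError("admin boundary layer is empty")
    water = None
    if config.water_path:
        water_fc = read_vector(config.water_path)
        if len(water_fc):
            water = water_fc.geometries[0]

    def maybe_geoms(path):
        return list(read_vector(path).geometries) if path else []

    settlements = []
    if config.settlements_path:
        sfc = read_vector(config.settlements_path)
        settlements = [
            SettlementExtent(g, p.get("stype", "hamlet"))
            for g, p in zip(sfc.geometries, sfc.properties)
        ]
    inputs: Dict[str, object] = {
        "grid": read_raster(config.smod_path),
        "centres": _load_centres(config.centres_path),
        "admin_boundary": admin_fc.geometries[0],
        "water": water,
        "features": FeatureSet(
            lines=maybe_geoms(config.lines_path),
            boundary_polygons=maybe_geoms(config.landuse_path),
            residential_polygons=maybe_geoms(config.residential_path),
        ),
        "settlements": settlements,
        "footprints": maybe_geoms(config.footprints_path),
    }
    if require_rasters:
        inputs["population"] = read_raster(config.population_path)
        inputs["surface_area"] = read_raster(config.surface_area_path)
    return inputs


def run_pipeline(config: PipelineConfig) -> Tuple[OutputBundle, Dict[str, object]]:
    """File-based entry point: read all configured inputs, run, return bundle.

    Output writing is left to the caller (CLI) so in-memory use stays pure.
    """
    inputs = load_inputs(config, require_rasters=True)
    return run_on_inputs(
        inputs["grid"],
        inputs["centres"],
        inputs["features"],
        inputs["settlements"],
        inputs["footprints"],
        inputs["population"],
        inputs["surface_area"],
        inputs["admin_boundary"],
        water=inputs["water"],
        config=config,
    )
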