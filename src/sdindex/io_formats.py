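"""Readers and writers for vector layers, rasters and the published outputs.

Vector layers are GeoJSON FeatureCollections (the one self-describing text
vector format the stack supports); rasters are single-band GeoTIFFs written
through tifffile with the standard georeferencing tags (ModelPixelScale,
ModelTiepoint, GeoKeyDirectory, GDAL_NODATA).

The three published layers share a file-stem convention
``{ISO3}_SocialDistancing_v1_0_{index|urban_extents|urban_points}`` and a
fixed attribute schema which :func:`write_outputs` validates field-by-field
before writing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import shapely
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from .errors import InputError
from .raster import Raster
from .scoring import ScoreRecord
from .urban_extents import UrbanCentre, UrbanExtent

logger = logging.getLogger(__name__)

# TIFF tag codes for georeferencing
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

# GeoKey: GTModelTypeGeoKey -> 1 projected, 2 geographic
_MODEL_TYPE_BY_CRS = {"metric": 1, "geographic": 2}
_CRS_BY_MODEL_TYPE = {1: "metric", 2: "geographic"}

INDEX_FIELDS = (
    "uext_ID",
    "adm0_ISO3",
    "UNIT_AREA",
    "BUILT_AREA",
    "BUILT_PROP",
    "NBUILTPROP",
    "POP_DENS",
    "BUILTscore",
    "POPscore",
    "INDEXvalue",
)
EXTENTS_FIELDS = ("uext_ID", "adm0_ISO3")
POINTS_FIELDS = ("PNT_LAT", "PNT_LON", "adm0_NAME", "adm0_ISO3", "urb_NAME", "uext_ID")


@dataclass
class FeatureCollection:
    """A light vector layer: parallel geometry and attribute lists."""

    geometries: List[BaseGeometry]
    properties: List[dict]
    crs: str = "geographic"

    def __len__(self) -> int:
        return len(self.geometries)


@dataclass
class OutputBundle:
    """The three published layers for one country."""

    index_records: List[ScoreRecord]
    extents: List[UrbanExtent]
    points: List[dict]  # rows with POINTS_FIELDS keys
    crs: str = "geographic"


# ---------------------------------------------------------------------------
# vector I/O (GeoJSON)
# ---------------------------------------------------------------------------

def read_vector(path, repair: bool = True) -> FeatureCollection:
    """Read a GeoJSON FeatureCollection.

    Invalid geometries are repaired with ``make_valid`` (or rejected when
    ``repair=False``).  The CRS is taken from the non-standard top-level
    ``crs`` member when present (``"metric"`` for local-plane fixtures),
    defaulting to geographic per the GeoJSON spec.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"vector file not found: {path}")
    if path.suffix.lower() in (".shp", ".gpkg"):
        raise InputError(
            f"unsupported vector format {path.suffix!r}: this build reads GeoJSON only"
        )
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"not valid GeoJSON: {path}: {exc}") from exc
    if payload.get("type") != "FeatureCollection":
        raise InputError(f"expected a FeatureCollection in {path}")
    crs = payload.get("crs", "geographic")
    if isinstance(crs, dict):  # legacy GeoJSON crs object -> assume geographic
        crs = "geographic"
    geometries: List[BaseGeometry] = []
    properties: List[dict] = []
    for feat in payload.get("features", []):
        geom = shape(feat["geometry"]) if feat.get("geometry") else shapely.Polygon()
        if not geom.is_valid:
            if not repair:
                raise InputError(f"invalid geometry in {path} with repair disabled")
            logger.warning("repairing invalid geometry read from %s", path)
            geom = shapely.make_valid(geom)
        geometries.append(geom)
        properties.append(dict(feat.get("properties") or {}))
    return FeatureCollection(geometries, properties, crs=crs)


def write_vector(collection: FeatureCollection, path) -> Path:
    """Write a FeatureCollection as GeoJSON (crs kept as a top-level member)."""
    path = Path(path)
    features = [
        {
            "type": "Feature",
            "geometry": mapping(geom) if not geom.is_empty else None,
            "properties": props,
        }
        for geom, props in zip(collection.geometries, collection.properties)
    ]
    payload = {"type": "FeatureCollection", "crs": collection.crs, "features": features}
    path.write_text(json.dumps(payload))
    return path


# ---------------------------------------------------------------------------
# raster I/O (GeoTIFF)
# ---------------------------------------------------------------------------

def write_raster(raster: Raster, path) -> Path:
    """Write a single-band GeoTIFF with georeferencing tags."""
    path = Path(path)
    a, _, c, _, e, f = raster.transform
    model_type = _MODEL_TYPE_BY_CRS[raster.crs]
    geokeys = (1, 1, 0, 1, 1024, 0, 1, model_type)  # version header + GTModelType
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (a, -e, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
    ]
    if raster.nodata is not None:
        nd = repr(float(raster.nodata))
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd))
    tifffile.imwrite(path, raster.values, extratags=extratags)
    return path


def read_raster(path) -> Raster:
    """Read a single-band GeoTIFF written by :func:`write_raster` (or GDAL)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) != 1:
            raise InputError(f"expected a single-band raster, got {len(tif.pages)} pages")
        page = tif.pages[0]
        values = page.asarray()
        if values.ndim == 3:
            raise InputError("multiband raster without a band selector")
        tags = {tag.code: tag.value for tag in page.tags.values()}
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise InputError(f"raster {path} lacks georeferencing tags")
    sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE]
    tie = tags[_TAG_MODEL_TIEPOINT]
    transform = (float(sx), 0.0, float(tie[3]), 0.0, -float(sy), float(tie[4]))
    crs = None
    if _TAG_GEO_KEY_DIRECTORY in tags:
        keys = tags[_TAG_GEO_KEY_DIRECTORY]
        for i in range(4, len(keys), 4):
            if keys[i] == 1024:
                crs = _CRS_BY_MODEL_TYPE.get(int(keys[i + 3]))
    if crs is None:
        raise InputError(f"raster {path} has no recognised CRS geokey")
    nodata = None
    if _TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[_TAG_GDAL_NODATA]).strip("\x00"))
    return Raster(values, transform, crs, nodata)


# ---------------------------------------------------------------------------
# published output layers
# ---------------------------------------------------------------------------

def _validate_schema(rows: Sequence[dict], required: Sequence[str], layer: str) -> None:
    problems = []
    for i, row in enumerate(rows):
        missing = [f for f in required if f not in row]
        extra = [f for f in row if f not in required]
        if missing:
            problems.append(f"{layer} row {i}: missing fields {missing}")
        if extra:
            problems.append(f"{layer} row {i}: unexpected fields {extra}")
        for f in required:
            if f in row and row[f] is None:
                problems.append(f"{layer} row {i}: field {f} is null (use -99 for no data)")
    if problems:
        raise InputError("output schema violation:\n  " + "\n  ".join(problems))


def write_outputs(bundle: OutputBundle, out_dir, iso3: str) -> Dict[str, Path]:
    """Write the three published layers; refuses schema violations.

    Returns a mapping layer-name -> path, with stems
    ``{ISO3}_SocialDistancing_v1_0_{index,urban_extents,urban_points}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(iso3) != 3:
        raise InputError(f"iso3 must be a 3-letter code, got {iso3!r}")
    iso3 = iso3.upper()

    index_rows = [r.to_attributes() for r in bundle.index_records]
    _validate_schema(index_rows, INDEX_FIELDS, "index")
    extent_ids = {e.uext_ID for e in bundle.extents}
    orphans = {r["uext_ID"] for r in index_rows} - extent_ids
    if orphans:
        raise InputError(f"index rows reference unknown extents: {sorted(orphans)}")
    extent_rows = [{"uext_ID": e.uext_ID, "adm0_ISO3": e.adm0_ISO3} for e in bundle.extents]
    _validate_schema(extent_rows, EXTENTS_FIELDS, "urban_extents")
    _validate_schema(bundle.points, POINTS_FIELDS, "urban_points")

    stem = f"{iso3}_SocialDistancing_v1_0"
    paths: Dict[str, Path] = {}
    index_fc = FeatureCollection(
        [r.geometry for r in bundle.index_records], index_rows, crs=bundle.crs
    )
    paths["index"] = write_vector(index_fc, out_dir / f"{stem}_index.geojson")
    extents_fc = FeatureCollection(
        [e.geometry for e in bundle.extents], extent_rows, crs=bundle.crs
    )
    paths["urban_extents"] = write_vector(
        extents_fc, out_dir / f"{stem}_urban_extents.geojson"
    )
    points_fc = FeatureCollection(
        [shapely.Point(row["PNT_LON"], row["PNT_LAT"]) for row in bundle.points],
        [dict(row) for row in bundle.points],
        crs=bundle.crs,
    )
    paths["urban_points"] = write_vector(
        points_fc, out_dir / f"{stem}_urban_points.geojson"
    )
    return paths
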