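"""Seedable toy country exercising every pipeline stage with known truth.

The generated bundle emulates the production inputs at desk scale: a
settlement-model raster (~1 km classes), urban-centre records with quality
flags, street/land-use features, BUA/SSA settlement extents, building
footprints and constrained population + surface-area rasters (3 arc-second
analogue, 100 m cells in the local metric plane).

The city is a grid of square street blocks.  Each block is planted with a
target built fraction and a target mean density:

* buildings are packed as one square per 5×5 sub-cell with exactly the
  target total area (position jitter never changes the area), so the
  realised built proportion equals the target to float precision;
* population counts are written as density × cell surface area on every
  cell of the block, so the zonal mean density equals the target exactly;
* population is only allocated to cells intersecting footprints (zero-built
  blocks must have zero density), mirroring "constrained" gridded
  population datasets.  Cells inside the raster but unsettled hold 0;
  everything beyond the raster footprint is the missing-data (−99) path.

Fixtures come in a local-metric variant and a geographic variant.  The
geographic variant maps the same layout onto a 3 arc-second grid (1 layout
metre → 1/120000°), which keeps block edges aligned with raster cells while
exercising degree/metre conversions throughout the pipeline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon, box
from shapely.geometry.base import BaseGeometry

from .errors import ConfigError
from .projection import EARTH_RADIUS_M
from .raster import Raster
from .scoring import classify_built, classify_pop, compute_index
from .spatial_units import FeatureSet, SettlementExtent
from .thresholds import build_threshold_table
from .urban_extents import UrbanCentre

#: One population cell in layout metres (the 3 arc-second analogue).
CELL_M = 100.0
#: One settlement-model cell in layout metres (the 30 arc-second analogue).
SMOD_CELL_M = 1000.0
#: Degrees per layout metre in the geographic variant (100 m -> 1/1200 deg).
DEG_PER_M = 1.0 / 120_000.0

MAX_PACKABLE = 0.98

# Default planted (built fraction, density people/km²) per block, rows bottom-up.
# Together the 16 blocks cover every built score 0–10 and pop score 0–10.
DEFAULT_TARGETS: Tuple[Tuple[Tuple[float, float], ...], ...] = (
    ((0.00, 0.0), (0.05, 1000.0), (0.12, 2600.0), (0.18, 3200.0)),
    ((0.25, 4000.0), (0.32, 5000.0), (0.45, 7000.0), (0.55, 10000.0)),
    ((0.65, 15000.0), (0.75, 20000.0), (0.85, 35000.0), (0.95, 40000.0)),
    ((0.42, 6000.0), (0.08, 1500.0), (0.52, 8500.0), (0.33, 4800.0)),
)


@dataclass
class CityConfig:
    """Layout and planted targets for one synthetic city."""

    n_blocks_x: int = 4
    n_blocks_y: int = 4
    block_size: float = 200.0  # layout metres, multiple of CELL_M
    built_prop_field: Optional[Sequence[Sequence[float]]] = None  # [iy][ix]
    density_field: Optional[Sequence[Sequence[float]]] = None  # [iy][ix]
    river: bool = False
    fringe_blocks: Optional[List[Tuple[float, float, float, float]]] = None
    seed: int = 0
    crs: str = "metric"
    lon0: float = -13.20  # geographic variant origin (domain lower-left)
    lat0: float = 8.40
    jitter: float = 0.5  # fraction of free sub-cell margin used for jitter
    domain_size: float = 15_000.0  # layout metres

    # city lower-left corner in layout metres
    city_x0: float = 7_000.0
    city_y0: float = 7_000.0

    def __post_init__(self) -> None:
        if self.n_blocks_x < 1 or self.n_blocks_y < 1:
            raise ConfigError("need at least one block in each direction")
        if self.block_size < CELL_M or (self.block_size % CELL_M) != 0:
            raise ConfigError(
                f"block_size must be a positive multiple of {CELL_M} m"
            )
        if self.crs not in ("metric", "geographic"):
            raise ConfigError(f"unknown crs {self.crs!r}")
        if not 0.0 <= self.jitter <= 1.0:
            raise ConfigError("jitter must be in [0, 1]")

    def targets(self) -> List[List[Tuple[float, float]]]:
        """Per-block (built fraction, density) grid, validated."""
        flat_defaults = [t for row in DEFAULT_TARGETS for t in row]
        out: List[List[Tuple[float, float]]] = []
        k = 0
        for iy in range(self.n_blocks_y):
            row: List[Tuple[float, float]] = []
            for ix in range(self.n_blocks_x):
                if self.built_prop_field is not None:
                    built = float(self.built_prop_field[iy][ix])
                else:
                    built = flat_defaults[k % len(flat_defaults)][0]
                if self.density_field is not None:
                    dens = float(self.density_field[iy][ix])
                else:
                    dens = flat_defaults[k % len(flat_defaults)][1]
                if not 0.0 <= built <= MAX_PACKABLE:
                    raise ConfigError(
                        f"built target {built} for block ({ix},{iy}) outside "
                        f"[0, {MAX_PACKABLE}]"
                    )
                if dens < 0:
                    raise ConfigError("density targets must be non-negative")
                if built == 0.0 and dens > 0:
                    raise ConfigError(
                        "constrained population: a block without buildings "
                        "cannot carry population"
                    )
                row.append((built, dens))
                k += 1
            out.append(row)
        return out


@dataclass
class SyntheticCityBundle:
    """All pipeline inputs for the toy country, plus the planted truth."""

    config: CityConfig
    crs: str
    settlement_grid: Raster
    centres: List[UrbanCentre]
    features: FeatureSet
    settlement_extents: List[SettlementExtent]
    footprints: List[Polygon]
    population: Raster
    surface_area: Raster
    admin_boundary: BaseGeometry
    water: Optional[BaseGeometry]
    truth: pd.DataFrame
    offgrid_point: Point  # inside the extent, outside the raster: must score -99
    iso3: str = "SYN"
    expected: Dict[str, object] = field(default_factory=dict)


class _Layout:
    """Maps layout metres to world coordinates (identity or degree grid)."""

    def __init__(self, config: CityConfig):
        self.config = config
        self.geographic = config.crs == "geographic"

    def xy(self, x: float, y: float) -> Tuple[float, float]:
        if not self.geographic:
            return x, y
        return (
            self.config.lon0 + x * DEG_PER_M,
            self.config.lat0 + y * DEG_PER_M,
        )

    def geom(self, g: BaseGeometry) -> BaseGeometry:
        if not self.geographic:
            return g
        return shapely.transform(
            g,
            lambda pts: np.column_stack(
                (
                    self.config.lon0 + pts[:, 0] * DEG_PER_M,
                    self.config.lat0 + pts[:, 1] * DEG_PER_M,
                )
            ),
        )

    def scale(self, length_m: float) -> float:
        return length_m * DEG_PER_M if self.geographic else length_m

    def transform_for(self, cell_m: float, x0: float, y_top: float):
        """North-up affine for a raster of layout cell size *cell_m*."""
        s = self.scale(cell_m)
        wx, wy = self.xy(x0, y_top)
        return (s, 0.0, wx, 0.0, -s, wy)

    def cell_area_km2(self, row: int, n_rows: int, y_top: float) -> float:
        """Surface area of a population cell on row *row* (0 = top), km²."""
        if not self.geographic:
            return (CELL_M / 1000.0) ** 2
        step = CELL_M * DEG_PER_M
        lat_top = self.config.lat0 + y_top * DEG_PER_M - row * step
        lat_bot = lat_top - step
        area_m2 = (
            EARTH_RADIUS_M**2
            * math.radians(step)
            * (math.sin(math.radians(lat_top)) - math.sin(math.radians(lat_bot)))
        )
        return area_m2 / 1.0e6


def _pack_block(
    x0: float,
    y0: float,
    size: float,
    built_target: float,
    rng: np.random.Generator,
    jitter: float,
    layout: _Layout,
) -> List[Polygon]:
    """Fill a block with 25 square buildings totalling exactly target·size²."""
    if built_target <= 0:
        return []
    m = 5
    g = size / m
    s = g * math.sqrt(built_target)
    margin = (g - s) / 2.0
    out: List[Polygon] = []
    for j in range(m):
        for i in range(m):
            dx, dy = 0.0, 0.0
            if jitter > 0 and margin > 0:
                dx, dy = rng.uniform(-margin * jitter, margin * jitter, size=2)
            cx = x0 + (i + 0.5) * g + dx
            cy = y0 + (j + 0.5) * g + dy
            out.append(
                layout.geom(box(cx - s / 2.0, cy - s / 2.0, cx + s / 2.0, cy + s / 2.0))
            )
    return out


def _settlement_grid(config: CityConfig, layout: _Layout, second_city: bool) -> Raster:
    n = int(round(config.domain_size / SMOD_CELL_M))
    values = np.full((n, n), 12, dtype=np.int16)  # low-density rural background

    def set_cell(ix: int, iy: int, cls: int) -> None:
        values[n - 1 - iy, ix] = cls

    cx = int(config.city_x0 // SMOD_CELL_M)
    cy = int(config.city_y0 // SMOD_CELL_M)
    # urban cluster around the city: centre cell + dense-cluster ring,
    # plus one diagonal peri-urban cell exercising queen contiguity
    set_cell(cx, cy, 30)
    for ix, iy in ((cx, cy + 1), (cx + 1, cy), (cx + 1, cy + 1)):
        set_cell(ix, iy, 23)
    set_cell(cx + 2, cy + 2, 21)
    # city blocks larger than one settlement cell: keep them urban
    for iy in range(cy, cy + int(math.ceil(config.n_blocks_y * config.block_size / SMOD_CELL_M)) + 1):
        for ix in range(cx, cx + int(math.ceil(config.n_blocks_x * config.block_size / SMOD_CELL_M)) + 1):
            if values[n - 1 - iy, ix] < 21:
                set_cell(ix, iy, 23)
    # distractor urban blob with no quality centre (must be dropped)
    set_cell(1, n - 3, 21)
    set_cell(2, n - 3, 21)
    # water and scattered rural classes
    set_cell(0, 0, 10)
    set_cell(1, 0, 10)
    set_cell(3, 3, 11)
    set_cell(4, 3, 13)
    if second_city:
        c2x, c2y = 20, 7
        set_cell(c2x, c2y, 30)
    transform = layout.transform_for(SMOD_CELL_M, 0.0, config.domain_size)
    return Raster(values, transform, config.crs, nodata=None)


def generate_city(config: CityConfig = CityConfig()) -> SyntheticCityBundle:
    """Deterministically generate the toy country for *config*.

    See the module docstring for what is planted and which invariants hold.
    """
    rng = np.random.default_rng(config.seed)
    layout = _Layout(config)
    targets = config.targets()
    size = config.block_size
    x0, y0 = config.city_x0, config.city_y0
    city_w = config.n_blocks_x * size
    city_h = config.n_blocks_y * size
    domain = config.domain_size

    grid = _settlement_grid(config, layout, second_city=False)

    smod = SMOD_CELL_M
    cx, cy = int(x0 // smod), int(y0 // smod)
    centre_poly = layout.geom(
        box(cx * smod, cy * smod, (cx + 1) * smod, (cy + 1) * smod)
    )
    px, py = layout.xy(x0 + city_w / 2.0, y0 + city_h / 2.0)
    centres = [
        UrbanCentre(Point(px, py), centre_poly, 1, "Synthtown", "SYN"),
        UrbanCentre(
            Point(*layout.xy(1500.0, domain - 2500.0)),
            layout.geom(box(1000.0, domain - 3000.0, 2000.0, domain - 2000.0)),
            0,
            "Falseville",
            "SYN",
        ),
    ]

    # street grid (lines span the whole domain so every extent face is closed)
    lines: List[BaseGeometry] = []
    for i in range(config.n_blocks_x + 1):
        xi = x0 + i * size
        lines.append(layout.geom(LineString([(xi, 0.0), (xi, domain)])))
    for j in range(config.n_blocks_y + 1):
        yj = y0 + j * size
        lines.append(layout.geom(LineString([(0.0, yj), (domain, yj)])))
    if config.river:
        yr = y0 - 1.5 * size
        lines.append(layout.geom(LineString([(0.0, yr), (domain, yr)])))

    # a land-use boundary polygon (airport) north-west of the city
    airport = layout.geom(box(x0 - 1800.0, y0 + city_h + 400.0, x0 - 800.0, y0 + city_h + 1000.0))
    # residential patches on the urban fringe (east of the city by default)
    fringe = config.fringe_blocks
    if fringe is None:
        fringe = [(city_w + 200.0, 100.0, city_w + 500.0, 400.0)]
    residential = [
        layout.geom(box(x0 + a, y0 + b, x0 + c, y0 + d)) for a, b, c, d in fringe
    ]
    features = FeatureSet(
        lines=lines, boundary_polygons=[airport], residential_polygons=residential
    )

    settlements = [
        SettlementExtent(layout.geom(box(x0, y0, x0 + city_w, y0 + city_h)), "BUA"),
        SettlementExtent(
            layout.geom(box(x0 - 1200.0, y0, x0 - 800.0, y0 + 400.0)), "SSA"
        ),
        SettlementExtent(
            layout.geom(box(x0 + 200.0, y0 + city_h + 1700.0, x0 + 300.0, y0 + city_h + 1800.0)),
            "hamlet",
        ),
    ]

    footprints: List[Polygon] = []
    truth_rows: List[dict] = []
    table = build_threshold_table()
    for iy in range(config.n_blocks_y):
        for ix in range(config.n_blocks_x):
            built_t, dens_t = targets[iy][ix]
            bx, by = x0 + ix * size, y0 + iy * size
            footprints.extend(
                _pack_block(bx, by, size, built_t, rng, config.jitter, layout)
            )
            built_score = classify_built(built_t)
            pop_score = classify_pop(dens_t, table)
            wx, wy = layout.xy(bx + size / 2.0, by + size / 2.0)
            truth_rows.append(
                {
                    "block_ix": ix,
                    "block_iy": iy,
                    "cx": wx,
                    "cy": wy,
                    "BUILT_PROP": built_t,
                    "POP_DENS": dens_t,
                    "BUILTscore": built_score,
                    "POPscore": pop_score,
                    "INDEXvalue": compute_index(built_score, pop_score),
                }
            )
    truth = pd.DataFrame(truth_rows)

    # constrained population raster covering the city exactly
    cells_x = int(city_w // CELL_M)
    cells_y = int(city_h // CELL_M)
    per_block = int(size // CELL_M)
    transform = layout.transform_for(CELL_M, x0, y0 + city_h)
    counts = np.zeros((cells_y, cells_x))
    areas = np.zeros((cells_y, cells_x))
    for r in range(cells_y):
        area_km2 = layout.cell_area_km2(r, cells_y, y0 + city_h)
        iy = (cells_y - 1 - r) // per_block  # block row, bottom-up
        for c in range(cells_x):
            ix = c // per_block
            areas[r, c] = area_km2
            counts[r, c] = targets[iy][ix][1] * area_km2
    population = Raster(counts, transform, config.crs, nodata=-99.0)
    surface_area = Raster(areas, transform, config.crs, nodata=None)

    admin = layout.geom(box(0.0, 0.0, domain, domain))
    water = layout.geom(box(0.0, 0.0, 2000.0, 1000.0))  # matches class-10 cells

    return SyntheticCityBundle(
        config=config,
        crs=config.crs,
        settlement_grid=grid,
        centres=centres,
        features=features,
        settlement_extents=settlements,
        footprints=footprints,
        population=population,
        surface_area=surface_area,
        admin_boundary=admin,
        water=water,
        truth=truth,
        offgrid_point=Point(*layout.xy(x0 + city_w + 1500.0, y0 + city_h / 2.0 + 100.0)),
        iso3="SYN",
    )


def generate_edge_cases(seed: int = 0) -> SyntheticCityBundle:
    """A bundle planting the awkward cases the pipeline must survive.

    Contains: a unit with zero buildings; a thin unit with no raster-cell
    centroid (interpolation fallback); a building straddling two units with
    conserved split area; a sub-hectare sliver that must be merged away;
    off-raster faces that must score −99; and a second city whose extent
    yields exactly 29 units and must be dropped by the 30-unit filter while
    the main city's extent (≥30 units) is kept.
    """
    config = CityConfig(
        block_size=400.0,
        seed=seed,
        jitter=0.0,  # deterministic margins so the straddler never overlaps
        domain_size=26_000.0,
    )
    bundle = generate_city(config)
    layout = _Layout(config)
    x0, y0 = config.city_x0, config.city_y0
    size = config.block_size

    # second city: 28 vertical lines -> exactly 29 faces in its extent
    grid = _settlement_grid(config, layout, second_city=True)
    bundle.settlement_grid = grid
    c2_cell_x, c2_cell_y = 20, 7
    c2_poly = layout.geom(
        box(
            c2_cell_x * SMOD_CELL_M,
            c2_cell_y * SMOD_CELL_M,
            (c2_cell_x + 1) * SMOD_CELL_M,
            (c2_cell_y + 1) * SMOD_CELL_M,
        )
    )
    bundle.centres.append(
        UrbanCentre(
            Point(*layout.xy((c2_cell_x + 0.5) * SMOD_CELL_M, (c2_cell_y + 0.5) * SMOD_CELL_M)),
            c2_poly,
            1,
            "Smalltown",
            "SYN",
        )
    )
    c2_mid = (c2_cell_x + 0.5) * SMOD_CELL_M
    for k in range(28):
        xk = c2_mid - 1350.0 + 100.0 * k
        bundle.features.lines.append(
            layout.geom(LineString([(xk, 0.0), (xk, config.domain_size)]))
        )
    # rebuild the main grid lines clipped to the first city's neighbourhood so
    # neither city's street network reaches the other's extent
    cut = 15_000.0
    main_lines: List[BaseGeometry] = []
    for i in range(config.n_blocks_x + 1):
        xi = x0 + i * size
        main_lines.append(layout.geom(LineString([(xi, 0.0), (xi, cut)])))
    for j in range(config.n_blocks_y + 1):
        yj = y0 + j * size
        main_lines.append(layout.geom(LineString([(0.0, yj), (cut, yj)])))
    extra = bundle.features.lines[(config.n_blocks_x + 1) + (config.n_blocks_y + 1):]
    bundle.features.lines = main_lines + list(extra)

    # thin unit without a cell centroid inside block (0,0): 80 m wide strip
    # between centroid columns, plus its 60 m and 260 m wide neighbours
    for xs in (x0 + 60.0, x0 + 140.0):
        bundle.features.lines.append(
            layout.geom(LineString([(xs, y0), (xs, y0 + size)]))
        )
    # sub-hectare sliver in block (1,0): 20 m wide, must merge away
    bundle.features.lines.append(
        layout.geom(LineString([(x0 + size + 20.0, y0), (x0 + size + 20.0, y0 + size)]))
    )
    # building straddling blocks (2,0) and (3,0), clear of packed buildings
    bx = x0 + 3 * size
    straddler = layout.geom(box(bx - 10.0, y0 + 110.0, bx + 10.0, y0 + 130.0))
    bundle.footprints.append(straddler)

    tiny_probe = Point(*layout.xy(x0 + 100.0, y0 + size / 2.0))
    targets = config.targets()
    per_block_area = size * size
    straddle_share = 10.0 * 20.0  # per side, layout m²
    adj = {}
    for ix in (2, 3):
        built_t, dens_t = targets[0][ix]
        prop = built_t + straddle_share / per_block_area
        adj[ix] = prop
        mask = (bundle.truth["block_ix"] == ix) & (bundle.truth["block_iy"] == 0)
        score = classify_built(prop)
        bundle.truth.loc[mask, "BUILT_PROP"] = prop
        bundle.truth.loc[mask, "BUILTscore"] = score
        pop_score = int(bundle.truth.loc[mask, "POPscore"].iloc[0])
        bundle.truth.loc[mask, "INDEXvalue"] = compute_index(score, pop_score)

    bundle.expected = {
        "dropped_extent_units": 29,
        "dropped_extent_centre": "Smalltown",
        "tiny_unit_probe": tiny_probe,
        "tiny_unit_density": targets[0][0][1],
        "tiny_unit_area_m2": 80.0 * size,
        "sliver_probe": Point(*layout.xy(x0 + size + 10.0, y0 + size / 2.0)),
        "straddle_area_m2": 2 * straddle_share,
        "straddle_built_props": adj,
    }
    return bundle


def write_fixture(bundle: SyntheticCityBundle, out_dir) -> Dict[str, Path]:
    """Persist a bundle as GeoTIFF/GeoJSON/CSV files; returns name -> path."""
    from .io_formats import FeatureCollection, write_raster, write_vector

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    crs = bundle.crs
    paths: Dict[str, Path] = {}
    paths["smod"] = write_raster(bundle.settlement_grid, out_dir / "smod.tif")
    paths["population"] = write_raster(bundle.population, out_dir / "population.tif")
    paths["surface_area"] = write_raster(bundle.surface_area, out_dir / "surface_area.tif")

    def fc(geoms, props) -> FeatureCollection:
        return FeatureCollection(list(geoms), list(props), crs=crs)

    paths["centres"] = write_vector(
        fc(
            (c.polygon for c in bundle.centres),
            (
                {
                    "qa_flag": c.qa_flag,
                    "name": c.name,
                    "country_iso3": c.country_iso3,
                    "PNT_LON": c.point.x,
                    "PNT_LAT": c.point.y,
                }
                for c in bundle.centres
            ),
        ),
        out_dir / "urban_centres.geojson",
    )
    paths["admin"] = write_vector(
        fc([bundle.admin_boundary], [{"name": "SYN"}]), out_dir / "admin.geojson"
    )
    if bundle.water is not None:
        paths["water"] = write_vector(
            fc([bundle.water], [{}]), out_dir / "water.geojson"
        )
    paths["lines"] = write_vector(
        fc(bundle.features.lines, ({} for _ in bundle.features.lines)),
        out_dir / "lines.geojson",
    )
    paths["landuse"] = write_vector(
        fc(
            bundle.features.boundary_polygons,
            ({} for _ in bundle.features.boundary_polygons),
        ),
        out_dir / "landuse.geojson",
    )
    paths["residential"] = write_vector(
        fc(
            bundle.features.residential_polygons,
            ({} for _ in bundle.features.residential_polygons),
        ),
        out_dir / "residential.geojson",
    )
    paths["settlements"] = write_vector(
        fc(
            (s.geometry for s in bundle.settlement_extents),
            ({"stype": s.stype} for s in bundle.settlement_extents),
        ),
        out_dir / "settlement_extents.geojson",
    )
    paths["footprints"] = write_vector(
        fc(bundle.footprints, ({} for _ in bundle.footprints)),
        out_dir / "footprints.geojson",
    )
    truth_path = out_dir / "truth.csv"
    bundle.truth.to_csv(truth_path, index=False)
    paths["truth"] = truth_path
    cfg = {k: v for k, v in vars(bundle.config).items() if not k.startswith("_")}
    cfg["fringe_blocks"] = (
        [list(t) for t in cfg["fringe_blocks"]] if cfg["fringe_blocks"] else None
    )
    for key in ("built_prop_field", "density_field"):
        if cfg[key] is not None:
            cfg[key] = [list(row) for row in cfg[key]]
    config_path = out_dir / "config.json"
    config_path.write_text(json.dumps(cfg, indent=2))
    paths["config"] = config_path
    return paths
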