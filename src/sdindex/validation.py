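"""Settlement-type comparison of score distributions.

Scored units are classified as informal settlements or "other" — either by
area overlap with mapped informal-settlement polygons, or by the majority
type of the buildings they contain — and the joint distribution of
population and built scores is compared between the two classes.  In cities
where this has been mapped, informal settlements concentrate at high
population-density scores, so the exceedance proportion P(POPscore ≥ t)
should be visibly higher for informal units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import pandas as pd
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .scoring import NODATA, ScoreRecord

logger = logging.getLogger(__name__)

INFORMAL = "Informal"
OTHER = "Other"


@dataclass
class SettlementClassMap:
    """Per-unit settlement class, keyed by (uext_ID, unit_id)."""

    classes: Dict[tuple, str]
    rule_used: str  # "area_overlap" or "majority_building_type"

    def class_of(self, record: ScoreRecord) -> str:
        return self.classes[(record.uext_ID, record.unit_id)]


def assign_by_area_overlap(
    records: Sequence[ScoreRecord],
    informal_polygons: Sequence[BaseGeometry],
    threshold: float = 0.5,
) -> SettlementClassMap:
    """Informal iff >= *threshold* of the unit's area lies inside informal polygons."""
    union = unary_union([p for p in informal_polygons if not p.is_empty])
    classes: Dict[tuple, str] = {}
    for rec in records:
        geom = rec.geometry
        frac = 0.0
        if geom is not None and geom.area > 0 and not union.is_empty:
            frac = geom.intersection(union).area / geom.area
        classes[(rec.uext_ID, rec.unit_id)] = INFORMAL if frac >= threshold else OTHER
    return SettlementClassMap(classes, "area_overlap")


def assign_by_majority_type(
    records: Sequence[ScoreRecord],
    typed_buildings: Sequence[tuple],  # (geometry, type_label) pairs
) -> SettlementClassMap:
    """Unit class = modal type of intersecting buildings; ties and no-building -> Other."""
    classes: Dict[tuple, str] = {}
    for rec in records:
        geom = rec.geometry
        counts: Dict[str, int] = {}
        if geom is not None:
            for bgeom, label in typed_buildings:
                if bgeom.intersects(geom):
                    counts[label] = counts.get(label, 0) + 1
        if not counts:
            classes[(rec.uext_ID, rec.unit_id)] = OTHER
            continue
        top = max(counts.values())
        winners = sorted(label for label, n in counts.items() if n == top)
        if len(winners) > 1:
            logger.info(
                "majority-type tie %s for unit %s/%s; assigning Other",
                winners,
                rec.uext_ID,
                rec.unit_id,
            )
            classes[(rec.uext_ID, rec.unit_id)] = OTHER
        else:
            classes[(rec.uext_ID, rec.unit_id)] = winners[0]
    return SettlementClassMap(classes, "majority_building_type")


def _scored(records: Sequence[ScoreRecord]) -> List[ScoreRecord]:
    return [r for r in records if r.POPscore != NODATA]


def joint_score_distribution(
    records: Sequence[ScoreRecord], classmap: SettlementClassMap
) -> pd.DataFrame:
    """Proportion of units per (POPscore, BUILTscore, class) cell.

    No-data units are excluded; proportions sum to 1 within each class.
    """
    rows = [
        {
            "POPscore": r.POPscore,
            "BUILTscore": r.BUILTscore,
            "class": classmap.class_of(r),
        }
        for r in _scored(records)
    ]
    if not rows:
        logger.warning("no scored units to tabulate")
        return pd.DataFrame(columns=["POPscore", "BUILTscore", "class", "proportion"])
    df = pd.DataFrame(rows)
    counts = (
        df.groupby(["class", "POPscore", "BUILTscore"]).size().rename("n").reset_index()
    )
    counts["proportion"] = counts["n"] / counts.groupby("class")["n"].transform("sum")
    return counts[["POPscore", "BUILTscore", "class", "proportion"]]


def score_exceedance(
    records: Sequence[ScoreRecord],
    classmap: SettlementClassMap,
    field: str,
    threshold: float,
) -> Dict[str, float]:
    """Per-class proportion of units with *field* >= *threshold*.

    *field* is one of POPscore, BUILTscore, INDEXvalue; no-data units are
    excluded from both numerator and denominator.
    """
    if field not in ("POPscore", "BUILTscore", "INDEXvalue"):
        raise ValueError(f"unsupported field {field!r}")
    totals: Dict[str, int] = {}
    hits: Dict[str, int] = {}
    for rec in _scored(records):
        cls = classmap.class_of(rec)
        totals[cls] = totals.get(cls, 0) + 1
        if getattr(rec, field) >= threshold:
            hits[cls] = hits.get(cls, 0) + 1
    return {cls: hits.get(cls, 0) / n for cls, n in totals.items()}
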