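"""Hexagonal-packing spacing model behind the population-density score.

The population-density score asks: could everyone in a street block stand in
an idealised hexagonal tessellation with a given spacing?  Each person
occupies one regular hexagon; the apothem *d* (centre to mid-side) is half
the centre-to-centre spacing, so an apothem of 3 m lets everyone keep 2 m
apart while moving.  A hexagon of apothem *d* has area

    A(d) = 2·√3·d²,

so the maximum density compatible with that spacing is

    T(d) = 10⁶ / A(d)   people per km².

Growing *d* from 3 m to 11 m in 1 m steps yields nine density thresholds
which bin mean unit densities into scores 10 (densest, d = 3 m) down to 2
(d = 11 m); non-zero densities below T(11 m) score 1 and zero density
scores 0.  The model is deliberately obstruction-free: it describes the
best possible spacing, not the achievable one.

All comparisons use the unrounded thresholds; the familiar printed figures
(A(3) = 31.18 m², T(3) = 32,075 /km², A(11) = 419.16 m², T(11) = 2,386 /km²)
are 2-dp / nearest-integer renderings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .errors import ConfigError

__all__ = [
    "SpacingModel",
    "ThresholdRow",
    "SpacingThresholdTable",
    "hexagon_area",
    "max_density",
    "build_threshold_table",
]


def hexagon_area(apothem: float) -> float:
    """Area in m² of a regular hexagon with the given apothem in metres.

    A regular hexagon of apothem *d* is six triangles of base ``2d/√3`` and
    height *d*, giving ``A = 2·√3·d²``.  The unrounded value is returned;
    round to 2 dp only for reporting.
    """
    if not apothem > 0:
        raise ValueError(f"apothem must be positive, got {apothem}")
    return 2.0 * math.sqrt(3.0) * apothem * apothem


def max_density(apothem: float) -> float:
    """Maximum density (people per km²) for hexagonal spacing with *apothem* m.

    One person per hexagon: ``T(d) = 10⁶ / A(d)`` using the unrounded area.
    Round to the nearest integer only for reporting.
    """
    return 1.0e6 / hexagon_area(apothem)


@dataclass(frozen=True)
class SpacingModel:
    """Apothem sweep defining the score thresholds (metres)."""

    d_min: float = 3.0
    d_max: float = 11.0
    d_step: float = 1.0

    def __post_init__(self) -> None:
        if self.d_min < 1:
            raise ConfigError(f"d_min must be >= 1 m, got {self.d_min}")
        if not self.d_max >= self.d_min:
            raise ConfigError("d_max must be >= d_min")
        if not self.d_step > 0:
            raise ConfigError("d_step must be positive")
        n_steps = (self.d_max - self.d_min) / self.d_step
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ConfigError("(d_max - d_min) must be divisible by d_step")

    @property
    def apothems(self) -> List[float]:
        n = int(round((self.d_max - self.d_min) / self.d_step)) + 1
        return [self.d_min + i * self.d_step for i in range(n)]


@dataclass(frozen=True)
class ThresholdRow:
    apothem: float
    area_m2: float          # unrounded A(d)
    max_density: float      # unrounded T(d), people per km²
    pop_score: int


@dataclass(frozen=True)
class SpacingThresholdTable:
    """Ordered apothem → (area, max density, score) rows, densest first."""

    rows: Tuple[ThresholdRow, ...]

    def __post_init__(self) -> None:
        apothems = [r.apothem for r in self.rows]
        dens = [r.max_density for r in self.rows]
        scores = [r.pop_score for r in self.rows]
        if any(b <= a for a, b in zip(apothems, apothems[1:])):
            raise ConfigError("apothems must be strictly increasing")
        if any(b >= a for a, b in zip(dens, dens[1:])):
            raise ConfigError("max densities must be strictly decreasing")
        if any(b >= a for a, b in zip(scores, scores[1:])):
            raise ConfigError("scores must be strictly decreasing")

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        """Audit rendering: area to 2 dp, density to nearest integer."""
        return pd.DataFrame(
            {
                "apothem_m": [r.apothem for r in self.rows],
                "area_m2": [round(r.area_m2, 2) for r in self.rows],
                "max_density_per_km2": [int(round(r.max_density)) for r in self.rows],
                "pop_score": [r.pop_score for r in self.rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_threshold_table(
    model: SpacingModel = SpacingModel(),
    scores: Optional[Sequence[int]] = None,
) -> SpacingThresholdTable:
    """Build the score-threshold table for an apothem sweep.

    With the default model (3–11 m in 1 m steps) the nine apothems map to
    scores 10 down to 2, one score per metre.  A model with a different step
    count needs an explicit ``scores`` sequence (strictly decreasing, one per
    apothem).
    """
    apothems = model.apothems
    if scores is None:
        if len(apothems) != 9:
            raise ConfigError(
                f"default score range 10..2 needs 9 apothems, model has "
                f"{len(apothems)}; pass scores= explicitly"
            )
        scores = list(range(10, 1, -1))
    if len(scores) != len(apothems):
        raise ConfigError("scores must have one entry per apothem")
    rows = tuple(
        ThresholdRow(d, hexagon_area(d), max_density(d), int(s))
        for d, s in zip(apothems, scores)
    )
    return SpacingThresholdTable(rows)
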