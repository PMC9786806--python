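"""Ploidy calling on a half-integer grid.

Mature plants are called from absolute 2C DNA amounts against published
per-cytotype ranges; seed tissues (embryo, endosperm) are called from peak
ratios against a reference tissue of known ploidy, which cancels
accession-level genome-size variation.  Called levels live on a 0.5x grid
(1x..20x): integral levels are euploid, half-integral levels are the "~"
aneuploid categories.  Endosperm calls above 12x are flagged uncertain —
identification error grows with ploidy and such calls are only putative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ContractError, InvalidMeasurementError

#: half-integer grid step
GRID_STEP = 0.5
#: maximum distance from a grid point for a raw level to be resolvable
SNAP_HALF_WIDTH = 0.25
#: calls above this level are flagged as putative
UNCERTAIN_ABOVE = 12.0

GRID_MIN = 1.0
GRID_MAX = 20.0


def is_on_grid(level: float, *, eps: float = 1e-9) -> bool:
    """True iff ``level`` is a positive multiple of 0.5."""
    return level > 0 and abs(level / GRID_STEP - round(level / GRID_STEP)) < eps


@dataclass(frozen=True, order=True)
class PloidyCategory:
    """A called ploidy level on the 0.5x grid.

    ``euploid`` and ``approximate`` are derived from ``level_x``;
    ``uncertain`` marks putative calls above 12x.
    """

    level_x: float

    def __post_init__(self) -> None:
        if not is_on_grid(self.level_x):
            raise ContractError(
                f"ploidy level must be a positive multiple of 0.5, got {self.level_x}"
            )

    @property
    def euploid(self) -> bool:
        return float(self.level_x).is_integer()

    @property
    def approximate(self) -> bool:
        return not self.euploid

    @property
    def uncertain(self) -> bool:
        return self.level_x > UNCERTAIN_ABOVE

    def __str__(self) -> str:
        return format_level(self.level_x)


def format_level(level_x: float) -> str:
    """Render a grid level as its category name: 3.0 -> "3x", 9.5 -> "~9.5x"."""
    if float(level_x).is_integer():
        return f"{int(level_x)}x"
    return f"~{level_x:g}x"


def parse_level(text: str) -> float:
    """Inverse of :func:`format_level` ("~9.5x" -> 9.5)."""
    value = float(text.strip().lstrip("~").rstrip("xX"))
    if not is_on_grid(value):
        raise ContractError(f"parsed level {value!r} is not on the 0.5x grid")
    return value


def snap_level(raw_level: float, *, half_width: float = SNAP_HALF_WIDTH) -> Optional[float]:
    """Snap a raw (continuous) level to the nearest grid point.

    Returns None when the raw level is farther than ``half_width`` from every
    grid point, or falls outside [1x, 20x]: such measurements are unresolvable
    rather than silently rounded.
    """
    nearest = round(raw_level / GRID_STEP) * GRID_STEP
    if abs(raw_level - nearest) > half_width + 1e-12:
        return None
    if nearest < GRID_MIN - 1e-12 or nearest > GRID_MAX + 1e-12:
        return None
    return float(nearest)


@dataclass(frozen=True)
class MaturePloidyCall:
    """Result of calling a mature plant from its absolute 2C value."""

    category: Optional[PloidyCategory]
    classified: bool
    candidates: tuple[int, ...] = ()  # nearest euploid levels when unclassified


# Published 2C ranges (pg) per cytotype for hawthorn; closed intervals.
DEFAULT_CYTOTYPE_RANGES: dict[int, tuple[float, float]] = {
    2: (1.37, 1.67),
    3: (2.05, 2.51),
    4: (2.74, 3.34),
    5: (3.42, 4.18),
}


@dataclass(frozen=True)
class CytotypeRanges:
    """Mapping ploidy -> closed [low_pg, high_pg] interval; intervals must be
    disjoint and increasing with ploidy."""

    ranges: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CYTOTYPE_RANGES)
    )

    def __post_init__(self) -> None:
        prev_high = -math.inf
        for ploidy in sorted(self.ranges):
            low, high = self.ranges[ploidy]
            if not (0 < low <= high):
                raise ContractError(f"invalid interval for {ploidy}x: [{low}, {high}]")
            if low <= prev_high:
                raise ContractError("cytotype ranges must be disjoint and increasing")
            prev_high = high


def call_mature_ploidy(value_pg: float, ranges: CytotypeRanges | None = None) -> MaturePloidyCall:
    """Call a mature plant's ploidy from its 2C value (pg).

    Values inside a published interval get that euploid level; values in gaps
    or outside all intervals come back unclassified with the two nearest
    candidate levels reported.
    """
    if value_pg <= 0:
        raise InvalidMeasurementError(f"2C value must be positive, got {value_pg}")
    ranges = ranges or CytotypeRanges()
    items = sorted(ranges.ranges.items())
    for ploidy, (low, high) in items:
        if low <= value_pg <= high:
            return MaturePloidyCall(PloidyCategory(float(ploidy)), True)
    # unclassified: report the two nearest levels by interval distance
    def distance(item: tuple[int, tuple[float, float]]) -> float:
        _, (low, high) = item
        if value_pg < low:
            return low - value_pg
        return value_pg - high

    nearest = sorted(items, key=distance)[:2]
    return MaturePloidyCall(None, False, tuple(sorted(p for p, _ in nearest)))


@dataclass(frozen=True)
class SeedTissueCall:
    """Result of calling a seed tissue from a peak ratio."""

    category: Optional[PloidyCategory]
    raw_level: float
    resolvable: bool


def call_seed_tissue_ploidy(
    tissue_peak_mean: float,
    reference_peak_mean: float,
    reference_ploidy: PloidyCategory,
    *,
    half_width: float = SNAP_HALF_WIDTH,
) -> SeedTissueCall:
    """Call a seed tissue's ploidy relative to a reference tissue.

    raw level = reference level x (tissue peak / reference peak), snapped to
    the 0.5x grid.  Raw levels farther than ``half_width`` from the grid are
    flagged unresolvable.
    """
    if tissue_peak_mean <= 0 or reference_peak_mean <= 0:
        raise InvalidMeasurementError("peak means must be positive")
    raw = reference_ploidy.level_x * (tissue_peak_mean / reference_peak_mean)
    snapped = snap_level(raw, half_width=half_width)
    if snapped is None:
        return SeedTissueCall(None, raw, False)
    return SeedTissueCall(PloidyCategory(snapped), raw, True)
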