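"""Outcome-proportion and germ-layer scoring arithmetic.

Percentages are rounded half-away-from-zero so printed one-decimal figures
are reproduced exactly (e.g. 15/54 -> 27.8).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from scipy import stats

from .errors import InputError, StatisticsError

__all__ = [
    "OutcomeCounts",
    "SpecimenScores",
    "percent",
    "layer_percentages",
    "compare_proportions",
]

GERM_LAYERS = (
    "ectoderm",
    "mesoderm",
    "endoderm",
    "neural_like",
    "epidermis_like",
    "other",
)


@dataclass(frozen=True)
class OutcomeCounts:
    """Category counts out of a common total (e.g. embryo outcome classes)."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise InputError(f"total must be positive, got {self.total}")
        if any(c < 0 for c in self.counts.values()):
            raise InputError("counts must be nonnegative")
        if sum(self.counts.values()) > self.total:
            raise InputError("category counts exceed the total")

    def percentages(self, decimals: int = 1) -> dict[str, float]:
        return {k: percent(v, self.total, decimals) for k, v in self.counts.items()}


@dataclass(frozen=True)
class SpecimenScores:
    """Germ-layer tissue scores for one specimen across its scored slices."""

    specimen_id: str
    scores: Mapping[str, float]
    slices: int

    def __post_init__(self) -> None:
        if self.slices < 0:
            raise InputError(f"slices must be >= 0, got {self.slices}")
        if any(v < 0 for v in self.scores.values()):
            raise InputError("layer scores must be nonnegative")


def percent(count: int, total: int, decimals: int = 1) -> float:
    """``100 * count / total`` rounded half-away-from-zero to `decimals` places."""
    if total <= 0:
        raise InputError(f"total must be positive, got {total}")
    if not 0 <= count <= total:
        raise InputError(f"count must be in [0, total], got {count}/{total}")
    if decimals < 0:
        raise InputError(f"decimals must be >= 0, got {decimals}")
    exact = Decimal(100) * Decimal(count) / Decimal(total)
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def layer_percentages(scores: Iterable[SpecimenScores]) -> dict[str, float]:
    """Per-layer percentage: summed layer scores over total slices scored.

    Layers need not sum to 100 (slices may carry no layer call, or several —
    the scoring rubric does not forbid multi-layer calls).
    """
    specimens = list(scores)
    if not specimens:
        raise InputError("at least one specimen is required")
    total_slices = sum(s.slices for s in specimens)
    if total_slices == 0:
        raise InputError("zero slices scored across specimens")
    layers: dict[str, float] = {}
    for s in specimens:
        for layer, v in s.scores.items():
            layers[layer] = layers.get(layer, 0.0) + float(v)
    return {layer: 100.0 * v / total_slices for layer, v in sorted(layers.items())}


def compare_proportions(
    a: tuple[int, int], b: tuple[int, int]
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact P for two (successes, failures) rows.

    The odds ratio uses the Haldane correction (add 0.5 to every cell) when
    any cell is zero.  Degenerate margins (an all-zero row or column) raise
    :class:`StatisticsError`.
    """
    (a1, a2), (b1, b2) = a, b
    if min(a1, a2, b1, b2) < 0:
        raise InputError("cell counts must be nonnegative")
    if a1 + a2 == 0 or b1 + b2 == 0 or a1 + b1 == 0 or a2 + b2 == 0:
        raise StatisticsError("degenerate 2x2 table: an all-zero row or column")
    if 0 in (a1, a2, b1, b2):
        ha1, ha2, hb1, hb2 = (a1 + 0.5, a2 + 0.5, b1 + 0.5, b2 + 0.5)
    else:
        ha1, ha2, hb1, hb2 = (float(a1), float(a2), float(b1), float(b2))
    odds_ratio = (ha1 * hb2) / (ha2 * hb1)
    _, p = stats.fisher_exact([[a1, a2], [b1, b2]], alternative="two-sided")
    return odds_ratio, float(p)
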