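"""Discrete evidence categories and proportion-wheel values.

The categories follow the classic descriptive scheme for Bayes factors
(anecdotal / moderate / strong / very strong / extreme, for either
hypothesis); they are approximate verbal labels for a continuous quantity,
not decision thresholds.  Boundary values are assigned to the stronger band
(BF10 = 10 is already "strong").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EvidenceLabel", "classify", "wheel_proportion"]

# (lower bound of BF10 band, category); bands are [lower, next) for H1
_BANDS_H1 = [
    (100.0, "Extreme"),
    (30.0, "Very strong"),
    (10.0, "Strong"),
    (3.0, "Moderate"),
    (1.0, "Anecdotal"),
]

_STRENGTH_ORDER = ["Anecdotal", "Moderate", "Strong", "Very strong", "Extreme"]


@dataclass(frozen=True)
class EvidenceLabel:
    """A verbal category with the half-open BF10 interval it covers."""

    category: str
    hypothesis: str | None        # "H1", "H0", or None for BF = 1
    bounds: tuple[float, float]   # [lower, upper) interval of BF10

    @property
    def text(self) -> str:
        if self.hypothesis is None:
            return "No evidence"
        return f"{self.category} evidence for {self.hypothesis}"

    def strength_rank(self) -> int:
        """Signed strength: positive toward H1, negative toward H0."""
        if self.hypothesis is None:
            return 0
        rank = _STRENGTH_ORDER.index(self.category) + 1
        return rank if self.hypothesis == "H1" else -rank


def classify(bf10: float) -> EvidenceLabel:
    """The evidence category of a Bayes factor BF10.

    >1 favors H1, <1 favors H0 (mirror bands on the reciprocal scale),
    exactly 1 is no evidence.  Boundary values go to the stronger band.
    """
    if not bf10 > 0:
        raise ValueError("a Bayes factor must be positive")
    if bf10 == 1.0:
        return EvidenceLabel("No evidence", None, (1.0, 1.0))
    if bf10 > 1.0:
        uppers = [math.inf, 100.0, 30.0, 10.0, 3.0]
        for (low, cat), high in zip(_BANDS_H1, uppers):
            if bf10 >= low:
                return EvidenceLabel(cat, "H1", (low, high))
    label = classify(1.0 / bf10)
    low, high = label.bounds
    return EvidenceLabel(label.category, "H0",
                         (1.0 / high if math.isfinite(high) else 0.0, 1.0 / low))


def wheel_proportion(bf10: float) -> float:
    """The fraction BF/(BF+1) of a proportion wheel claimed by H1.

    With equal prior odds this is the posterior probability of H1, and the
    size of the smaller area is the probability that an all-or-none decision
    is wrong.
    """
    if not bf10 > 0:
        raise ValueError("a Bayes factor must be positive")
    if math.isinf(bf10):
        return 1.0
    # evaluated through the smaller odds so that the complementary identity
    # wheel(bf) + wheel(1/bf) == 1 holds exactly in floating point
    if bf10 > 1.0:
        inv = 1.0 / bf10
        return 1.0 - inv / (inv + 1.0)
    return bf10 / (bf10 + 1.0)
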