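"""Shared result containers: Bayes factors and posterior summaries."""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = ["BayesFactorResult", "PosteriorSummary", "format_bf"]


def format_bf(bf: float, sig: int = 3) -> str:
    """Render a Bayes factor, switching to scientific notation for extremes.

    Values outside [1e-4, 1e6] are shown as e.g. ``8.192e+39``; everything
    else in plain decimal with ``sig`` significant digits.
    """
    if bf == 0.0:
        return "0"
    if math.isinf(bf):
        return "inf" if bf > 0 else "-inf"
    if abs(bf) > 1e6 or abs(bf) < 1e-4:
        return f"{bf:.{sig}e}"
    return f"{bf:.{sig}g}"


@dataclass(frozen=True)
class BayesFactorResult:
    """A Bayes factor stored on the natural-log scale.

    ``log_bf10`` is log BF of the first-named hypothesis in ``comparison``
    over the second.  ``error_pct`` is the numerical-integration error as a
    percentage of the Bayes factor (akin to a coefficient of variation); it is
    None when the deterministic quadrature error is below tolerance.
    """

    log_bf10: float
    error_pct: float | None = None
    comparison: str = "H1 vs H0"

    def __post_init__(self) -> None:
        if self.error_pct is not None and self.error_pct < 0:
            raise ValueError("error_pct must be non-negative")

    @property
    def bf10(self) -> float:
        return math.exp(self.log_bf10)

    @property
    def bf01(self) -> float:
        return math.exp(-self.log_bf10)

    def inverted(self) -> "BayesFactorResult":
        """The same evidence reported in the opposite direction."""
        a, _, b = self.comparison.partition(" vs ")
        return replace(self, log_bf10=-self.log_bf10,
                       comparison=f"{b} vs {a}" if b else self.comparison)

    def __str__(self) -> str:
        err = "" if self.error_pct is None else f" (error {self.error_pct:.3g}%)"
        return f"BF[{self.comparison}] = {format_bf(self.bf10)}{err}"


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior median, central 95% credible interval, density at the null."""

    median: float
    ci95: tuple[float, float]
    density_at_zero: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.median <= hi):
            raise ValueError("credible interval must bracket the median")
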