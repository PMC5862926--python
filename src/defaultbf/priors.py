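"""Prior families for the default tests.

Two families cover every analysis here:

* a Cauchy prior on the standardized effect size delta (the JZS prior), with
  one-sided "folded" variants that double the density on a half-line;
* a stretched beta prior on a correlation rho, i.e. a Beta(1/kappa, 1/kappa)
  rescaled from (0, 1) to (-1, 1).  Width kappa = 1 is the uniform prior on
  (-1, 1); smaller kappa concentrates mass near rho = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "SQRT2_OVER_2",
    "EffectSizePrior",
    "CorrelationPrior",
    "ParameterError",
    "prior_density",
    "prior_mass_positive",
]

#: the default JZS scale, stored exactly as sqrt(2)/2 (displayed as 0.707)
SQRT2_OVER_2 = math.sqrt(2.0) / 2.0

_EFFECT_FAMILIES = ("cauchy", "folded_cauchy_positive", "folded_cauchy_negative")
_SIDES = ("two_sided", "positive", "negative")


class ParameterError(ValueError):
    """Invalid prior parameterization."""


@dataclass(frozen=True)
class EffectSizePrior:
    """Cauchy(0, scale) prior on delta, optionally folded onto a half-line."""

    family: str = "cauchy"
    scale: float = SQRT2_OVER_2

    def __post_init__(self) -> None:
        if self.family not in _EFFECT_FAMILIES:
            raise ParameterError(f"unknown family {self.family!r}")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ParameterError("Cauchy scale must be a positive finite number")

    @property
    def side(self) -> int:
        """-1, 0 or +1: the half-line the prior lives on (0 = two-sided)."""
        return {"cauchy": 0, "folded_cauchy_positive": 1,
                "folded_cauchy_negative": -1}[self.family]

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        dens = stats.cauchy.pdf(x, scale=self.scale)
        if self.side > 0:
            dens = np.where(x >= 0, 2.0 * dens, 0.0)
        elif self.side < 0:
            dens = np.where(x <= 0, 2.0 * dens, 0.0)
        return dens if dens.ndim else float(dens)

    def folded(self, side: int) -> "EffectSizePrior":
        """The one-sided version of this prior on the given half-line."""
        fam = {1: "folded_cauchy_positive", -1: "folded_cauchy_negative",
               0: "cauchy"}[side]
        return EffectSizePrior(fam, self.scale)


@dataclass(frozen=True)
class CorrelationPrior:
    """Stretched beta prior on rho in (-1, 1) with width kappa.

    density(rho) proportional to (1 - rho^2)^(1/kappa - 1), normalized over
    the side's support.  kappa is restricted to (0, 2] so the implied beta
    shape parameters stay >= 1/2.
    """

    kappa: float = 1.0
    side: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 < self.kappa <= 2.0):
            raise ParameterError("stretched beta width kappa must be in (0, 2]")
        if self.side not in _SIDES:
            raise ParameterError(f"unknown side {self.side!r}")

    @property
    def _alpha(self) -> float:
        return 1.0 / self.kappa

    def pdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        a = self._alpha
        # two-sided normalizing constant: 2^(2a-1) * B(a, a)
        log_norm = (2 * a - 1) * math.log(2.0) + special.betaln(a, a)
        with np.errstate(divide="ignore"):
            log_dens = special.xlog1py(a - 1.0, -rho * rho) - log_norm
        dens = np.where(np.abs(rho) < 1.0, np.exp(log_dens), 0.0)
        if self.side == "positive":
            dens = np.where(rho >= 0, 2.0 * dens, 0.0)
        elif self.side == "negative":
            dens = np.where(rho <= 0, 2.0 * dens, 0.0)
        return dens if dens.ndim else float(dens)

    def with_side(self, side: str) -> "CorrelationPrior":
        return CorrelationPrior(self.kappa, side)


Prior = EffectSizePrior | CorrelationPrior


def prior_density(prior: Prior, x) -> float:
    """Height of the prior density at ``x`` (used for Savage-Dickey ratios)."""
    return prior.pdf(x)


def prior_mass_positive(prior: Prior) -> float:
    """Prior mass on the positive half-line; 1/2 for every symmetric prior."""
    if isinstance(prior, EffectSizePrior):
        if prior.side != 0:
            raise ParameterError("prior must be two-sided")
        return 0.5
    if prior.side != "two_sided":
        raise ParameterError("prior must be two-sided")
    return 0.5
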