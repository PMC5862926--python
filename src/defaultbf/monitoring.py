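"""Sequential evidence monitoring, robustness curves, stopping rules.

A sequential analysis recomputes the Bayes factor on growing data prefixes
(rows are assumed to be in data-collection order), one trace per prior
scale.  A robustness curve sweeps the prior scale on the full data.  The
stopping-rule evaluator replays a preregistered plan (minimum group size,
evidence threshold, maximum size) against a sequential trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .correlation import CorrelationStats, correlation_bf
from .data import DataTable, DataError
from .priors import CorrelationPrior, EffectSizePrior
from .results import BayesFactorResult
from .ttest import TTestSufficientStats, jzs_ttest_bf, pooled_t
from . import data as _data

__all__ = [
    "TTestAnalysis", "CorrelationAnalysis", "SequentialTrace",
    "StoppingRule", "StopDecision",
    "sequential_bf", "robustness_curve", "evaluate_stopping",
]


@dataclass(frozen=True)
class TTestAnalysis:
    """Two-sample t-test specification for monitoring."""

    dependent: str
    group: str
    hypothesis: str = "two_sided"

    @property
    def side(self) -> int:
        return {"two_sided": 0, "group1_greater": 1, "group2_greater": -1}[self.hypothesis]

    def bf(self, table: DataTable, scale: float) -> BayesFactorResult | None:
        if scale == 0.0:
            return BayesFactorResult(0.0, None, "H1 vs H0")
        desc = _data.descriptives(table, self.dependent, self.group)
        if len(desc) != 2 or any(d.n < 2 for d in desc):
            return None
        try:
            stats_ = pooled_t(desc)
        except DataError:
            return None
        prior = EffectSizePrior().folded(self.side)
        prior = EffectSizePrior(prior.family, scale)
        return jzs_ttest_bf(stats_, prior)

    def group_sizes(self, table: DataTable) -> tuple[int, ...]:
        desc_col = table.column(self.group)
        y = table.column(self.dependent)
        keep = desc_col.notna() & y.notna()
        return tuple(int(((desc_col == lev) & keep).sum())
                     for lev in table.group_levels(self.group))


@dataclass(frozen=True)
class CorrelationAnalysis:
    """Pearson-correlation specification for monitoring (scale = kappa)."""

    x: str
    y: str
    side: str = "two_sided"

    def bf(self, table: DataTable, scale: float) -> BayesFactorResult | None:
        if scale == 0.0:
            return BayesFactorResult(0.0, None, "H1 vs H0")
        xs = table.column(self.x)
        ys = table.column(self.y)
        keep = xs.notna() & ys.notna()
        xv = xs[keep].to_numpy(dtype=float)
        yv = ys[keep].to_numpy(dtype=float)
        if xv.size < 3 or np.std(xv) == 0 or np.std(yv) == 0:
            return None
        r = float(np.corrcoef(xv, yv)[0, 1])
        stats_ = CorrelationStats(xv.size, r)
        return correlation_bf(stats_, CorrelationPrior(scale, self.side))

    def group_sizes(self, table: DataTable) -> tuple[int, ...]:
        xs, ys = table.column(self.x), table.column(self.y)
        return (int((xs.notna() & ys.notna()).sum()),)


Analysis = TTestAnalysis | CorrelationAnalysis


@dataclass(frozen=True)
class SequentialTrace:
    """(n, log BF) evidence trace for one prior scale."""

    scale: float
    points: tuple[tuple[int, float], ...]
    group_sizes: tuple[tuple[int, ...], ...] = field(default=())

    @property
    def ns(self) -> list[int]:
        return [n for n, _ in self.points]

    @property
    def log_bfs(self) -> list[float]:
        return [b for _, b in self.points]

    def to_dict(self) -> dict:
        return {"scale": self.scale,
                "points": [{"n": n, "bf10": math.exp(b)} for n, b in self.points]}


def sequential_bf(table: DataTable, analysis: Analysis,
                  scales: Sequence[float]) -> list[SequentialTrace]:
    """One evidence trace per prior scale, recomputed on each data prefix.

    Rows must be in collection order; a trace starts at the first prefix
    where the statistic exists (two observations per group for the t-test,
    three complete pairs for the correlation).
    """
    traces = []
    for scale in scales:
        if scale < 0:
            raise ValueError("prior scales must be non-negative")
        pts: list[tuple[int, float]] = []
        sizes: list[tuple[int, ...]] = []
        for n in range(1, table.n_rows + 1):
            prefix = table.head(n)
            try:
                res = analysis.bf(prefix, scale)
            except (DataError, ValueError):
                res = None
            if res is None:
                continue
            pts.append((n, res.log_bf10))
            sizes.append(analysis.group_sizes(prefix))
        traces.append(SequentialTrace(scale, tuple(pts), tuple(sizes)))
    return traces


def robustness_curve(table: DataTable, analysis: Analysis,
                     r_grid: Sequence[float]) -> list[tuple[float, float]]:
    """(scale, log BF) on the full data for each prior scale in the grid.

    Scale 0 is the degenerate prior at the null value: the Bayes factor is
    exactly 1 (handled analytically, not by quadrature).
    """
    grid = list(r_grid)
    if any(r < 0 for r in grid):
        raise ValueError("prior scales must be non-negative")
    if sorted(grid) != grid:
        raise ValueError("r_grid must be ascending")
    out = []
    for scale in grid:
        res = analysis.bf(table, scale)
        if res is None:
            raise DataError("statistic undefined on the full data")
        out.append((scale, res.log_bf10))
    return out


@dataclass(frozen=True)
class StoppingRule:
    """Preregistered plan: minimum/maximum per group and a BF threshold."""

    min_per_group: int
    max_per_group: int
    bf_threshold: float

    def __post_init__(self) -> None:
        if self.min_per_group > self.max_per_group:
            raise ValueError("min_per_group cannot exceed max_per_group")
        if self.bf_threshold <= 1.0:
            raise ValueError("bf_threshold must exceed 1")


@dataclass(frozen=True)
class StopDecision:
    """Outcome of replaying a stopping rule over a sequential trace."""

    stopped: bool
    stop_n: int | None          # total n at the stopping point
    direction: str | None       # "H1" (BF >= thr) or "H0" (BF <= 1/thr)
    max_reached: bool


def evaluate_stopping(trace: SequentialTrace, rule: StoppingRule,
                      group_sizes: Sequence[Sequence[int]] | None = None
                      ) -> StopDecision:
    """First point satisfying the plan, else a max-reached/censored outcome.

    The trace's log BF is compared on the convention of its own comparison
    direction; crossing either the threshold or its reciprocal stops.
    """
    sizes = group_sizes if group_sizes is not None else trace.group_sizes
    if len(sizes) != len(trace.points):
        raise ValueError("trace and group sizes are not aligned")
    log_thr = math.log(rule.bf_threshold)
    for (n, log_bf), gs in zip(trace.points, sizes):
        if min(gs) < rule.min_per_group:
            continue
        if max(gs) > rule.max_per_group:
            break
        if log_bf >= log_thr:
            return StopDecision(True, n, "H1", False)
        if log_bf <= -log_thr:
            return StopDecision(True, n, "H0", False)
    return StopDecision(False, None, None, True)
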