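"""End-to-end ANOVA-family analyses: enumerate, estimate, tabulate.

These drivers glue the pieces together the way the worked examples do: build
the candidate model space under marginality, estimate each model's marginal
likelihood, and report the model-comparison and model-averaged effects
tables against the nuisance-only null model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .anova import (GPriorSettings, ModelSpec, build_design,
                    marginal_likelihood, canonical_term)
from .data import DataTable, wide_to_cells
from .modelspace import (EffectRow, ModelComparisonRow, comparison_table,
                         effects_table, enumerate_models)
from .results import BayesFactorResult

__all__ = ["AnovaResult", "run_anova", "run_rm_anova"]


@dataclass(frozen=True)
class AnovaResult:
    """Model comparison plus Bayesian-model-averaged effects."""

    models: list[ModelSpec]
    comparison: list[ModelComparisonRow]
    effects: list[EffectRow]

    @property
    def null_model(self) -> ModelSpec:
        return self.models[0]

    def bf_vs_null(self, model: ModelSpec) -> float:
        for row in self.comparison:
            if row.model == model:
                return row.bf10
        raise KeyError(f"model {model.name()} not in table")


def run_anova(table: DataTable, dependent: str,
              fixed: Sequence[str], random: Sequence[str] = (),
              nuisance: Sequence[Sequence[str] | str] = (),
              settings: GPriorSettings | None = None,
              max_order: int | None = None) -> AnovaResult:
    """Bayesian ANOVA over the full marginality-closed model space.

    ``random`` names factors treated as random effects (wider prior scale);
    they are added to every model as nuisance terms, as is anything in
    ``nuisance`` (a factor name or an explicit term tuple).
    """
    settings = settings or GPriorSettings()
    nuisance_terms = {canonical_term((t,) if isinstance(t, str) else t)
                      for t in nuisance}
    nuisance_terms |= {(f,) for f in random}
    models = enumerate_models(list(fixed), nuisance_terms,
                              max_order=max_order, random_factors=random)

    estimates = []
    for i, model in enumerate(models):
        per_model = replace(settings, seed=settings.seed + i)
        y, blocks = build_design(table, dependent, model)
        rand = [t for t in model.terms if model.is_random(t)]
        estimates.append(marginal_likelihood(y, blocks, per_model,
                                             random_terms=rand))

    null_est = estimates[0]
    bfs: dict[ModelSpec, BayesFactorResult] = {}
    for model, est in zip(models, estimates):
        err = (est.mc_error_pct ** 2 + null_est.mc_error_pct ** 2) ** 0.5
        if model is models[0]:
            err = 0.0
        bfs[model] = BayesFactorResult(est.log_ml - null_est.log_ml,
                                       err if err > 0 else None,
                                       f"{model.name()} vs Null model")
    rows = comparison_table(bfs)
    rows.sort(key=lambda r: models.index(r.model))
    effects = effects_table(rows)
    return AnovaResult(models, rows, effects)


def run_rm_anova(wide: DataTable,
                 factor_defs: Mapping[str, Sequence[str]],
                 cell_map: Mapping[str, Sequence[str]],
                 settings: GPriorSettings | None = None,
                 *, subject: str = "subject",
                 dependent: str = "value") -> AnovaResult:
    """Repeated-measures ANOVA with a random participant factor.

    The wide table (one column per cell) is reshaped to long format; the
    subject factor is random, included in every model (the null model is
    grand mean + subject).
    """
    long = wide_to_cells(wide, factor_defs, cell_map,
                         dependent=dependent, subject=subject)
    return run_anova(long, dependent, fixed=list(factor_defs),
                     random=[subject], settings=settings)
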