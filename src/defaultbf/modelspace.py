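"""Model enumeration under marginality, and Bayesian model averaging tables.

All probability arithmetic is done in log space with log-sum-exp so that
tables remain exact when Bayes factors reach magnitudes like 1e+39.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .anova import ModelSpec, Term, canonical_term, term_name
from .results import BayesFactorResult, format_bf

__all__ = [
    "ModelComparisonRow", "EffectRow",
    "enumerate_models", "comparison_table", "rebase_bayes_factors",
    "effects_table",
]


def enumerate_models(fixed_factors: Sequence[str],
                     nuisance_terms: Iterable[Iterable[str]] = (),
                     max_order: int | None = None,
                     random_factors: Iterable[str] = ()) -> list[ModelSpec]:
    """All marginality-closed candidate models for the given factors.

    Every interaction in a model is accompanied by all its sub-terms; each
    model additionally carries the nuisance terms; the nuisance-only null
    model comes first.  Models are ordered by size, then lexicographically.
    """
    factors = list(fixed_factors)
    if len(set(factors)) != len(factors):
        raise ValueError("factors must be unique")
    if not factors:
        raise ValueError("at least one factor is required")
    max_order = len(factors) if max_order is None else max_order
    nuisance = frozenset(canonical_term(t) for t in nuisance_terms)
    random_factors = frozenset(random_factors)

    candidate_terms = [canonical_term(c)
                       for k in range(1, max_order + 1)
                       for c in itertools.combinations(sorted(factors), k)]
    candidate_terms = [t for t in candidate_terms if t not in nuisance]

    models = []
    for mask in itertools.product([False, True], repeat=len(candidate_terms)):
        terms = {t for t, m in zip(candidate_terms, mask) if m}
        if all(sub in terms or sub in nuisance
               for t in terms for sub in _proper_subterms(t)):
            models.append(ModelSpec(frozenset(terms) | nuisance, nuisance,
                                    random_factors))
    models.sort(key=lambda m: (len(m.terms), sorted(m.terms)))
    return models


def _proper_subterms(term: Term) -> list[Term]:
    return [c for k in range(1, len(term))
            for c in itertools.combinations(term, k)]


@dataclass(frozen=True)
class ModelComparisonRow:
    """One row of the model-comparison table."""

    model: Hashable
    prior_prob: float
    posterior_prob: float
    log_bf10: float          # vs the table's base model
    bf_m: float              # change from prior to posterior model odds
    error_pct: float | None = None

    @property
    def bf10(self) -> float:
        return math.exp(self.log_bf10)

    def to_dict(self) -> dict:
        name = self.model.name() if isinstance(self.model, ModelSpec) else str(self.model)
        return {"model": name, "P(M)": self.prior_prob,
                "P(M|data)": self.posterior_prob,
                "BF10": self.bf10, "BFM": self.bf_m,
                "error_pct": self.error_pct}


def _as_log_bf(value) -> tuple[float, float | None]:
    if isinstance(value, BayesFactorResult):
        return value.log_bf10, value.error_pct
    return math.log(value) if value != 0 else -math.inf, None


def comparison_table(bfs: Mapping[Hashable, "BayesFactorResult | float"],
                     prior_probs: Mapping[Hashable, float] | str = "uniform"
                     ) -> list[ModelComparisonRow]:
    """P(M), P(M|data), BF10 and BF_M for each model.

    ``bfs`` maps each model to its Bayes factor against a common base model
    (base included, with BF 1).  P(M|data) = BF_m P(M) / sum_j BF_j P(M_j).
    """
    keys = list(bfs)
    log_bf = np.array([_as_log_bf(bfs[k])[0] for k in keys])
    errors = [_as_log_bf(bfs[k])[1] for k in keys]
    if prior_probs == "uniform":
        log_prior = np.full(len(keys), -math.log(len(keys)))
    else:
        prior = np.array([prior_probs[k] for k in keys], dtype=float)
        if abs(prior.sum() - 1.0) > 1e-9:
            raise ValueError(f"prior probabilities sum to {prior.sum()}, not 1")
        with np.errstate(divide="ignore"):
            log_prior = np.log(prior)
    log_joint = log_bf + log_prior
    log_post = log_joint - logsumexp(log_joint)
    rows = []
    for i, key in enumerate(keys):
        post = math.exp(log_post[i])
        prior_p = math.exp(log_prior[i])
        # BF_M = posterior odds / prior odds, in log space
        log_post_rest = logsumexp(np.delete(log_post, i))
        log_prior_rest = logsumexp(np.delete(log_prior, i))
        if post >= 1.0 or not math.isfinite(log_post_rest):
            bf_m = math.inf
        else:
            bf_m = math.exp(log_post[i] - log_post_rest
                            - (log_prior[i] - log_prior_rest))
        rows.append(ModelComparisonRow(key, prior_p, post, float(log_bf[i]),
                                       bf_m, errors[i]))
    return rows


def rebase_bayes_factors(bfs: Mapping[Hashable, "BayesFactorResult | float"],
                         new_base: Hashable) -> dict[Hashable, float]:
    """Re-express a BF map against a different base model (in log space)."""
    if new_base not in bfs:
        raise KeyError(f"new base {new_base!r} not present in the map")
    log_base = _as_log_bf(bfs[new_base])[0]
    return {k: math.exp(_as_log_bf(v)[0] - log_base) for k, v in bfs.items()}


@dataclass(frozen=True)
class EffectRow:
    """Bayesian-model-averaged inclusion summary for one term."""

    term: Term
    prior_inclusion: float
    posterior_inclusion: float
    bf_inclusion: float

    def to_dict(self) -> dict:
        return {"term": term_name(self.term), "P(incl)": self.prior_inclusion,
                "P(incl|data)": self.posterior_inclusion,
                "BF_inclusion": self.bf_inclusion}


def effects_table(rows: Sequence[ModelComparisonRow],
                  terms: Sequence[Iterable[str]] | None = None) -> list[EffectRow]:
    """Per-term inclusion probabilities summed over the model space.

    P(incl) sums P(M) over models containing the term; the inclusion Bayes
    factor is the ratio of posterior to prior inclusion odds.  Nuisance terms
    (present in every model) are not listed.
    """
    specs = [r.model for r in rows]
    if not all(isinstance(s, ModelSpec) for s in specs):
        raise TypeError("effects_table needs rows keyed by ModelSpec")
    nuisance = frozenset().union(*(s.nuisance for s in specs)) if specs else frozenset()
    if terms is None:
        all_terms = sorted({t for s in specs for t in s.terms} - nuisance,
                           key=lambda t: (len(t), t))
    else:
        all_terms = [canonical_term(t) for t in terms]
    out = []
    for term in all_terms:
        has = [term in s.terms for s in specs]
        if not any(has):
            raise ValueError(f"term {term_name(term)} absent from every model")
        p_incl = sum(r.prior_prob for r, h in zip(rows, has) if h)
        p_incl_post = sum(r.posterior_prob for r, h in zip(rows, has) if h)
        p_incl_post = min(p_incl_post, 1.0)
        if p_incl_post >= 1.0 and p_incl < 1.0:
            bf = math.inf
        elif p_incl >= 1.0:
            bf = math.nan
        else:
            bf = (p_incl_post / (1.0 - p_incl_post)) / (p_incl / (1.0 - p_incl))
        out.append(EffectRow(term, p_incl, p_incl_post, bf))
    return out


def format_comparison_table(rows: Sequence[ModelComparisonRow]) -> str:
    """Aligned-text rendering of a model-comparison table."""
    header = ["Models", "P(M)", "P(M|data)", "BF M", "BF 10", "error %"]
    body = []
    for r in rows:
        name = r.model.name() if isinstance(r.model, ModelSpec) else str(r.model)
        body.append([name, f"{r.prior_prob:.3f}", f"{r.posterior_prob:.3f}",
                     format_bf(r.bf_m), format_bf(r.bf10),
                     "" if r.error_pct is None else f"{r.error_pct:.3g}"])
    widths = [max(len(h), *(len(row[i]) for row in body))
              for i, h in enumerate(header)]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    for row in body:
        lines.append("  ".join(c.ljust(w) for c, w in zip(row, widths)))
    return "\n".join(lines)


def format_effects_table(rows: Sequence[EffectRow]) -> str:
    header = ["Effects", "P(incl)", "P(incl|data)", "BF Inclusion"]
    body = [[term_name(r.term), f"{r.prior_inclusion:.3f}",
             f"{r.posterior_inclusion:.3f}", format_bf(r.bf_inclusion)]
            for r in rows]
    widths = [max(len(h), *(len(row[i]) for row in body))
              for i, h in enumerate(header)]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    for row in body:
        lines.append("  ".join(c.ljust(w) for c, w in zip(row, widths)))
    return "\n".join(lines)
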