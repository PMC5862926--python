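"""Marginal likelihoods and Bayes factors for ANOVA-type linear models.

The model for a response y with factorial predictors is

    y = mu 1 + sum_t X_t beta_t + eps,      eps ~ N(0, sigma^2 I),

with the Jeffreys prior p(mu, sigma^2) proportional to 1/sigma^2 on the
common parameters and, per term t, a g-prior on standardized effects:
beta_t | g_t ~ N(0, g_t sigma^2 I).  Each term's g_t is mixed over a scaled
inverse-chi-square density (inverse-gamma(1/2, r_t^2 / 2)), which makes the
implied prior on standardized effect sizes Cauchy with scale r_t.  Fixed
factors default to r = 0.5; random (participant) factors get a wider r = 1
because subjects are assumed a priori variable.

Factor effects are coded on an orthonormal basis of the sum-to-zero subspace
(a k-level factor contributes k-1 columns; interactions use Kronecker
products of the component bases).  With this coding a balanced two-group
one-factor model with r = 0.5 is exactly the JZS t-test with Cauchy scale
sqrt(2)*0.5 = 0.707.

The remaining (g_1 ... g_p) integral is evaluated by deterministic quadrature
when p = 1 and by seeded importance sampling (log-normal proposal centered at
the Laplace mode found on the log-g scale) when p > 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special

from ._quadrature import adaptive_integrate
from .data import DataTable, DataError
from .results import BayesFactorResult

__all__ = [
    "ModelSpec", "GPriorSettings", "MarginalLikelihoodEstimate",
    "term_name", "build_design", "marginal_likelihood", "model_bf",
]

Term = tuple[str, ...]


def canonical_term(term: Iterable[str]) -> Term:
    return tuple(sorted(term))


def term_name(term: Term) -> str:
    return " * ".join(term)


def _subterms(term: Term) -> set[Term]:
    """All proper non-empty sub-terms of an interaction."""
    import itertools
    out: set[Term] = set()
    for k in range(1, len(term)):
        out.update(itertools.combinations(term, k))
    return out


@dataclass(frozen=True)
class ModelSpec:
    """A set of model terms closed under marginality.

    ``terms`` holds every term in the model (nuisance terms included);
    ``nuisance`` marks the subset present in every candidate model of an
    analysis; ``random_factors`` names factors treated as random effects.
    """

    terms: frozenset[Term]
    nuisance: frozenset[Term] = field(default_factory=frozenset)
    random_factors: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        terms = frozenset(canonical_term(t) for t in self.terms)
        nuisance = frozenset(canonical_term(t) for t in self.nuisance)
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "nuisance", nuisance)
        object.__setattr__(self, "random_factors", frozenset(self.random_factors))
        if not nuisance <= terms:
            raise ValueError("nuisance terms must be part of the model")
        for term in terms:
            missing = _subterms(term) - terms
            if missing:
                raise ValueError(
                    f"marginality violation: {term_name(term)} requires "
                    + ", ".join(sorted(term_name(t) for t in missing)))

    @property
    def sorted_terms(self) -> list[Term]:
        return sorted(self.terms, key=lambda t: (len(t), t))

    def name(self) -> str:
        effects = [t for t in self.sorted_terms if t not in self.nuisance]
        if not effects:
            return "Null model"
        return " + ".join(term_name(t) for t in effects)

    def is_random(self, term: Term) -> bool:
        return all(f in self.random_factors for f in term)


@dataclass(frozen=True)
class GPriorSettings:
    """Prior scales and Monte-Carlo controls for the g-prior integral."""

    r_fixed: float = 0.5
    r_random: float = 1.0
    mc_samples: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r_fixed <= 0 or self.r_random <= 0:
            raise ValueError("prior scales must be positive")
        if self.mc_samples < 100:
            raise ValueError("mc_samples must be at least 100")


@dataclass(frozen=True)
class MarginalLikelihoodEstimate:
    """log marginal likelihood with its Monte-Carlo error (0 if quadrature)."""

    log_ml: float
    mc_error_pct: float = 0.0
    high_error: bool = False


def _sum_to_zero_basis(k: int) -> np.ndarray:
    """Orthonormal k x (k-1) basis of the sum-to-zero subspace."""
    centering = np.eye(k) - np.ones((k, k)) / k
    eigval, eigvec = np.linalg.eigh(centering)
    return eigvec[:, eigval > 0.5]


def _indicator(table: DataTable, factor: str) -> tuple[np.ndarray, list]:
    col = table.column(factor)
    levels = table.group_levels(factor)
    if len(levels) < 2:
        raise DataError(f"factor {factor!r} has fewer than 2 levels")
    idx = {lev: i for i, lev in enumerate(levels)}
    z = np.zeros((table.n_rows, len(levels)))
    for i, v in enumerate(col):
        z[i, idx[v]] = 1.0
    return z, levels


def build_design(table: DataTable, dependent: str, model: ModelSpec
                 ) -> tuple[np.ndarray, dict[Term, np.ndarray]]:
    """Response vector and per-term effect-column blocks (complete cases).

    Main effects are Z_f Q_f with Z_f the cell indicator and Q_f the
    orthonormal sum-to-zero basis; an interaction block is the row-wise
    Kronecker product of its components' blocks.
    """
    if table.level(dependent) != "continuous":
        raise DataError(f"dependent column {dependent!r} must be continuous")
    factors = sorted({f for term in model.terms for f in term})
    for f in factors:
        if table.level(f) != "nominal":
            raise DataError(f"factor {f!r} must be nominal")
    frame = table.to_frame()[[dependent, *factors]].dropna().reset_index(drop=True)
    complete = DataTable(frame, {dependent: "continuous",
                                 **{f: "nominal" for f in factors}})
    y = complete.column(dependent).to_numpy(dtype=float)

    mains: dict[str, np.ndarray] = {}
    cells: dict[str, np.ndarray] = {}
    for f in factors:
        z, levels = _indicator(complete, f)
        cells[f] = z
        mains[f] = z @ _sum_to_zero_basis(len(levels))

    blocks: dict[Term, np.ndarray] = {}
    for term in model.sorted_terms:
        block = mains[term[0]]
        for f in term[1:]:
            # row-wise Kronecker of the component main-effect blocks
            block = (block[:, :, None] * mains[f][:, None, :]).reshape(len(y), -1)
        # an empty factorial cell leaves the interaction block unidentifiable
        if len(term) > 1:
            occupied = cells[term[0]]
            for f in term[1:]:
                occupied = (occupied[:, :, None] * cells[f][:, None, :]
                            ).reshape(len(y), -1)
            empty = np.flatnonzero(occupied.sum(axis=0) == 0)
            if empty.size:
                raise DataError(
                    f"term {term_name(term)} has {empty.size} empty cell(s)")
        blocks[term] = block
    return y, blocks


# -- the g integral --------------------------------------------------------

class _GIntegrand:
    """log of BF(g) against the null (intercept-only) model, times prior."""

    def __init__(self, y: np.ndarray, blocks: Mapping[Term, np.ndarray],
                 scales: Sequence[float]):
        self.terms = list(blocks)
        self.scales = np.asarray(scales, dtype=float)
        x = np.concatenate([blocks[t] for t in self.terms], axis=1)
        # integrating the intercept flat projects everything off the ones
        # vector; in unbalanced designs the effect columns are not already
        # orthogonal to it
        x = x - x.mean(axis=0)
        self.col_term = np.concatenate([
            np.full(blocks[t].shape[1], i) for i, t in enumerate(self.terms)])
        self.n = y.size
        yc = y - y.mean()
        self.yty = float(yc @ yc)
        self.xtx = x.T @ x
        self.xty = x.T @ yc

    @property
    def p(self) -> int:
        return len(self.terms)

    def log_bf(self, g: np.ndarray) -> float:
        """log BF(g) = -1/2 log|I + X G X'| - (n-1)/2 log(residual ratio)."""
        gcol = g[self.col_term]
        m = np.eye(len(gcol)) + self.xtx * np.sqrt(np.outer(gcol, gcol))
        sign, logdet = np.linalg.slogdet(m)
        if sign <= 0:
            return -np.inf
        rt_g = np.sqrt(gcol) * self.xty
        quad = self.yty - rt_g @ np.linalg.solve(m, rt_g)
        if quad <= 0:
            return -np.inf
        return -0.5 * logdet - (self.n - 1) / 2.0 * (math.log(quad) - math.log(self.yty))

    def log_prior(self, g: np.ndarray) -> float:
        """sum of log inverse-gamma(1/2, r^2/2) densities."""
        r2 = self.scales ** 2
        return float(np.sum(0.5 * np.log(r2 / 2.0) - special.gammaln(0.5)
                            - 1.5 * np.log(g) - r2 / (2.0 * g)))

    def log_h(self, u: np.ndarray) -> float:
        """integrand on the log-g scale, Jacobian included."""
        g = np.exp(u)
        return self.log_bf(g) + self.log_prior(g) + float(u.sum())


def _log_bf_quadrature(core: _GIntegrand) -> tuple[float, float]:
    """Deterministic single-g integral of BF(g) over its prior."""
    res = optimize.minimize_scalar(lambda u: -core.log_h(np.array([u])),
                                   bounds=(-20.0, 20.0), method="bounded")
    u0 = float(res.x)
    peak = core.log_h(np.array([u0]))

    def f(us: np.ndarray) -> np.ndarray:
        return np.array([math.exp(core.log_h(np.array([u])) - peak) for u in us])

    val, err = adaptive_integrate(f, u0 - 45.0, u0 + 45.0, initial_panels=16)
    return peak + math.log(val), err / val


def _log_bf_importance(core: _GIntegrand, settings: GPriorSettings
                       ) -> tuple[float, float]:
    """Seeded importance sampling with a log-normal proposal at the mode."""
    p = core.p
    res = optimize.minimize(lambda u: -core.log_h(np.asarray(u)),
                            x0=np.zeros(p), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8,
                                     "maxiter": 4000})
    mode = np.asarray(res.x, dtype=float)

    # finite-difference Hessian of -log_h at the mode
    h = 1e-4
    hess = np.zeros((p, p))
    f0 = core.log_h(mode)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            val = (core.log_h(mode + ei + ej) - core.log_h(mode + ei - ej)
                   - core.log_h(mode - ei + ej) + core.log_h(mode - ei - ej)
                   ) / (4 * h * h)
            hess[i, j] = hess[j, i] = -val
    try:
        cov = np.linalg.inv(hess)
        # symmetrize and inflate for heavier-than-Gaussian tails
        cov = 1.44 * 0.5 * (cov + cov.T)
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.eye(p) * 1.2

    rng = np.random.default_rng(settings.seed)
    m = settings.mc_samples
    z = rng.standard_normal((m, p))
    us = mode + z @ chol.T
    log_h = np.array([core.log_h(u) for u in us])
    # multivariate normal proposal log-density
    sol = np.linalg.solve(chol, (us - mode).T)
    log_q = (-0.5 * np.sum(sol * sol, axis=0)
             - 0.5 * p * math.log(2 * math.pi)
             - np.sum(np.log(np.diag(chol))))
    log_w = log_h - log_q
    log_w = np.where(np.isfinite(log_w), log_w, -np.inf)
    shift = log_w.max()
    w = np.exp(log_w - shift)
    est = float(w.mean())
    se = float(w.std(ddof=1) / math.sqrt(m))
    return shift + math.log(est), se / est


def _null_log_ml(y: np.ndarray) -> float:
    """Exact log marginal likelihood of the intercept-only model."""
    n = y.size
    yc = y - y.mean()
    yty = float(yc @ yc)
    return (special.gammaln((n - 1) / 2.0) - (n - 1) / 2.0 * math.log(math.pi)
            - 0.5 * math.log(n) - (n - 1) / 2.0 * math.log(yty))


def marginal_likelihood(y: np.ndarray, blocks: Mapping[Term, np.ndarray],
                        settings: GPriorSettings | None = None,
                        *, random_terms: Iterable[Term] = ()
                        ) -> MarginalLikelihoodEstimate:
    """log marginal likelihood of y under the model with the given blocks.

    ``blocks`` may be empty (the intercept-only null model).  Terms listed in
    ``random_terms`` use the wider random-effect scale.
    """
    settings = settings or GPriorSettings()
    y = np.asarray(y, dtype=float)
    if not blocks:
        return MarginalLikelihoodEstimate(_null_log_ml(y))
    p_cols = sum(b.shape[1] for b in blocks.values())
    if y.size <= p_cols + 1:
        raise DataError("not enough observations for the requested design")
    random_set = {canonical_term(t) for t in random_terms}
    scales = [settings.r_random if canonical_term(t) in random_set
              else settings.r_fixed for t in blocks]
    core = _GIntegrand(y, blocks, scales)
    if core.p == 1:
        log_bf, rel_err = _log_bf_quadrature(core)
        mc_error_pct = 100.0 * rel_err
    else:
        log_bf, rel_err = _log_bf_importance(core, settings)
        mc_error_pct = 100.0 * rel_err
    return MarginalLikelihoodEstimate(
        _null_log_ml(y) + log_bf, mc_error_pct, high_error=mc_error_pct > 15.0)


def model_bf(table: DataTable, dependent: str, model: ModelSpec,
             base: ModelSpec, settings: GPriorSettings | None = None
             ) -> BayesFactorResult:
    """Bayes factor of ``model`` against ``base`` (shared nuisance terms)."""
    settings = settings or GPriorSettings()
    if not base.nuisance == model.nuisance:
        raise DataError("model and base must share their nuisance terms")
    if not base.nuisance <= model.terms:
        raise DataError("nuisance terms must appear in the candidate model")
    if model.terms == base.terms:
        return BayesFactorResult(0.0, None, f"{model.name()} vs {base.name()}")
    ests = []
    for spec in (model, base):
        y, blocks = build_design(table, dependent, spec)
        rand = [t for t in spec.terms if spec.is_random(t)]
        ests.append(marginal_likelihood(y, blocks, settings, random_terms=rand))
    log_bf = ests[0].log_ml - ests[1].log_ml
    err = math.hypot(ests[0].mc_error_pct, ests[1].mc_error_pct)
    return BayesFactorResult(log_bf, err if err > 0 else None,
                             f"{model.name()} vs {base.name()}")
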