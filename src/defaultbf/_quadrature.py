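"""Adaptive vectorized quadrature used by every marginal-likelihood integral.

All Bayes factors in this package are one-dimensional integrals of smooth,
unimodal-ish densities (noncentral-t x Cauchy over the effect size, the exact
sample-correlation density x stretched beta over rho, the g-prior integrand
over log g).  They are evaluated with an adaptive composite Gauss-Legendre
rule that bisects panels until the nested coarse/fine estimates agree, calling
the integrand on whole abscissa arrays at once.  Integrals over the real line
are folded onto a finite interval with the tangent substitution
x = center + scale * tan(pi*u/2), u in (-1, 1).
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

__all__ = ["adaptive_integrate", "integrate_real_line", "QuadratureError"]

# nested Gauss-Legendre abscissae/weights on (-1, 1)
_X_LO, _W_LO = np.polynomial.legendre.leggauss(10)
_X_HI, _W_HI = np.polynomial.legendre.leggauss(21)


class QuadratureError(RuntimeError):
    """Raised when panel refinement fails to reach the requested tolerance."""


def _panel_estimates(f: Callable[[np.ndarray], np.ndarray],
                     lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Coarse and fine Gauss-Legendre estimates for a batch of panels."""
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    x_lo = mid[:, None] + half[:, None] * _X_LO[None, :]
    x_hi = mid[:, None] + half[:, None] * _X_HI[None, :]
    n_pan = lo.size
    vals = f(np.concatenate([x_lo.ravel(), x_hi.ravel()]))
    v_lo = vals[: n_pan * _X_LO.size].reshape(n_pan, -1)
    v_hi = vals[n_pan * _X_LO.size:].reshape(n_pan, -1)
    coarse = half * (v_lo @ _W_LO)
    fine = half * (v_hi @ _W_HI)
    return coarse, fine


def adaptive_integrate(f: Callable[[np.ndarray], np.ndarray],
                       a: float, b: float, *,
                       epsabs: float = 1e-10, epsrel: float = 1e-8,
                       initial_panels: int = 8, max_depth: int = 40,
                       max_panels: int = 4096) -> tuple[float, float]:
    """Integrate ``f`` on (a, b); returns (value, error_estimate).

    ``f`` must accept an ndarray of abscissae and return an ndarray of values.
    """
    edges = np.linspace(a, b, initial_panels + 1)
    lo, hi = edges[:-1], edges[1:]
    total = 0.0
    err = 0.0
    for _ in range(max_depth):
        coarse, fine = _panel_estimates(f, lo, hi)
        panel_err = np.abs(fine - coarse)
        running = total + fine.sum()
        tol = max(epsabs, epsrel * abs(running))
        # panels whose error is already negligible are retired
        keep = panel_err > tol / max(lo.size, 1) * 0.5
        total += fine[~keep].sum()
        err += panel_err[~keep].sum()
        if not keep.any():
            return total, err
        if lo.size > max_panels:
            raise QuadratureError(
                f"quadrature did not converge: {lo.size} panels, "
                f"residual error {panel_err[keep].sum():.3e}")
        lo, hi = lo[keep], hi[keep]
        mid = 0.5 * (lo + hi)
        lo = np.concatenate([lo, mid])
        hi = np.concatenate([mid, hi])
    raise QuadratureError("quadrature exceeded maximum refinement depth")


def integrate_real_line(f: Callable[[np.ndarray], np.ndarray], *,
                        center: float = 0.0, scale: float = 1.0,
                        lower: float | None = None, upper: float | None = None,
                        epsabs: float = 1e-10, epsrel: float = 1e-8) -> tuple[float, float]:
    """Integrate ``f`` over (lower, upper) (defaults to the whole real line).

    Uses x = center + scale*tan(pi u / 2); centering near the integrand's mass
    keeps the substituted integrand well resolved.
    """
    if scale <= 0 or not math.isfinite(scale):
        scale = 1.0

    def to_x(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        t = np.tan(0.5 * np.pi * u)
        x = center + scale * t
        jac = scale * 0.5 * np.pi * (1.0 + t * t)
        return x, jac

    def g(u: np.ndarray) -> np.ndarray:
        x, jac = to_x(u)
        return f(x) * jac

    def u_of(x: float) -> float:
        return 2.0 / np.pi * math.atan((x - center) / scale)

    a = -1.0 if lower is None or not math.isfinite(lower) else u_of(lower)
    b = 1.0 if upper is None or not math.isfinite(upper) else u_of(upper)
    # open interval: nudge off the poles of tan
    eps = 1e-15
    return adaptive_integrate(g, a + eps if a == -1.0 else a,
                              b - eps if b == 1.0 else b,
                              epsabs=epsabs, epsrel=epsrel)
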