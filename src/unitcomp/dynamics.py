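"""Deterministic 1-D map utilities: reproduction curves, fixed points, iteration.

Works on any :class:`~unitcomp.models.MapModel`.  All maps in the derived
family have strictly decreasing per-capita growth ``f(N)/N``, so for
``lam > 1`` the positive fixed point of ``f(N) = N`` exists and is unique —
the bracketed root-finder exploits this by doubling the upper bracket until
``f(N) < N``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .models import MapModel

__all__ = [
    "FixedPointResult",
    "reproduction_curve",
    "fixed_point",
    "iterate_map",
    "calibrate_a",
]

_BRACKET_EPS = 1e-12


@dataclass(frozen=True)
class FixedPointResult:
    """Positive fixed point of a population map with local stability.

    ``N_star = 0`` with ``converged=True`` means only the trivial fixed point
    exists (``lam <= 1``).  ``stable`` is ``|f'(N_star)| < 1``, with the
    derivative from a central difference.
    """

    N_star: float
    stable: bool
    derivative: float
    converged: bool


def _central_derivative(f, x: float) -> float:
    h = 1e-6 * max(1.0, abs(x))
    return (f(x + h) - f(x - h)) / (2.0 * h)


def reproduction_curve(model: MapModel, N_grid) -> pd.DataFrame:
    """Tabulate ``f(N)`` over a grid of population sizes.

    Returns a DataFrame with columns ``N``, ``f_N``, ``model`` and
    ``params_hash`` (a short stable hash of the model's parameters, so
    exported curves are traceable to the exact parameter set).
    """
    N_grid = np.asarray(N_grid, dtype=float)
    if N_grid.size == 0:
        raise ValueError("N_grid must be nonempty")
    if np.any(N_grid < 0):
        raise ValueError("N_grid must be non-negative")
    if np.any(np.diff(N_grid) <= 0) and N_grid.size > 1:
        raise ValueError("N_grid must be strictly increasing")
    f_N = np.asarray(model(N_grid), dtype=float)
    return pd.DataFrame(
        {
            "N": N_grid,
            "f_N": f_N,
            "model": model.name,
            "params_hash": model.params_hash(),
        }
    )


def fixed_point(model: MapModel) -> FixedPointResult:
    """Locate the positive fixed point ``f(N_star) = N_star`` of a map.

    For ``lam <= 1`` only the trivial fixed point 0 exists and is reported
    directly.  Otherwise the root of ``f(N) - N`` is bracketed in
    ``[1e-12, N_up]`` with ``N_up`` doubled until ``f(N_up) < N_up`` (unique
    sign change, since per-capita growth decreases), then solved by Brent's
    method.  If no bracket is found the result is flagged
    ``converged=False`` rather than fabricating a root.
    """
    lam = model.lam
    if lam <= 1.0:
        return FixedPointResult(
            N_star=0.0,
            stable=lam < 1.0,
            derivative=lam,
            converged=True,
        )
    g = lambda N: model(N) - N
    lo = _BRACKET_EPS
    hi = 1.0
    for _ in range(1024):
        if g(hi) < 0.0:
            break
        hi *= 2.0
    else:
        return FixedPointResult(
            N_star=math.nan, stable=False, derivative=math.nan, converged=False
        )
    if g(lo) <= 0.0:
        return FixedPointResult(
            N_star=math.nan, stable=False, derivative=math.nan, converged=False
        )
    N_star = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    deriv = _central_derivative(model, N_star)
    return FixedPointResult(
        N_star=float(N_star),
        stable=bool(abs(deriv) < 1.0),
        derivative=float(deriv),
        converged=True,
    )


def iterate_map(model: MapModel, N0: float, T: int) -> np.ndarray:
    """Deterministically iterate ``N -> f(N)`` for ``T`` steps.

    Returns the series ``[N0, f(N0), f(f(N0)), ...]`` of length ``T + 1``.
    Because the derived maps predict expected (not realised) populations,
    iterated values are the deterministic mean map, not a forecast of the
    stochastic process.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if N0 < 0:
        raise ValueError("N0 must be >= 0")
    series = np.empty(T + 1, dtype=float)
    series[0] = N0
    for t in range(1, T + 1):
        series[t] = model(series[t - 1])
    return series


def calibrate_a(lam: float, b: float, N_star_target: float) -> float:
    """Density-dependence scale ``a`` giving a prescribed fixed point.

    For the phenomenological Hassell map ``lam*N/(1+a*N)**b``, the positive
    fixed point is ``N_star = (lam**(1/b) - 1)/a``; inverting gives the unique
    ``a = (lam**(1/b) - 1)/N_star_target``.  Requires ``lam > 1`` (otherwise
    no positive fixed point exists).
    """
    if lam <= 1.0:
        raise ValueError("lam must be > 1 for a positive fixed point")
    if b <= 0 or N_star_target <= 0:
        raise ValueError("b and N_star_target must be > 0")
    return (lam ** (1.0 / b) - 1.0) / N_star_target
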