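"""Closed-form discrete-time population maps derived from unit competition.

Each function evaluates the expected next-generation population ``f(N)`` for
one member of the derived Hassell family.  Throughout, ``a = e^{u/Rbar} - 1``
is the density-dependence scale set by the unit size ``u`` relative to the
expected pool ``Rbar``, and the Hassell exponent equals the reproduction
threshold ``s = s'/u`` — so the exponent is inversely proportional to the
unit size, i.e. to the inequality of the random allocation.

The family and its limit relations:

* ``hassell_fp``      — lam*N / (1 + a*N)**s           (fixed threshold)
* ``beverton_holt``   — s = 1 case (maximal inequality, ideal contest)
* ``ricker``          — u -> 0 limit at fixed s' (equal shares, ideal scramble)
* ``nb_full``         — negative-binomially varying threshold
* ``hassell_nb``      — nb_full under k = s0; Hassell form with exponent k
* ``gamma_limit``     — u -> 0 limit of nb_full; real exponent k = s'^2/var(s')
* ``fecundity_full``  — saturating fecundity; dominated by hassell_fp
* ``fecundity_bh``    — its s = 1 case
* ``ricker_bh``       — its u -> 0 limit: Ricker times a Beverton-Holt factor
* ``hassell_pheno``   — the phenomenological map lam*N/(1+a*N)**b itself

``N`` may be a scalar or ndarray; all maps satisfy ``f(0) = 0``, ``f(N) > 0``
for ``N > 0``, and strictly decreasing per-capita growth ``f(N)/N``.

These maps predict the *expected* next population; they are the exact
expectation of the individual-based process in :mod:`unitcomp.simulator`,
and agree with the truncated series of
:func:`unitcomp.allocation.series_expected_population` to the series
tolerance.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .params import CompetitionParams, FecundityLaw, ThresholdLaw

__all__ = [
    "MapModel",
    "make_model",
    "hassell_fp",
    "beverton_holt",
    "ricker",
    "nb_full",
    "hassell_nb",
    "shape_from_moments",
    "gamma_limit",
    "fecundity_full",
    "fecundity_bh",
    "ricker_bh",
    "hassell_pheno",
]


def _check_N(N):
    N = np.asarray(N, dtype=float)
    if np.any(N < 0):
        raise ValueError("N must be >= 0")
    return N


def _scalarize(x):
    return float(x) if np.ndim(x) == 0 else x


def hassell_fp(N, params: CompetitionParams):
    """Derived Hassell map ``lam*N / (1 + a*N)**s`` with exponent ``s = s'/u``."""
    N = _check_N(N)
    return _scalarize(params.lam * N / (1.0 + params.a * N) ** params.s)


def beverton_holt(N, params: CompetitionParams):
    """Beverton-Holt map ``lam*N / (1 + a*N)``: the ``s = 1`` case.

    Maximal allocation inequality (one unit suffices to reproduce; ideal
    contest).  Monotone in ``N`` with asymptote ``lam/a``.  Requires
    ``params.s == 1``.
    """
    if params.s != 1:
        raise ValueError(f"beverton_holt requires s=1, got s={params.s}")
    N = _check_N(N)
    return _scalarize(params.lam * N / (1.0 + params.a * N))


def ricker(N, sprime: float, Rbar: float, lam: float):
    """Ricker map ``lam*N*exp(-s'*N/Rbar)``: equal-allocation (u -> 0) limit.

    ``sprime`` is the resource amount required for reproduction.  The map
    peaks at ``N = Rbar/sprime``.
    """
    if sprime <= 0 or Rbar <= 0 or lam <= 0:
        raise ValueError("sprime, Rbar and lam must all be > 0")
    N = _check_N(N)
    return _scalarize(lam * N * np.exp(-sprime * N / Rbar))


def nb_full(N, params: CompetitionParams, law: ThresholdLaw):
    """Map for a negative-binomially varying reproduction threshold.

    ``f(N) = lam*N/(1+aN)**s0 * ((1+aN)/(1+(1+delta/k)aN))**k``; the
    expectation of the fixed-threshold map over the threshold law.
    """
    if law.continuous:
        raise ValueError("nb_full requires the discrete threshold law")
    N = _check_N(N)
    aN = params.a * N
    ratio = (1.0 + aN) / (1.0 + (1.0 + law.delta / law.k) * aN)
    return _scalarize(params.lam * N / (1.0 + aN) ** law.s0 * ratio**law.k)


def hassell_nb(N, params: CompetitionParams, law: ThresholdLaw):
    """Hassell form of the varying-threshold map, valid under ``k = s0``.

    ``f(N) = lam*N / (1 + (1+delta/k) a N)**k``: a Hassell map whose exponent
    ``k`` shrinks as the threshold variance grows.  The reduction from
    :func:`nb_full` holds only when the shape equals the minimum threshold,
    so ``law.k == law.s0`` is enforced.
    """
    if law.continuous:
        raise ValueError("hassell_nb requires the discrete threshold law")
    if law.k != law.s0:
        raise ValueError(
            f"hassell_nb requires k == s0 (got k={law.k}, s0={law.s0})"
        )
    N = _check_N(N)
    scale = (1.0 + law.delta / law.k) * params.a
    return _scalarize(params.lam * N / (1.0 + scale * N) ** law.k)


def shape_from_moments(
    sbar_prime: float, var_sprime: float, u: float
) -> tuple[float, float]:
    """Threshold-law shape ``k`` and mean excess ``delta`` from amount moments.

    Given the mean ``sbar_prime`` and variance ``var_sprime`` of the required
    resource amount ``s'`` and the unit size ``u``:

        k     = sbar_prime / (u + var_sprime / sbar_prime)
        delta = (var_sprime / u) / (u + var_sprime / sbar_prime)

    ``k`` mixes the allocation inequality (through ``u``) with the threshold
    variation; increasing ``var_sprime`` at fixed ``sbar_prime`` decreases the
    Hassell exponent.  At ``u = 0`` only the variation survives:
    ``k = sbar_prime**2 / var_sprime`` and ``delta`` diverges (returned as
    ``math.inf``).  The degenerate case ``u = 0, var_sprime = 0`` has no
    finite shape and raises.
    """
    if sbar_prime <= 0:
        raise ValueError("sbar_prime must be > 0")
    if var_sprime < 0:
        raise ValueError("var_sprime must be >= 0")
    if u < 0:
        raise ValueError("u must be >= 0")
    if u == 0 and var_sprime == 0:
        raise ValueError("u = 0 with var_sprime = 0: shape parameter diverges")
    denom = u + var_sprime / sbar_prime
    k = sbar_prime / denom
    delta = math.inf if u == 0 else (var_sprime / u) / denom
    return k, delta


def gamma_limit(N, sbar_prime: float, k: float, Rbar: float, lam: float):
    """Equal-allocation map with a gamma-distributed required amount.

    ``f(N) = lam*N / (1 + sbar_prime*N/(k*Rbar))**k``: the ``u -> 0`` limit of
    :func:`nb_full` at fixed mean amount ``sbar_prime``.  The exponent
    ``k = sbar_prime**2 / var(s')`` may be any positive real — the only member
    of the family with a non-integer exponent.
    """
    if sbar_prime <= 0 or k <= 0 or Rbar <= 0 or lam <= 0:
        raise ValueError("sbar_prime, k, Rbar and lam must all be > 0")
    N = _check_N(N)
    return _scalarize(lam * N / (1.0 + sbar_prime / (k * Rbar) * N) ** k)


def _check_fecundity_law(params: CompetitionParams, law: FecundityLaw) -> None:
    if (law.lam, law.u, law.s) != (params.lam, params.u, params.s):
        raise ValueError("fecundity law (lam, u, s) must match CompetitionParams")


def fecundity_full(N, params: CompetitionParams, law: FecundityLaw):
    """Map with saturating fecundity above the threshold.

    ``f(N) = lam*N / ((1+aN)**(s-1) * (1 + xi*aN))`` with
    ``xi = (1-e^{-gamma*u})^{-1} >= 1``: one factor of the fixed-threshold
    denominator has ``N`` inflated to ``xi*N``, so the map is dominated by
    :func:`hassell_fp` (strictly for ``N > 0`` and finite ``gamma``).
    """
    _check_fecundity_law(params, law)
    N = _check_N(N)
    aN = params.a * N
    return _scalarize(
        params.lam * N / ((1.0 + aN) ** (params.s - 1) * (1.0 + law.xi * aN))
    )


def fecundity_bh(N, params: CompetitionParams, law: FecundityLaw):
    """Beverton-Holt form of the saturating-fecundity map (``s = 1``)."""
    _check_fecundity_law(params, law)
    if params.s != 1:
        raise ValueError(f"fecundity_bh requires s=1, got s={params.s}")
    N = _check_N(N)
    aN = params.a * N
    return _scalarize(params.lam * N / (1.0 + law.xi * aN))


def ricker_bh(N, sprime: float, Rbar: float, lam: float, gamma: float):
    """Equal-allocation limit of the saturating-fecundity map.

    ``f(N) = lam*N*exp(-s'N/Rbar) / (1 + N/(gamma*Rbar))``: the Ricker map
    damped by a Beverton-Holt-style factor, hence below the Ricker map
    everywhere for finite ``gamma``.
    """
    if sprime <= 0 or Rbar <= 0 or lam <= 0 or gamma <= 0:
        raise ValueError("sprime, Rbar, lam and gamma must all be > 0")
    N = _check_N(N)
    return _scalarize(
        lam * N * np.exp(-sprime * N / Rbar) / (1.0 + N / (gamma * Rbar))
    )


def hassell_pheno(N, lam: float, a: float, b: float):
    """Phenomenological Hassell map ``lam*N / (1 + a*N)**b``.

    The population-level form with free parameters; in the derived maps
    ``a = e^{u/Rbar} - 1`` and ``b`` is the threshold ``s`` (or shape ``k``).
    """
    if lam <= 0 or a <= 0 or b <= 0:
        raise ValueError("lam, a and b must all be > 0")
    N = _check_N(N)
    return _scalarize(lam * N / (1.0 + a * N) ** b)


@dataclass(frozen=True)
class MapModel:
    """A named 1-D population map ``N -> f(N)`` with its parameters.

    ``f`` accepts scalars or arrays of non-negative ``N``.  ``params`` holds
    the scalar parameters actually used (for reporting and hashing);
    ``params["lam"]`` is the density-independent growth factor, needed by
    fixed-point analysis.
    """

    name: str
    params: dict = field(hash=False)
    f: Callable = field(hash=False, compare=False)

    @property
    def lam(self) -> float:
        return float(self.params["lam"])

    def params_hash(self) -> str:
        """Short stable hash of (name, params) for tagging exported tables."""
        blob = json.dumps({"name": self.name, "params": self.params}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def __call__(self, N):
        return self.f(N)


def make_model(name: str, **kw) -> MapModel:
    """Construct a :class:`MapModel` by name.

    Recognised names and their keyword parameters:

    - ``hassell_fp``, ``beverton_holt``: ``lam, u, Rbar, s``
    - ``ricker``: ``sprime, Rbar, lam``
    - ``nb_full``, ``hassell_nb``: ``lam, u, Rbar, s0, delta, k`` (``s`` of the
      competition bundle is irrelevant and set to ``s0``)
    - ``gamma_limit``: ``sbar_prime, k, Rbar, lam``
    - ``fecundity_full``, ``fecundity_bh``: ``lam, u, Rbar, s, gamma``
    - ``ricker_bh``: ``sprime, Rbar, lam, gamma``
    - ``hassell`` (phenomenological): ``lam, a, b``
    """
    if name in ("hassell_fp", "beverton_holt"):
        p = CompetitionParams(lam=kw["lam"], u=kw["u"], Rbar=kw["Rbar"],
                              s=int(kw.get("s", 1)))
        fn = hassell_fp if name == "hassell_fp" else beverton_holt
        params = {"lam": p.lam, "u": p.u, "Rbar": p.Rbar, "s": p.s}
        return MapModel(name, params, lambda N, p=p: fn(N, p))
    if name == "ricker":
        args = {k: float(kw[k]) for k in ("sprime", "Rbar", "lam")}
        return MapModel(name, args, lambda N, a=args: ricker(N, **a))
    if name in ("nb_full", "hassell_nb"):
        p = CompetitionParams(lam=kw["lam"], u=kw["u"], Rbar=kw["Rbar"],
                              s=int(kw["s0"]))
        law = ThresholdLaw(s0=int(kw["s0"]), delta=float(kw["delta"]),
                           k=float(kw["k"]))
        fn = nb_full if name == "nb_full" else hassell_nb
        if name == "hassell_nb" and law.k != law.s0:
            raise ValueError("hassell_nb requires k == s0")
        params = {"lam": p.lam, "u": p.u, "Rbar": p.Rbar,
                  "s0": law.s0, "delta": law.delta, "k": law.k}
        return MapModel(name, params, lambda N, p=p, l=law: fn(N, p, l))
    if name == "gamma_limit":
        args = {k: float(kw[k]) for k in ("sbar_prime", "k", "Rbar", "lam")}
        return MapModel(name, args, lambda N, a=args: gamma_limit(N, **a))
    if name in ("fecundity_full", "fecundity_bh"):
        p = CompetitionParams(lam=kw["lam"], u=kw["u"], Rbar=kw["Rbar"],
                              s=int(kw.get("s", 1)))
        law = FecundityLaw(lam=p.lam, gamma=float(kw["gamma"]), s=p.s, u=p.u)
        fn = fecundity_full if name == "fecundity_full" else fecundity_bh
        params = {"lam": p.lam, "u": p.u, "Rbar": p.Rbar, "s": p.s,
                  "gamma": law.gamma}
        return MapModel(name, params, lambda N, p=p, l=law: fn(N, p, l))
    if name == "ricker_bh":
        args = {k: float(kw[k]) for k in ("sprime", "Rbar", "lam", "gamma")}
        return MapModel(name, args, lambda N, a=args: ricker_bh(N, **a))
    if name == "hassell":
        args = {k: float(kw[k]) for k in ("lam", "a", "b")}
        return MapModel(name, args, lambda N, a=args: hassell_pheno(N, **a))
    raise ValueError(f"unknown model name {name!r}")
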