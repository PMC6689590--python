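"""Exact probability laws of the unit-allocation process and series oracles.

Everything here is derived from one stochastic picture: ``M`` resource units
are handed out one at a time, each to a uniformly random one of ``N``
individuals.  The per-individual unit count is then binomial; when the total
pool ``R`` is exponential with mean ``Rbar``, the unit total ``M = floor(R/u)``
is geometric, and the per-individual count marginalised over ``M`` is again
geometric.

The :func:`series_expected_population` oracle evaluates the expected
next-generation population as a directly truncated infinite sum over the
pool size (or the threshold / unit-count distribution), with a rigorous
geometric tail bound.  The closed-form maps in :mod:`unitcomp.models` must
reproduce these sums to within the truncation tolerance; that numerical
equivalence is the executable form of the summation identities behind the
derived maps.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .params import CompetitionParams, FecundityLaw, ThresholdLaw

__all__ = [
    "ConvergenceError",
    "unit_count_pmf",
    "allocation_variance",
    "success_prob",
    "unit_total_pmf",
    "obtained_units_pmf",
    "obtained_units_pmf_mixture",
    "threshold_pmf",
    "threshold_gamma_pdf",
    "fecundity_at",
    "series_expected_population",
]

#: Hard cap on the number of series terms before declaring non-convergence.
MAX_TERMS = 10_000_000


class ConvergenceError(RuntimeError):
    """A truncated series could not reach the requested tail bound."""


def _check_int(x, name: str) -> int:
    if isinstance(x, bool) or int(x) != x:
        raise ValueError(f"{name} must be an integer, got {x!r}")
    return int(x)


def unit_count_pmf(m: int, M: int, N: int) -> float:
    """Probability that one individual obtains exactly ``m`` of ``M`` units.

    Each of the ``M`` units independently goes to one of ``N`` equally likely
    individuals, so the count for a focal individual is
    ``Binomial(M, 1/N)``.  For ``N = 1`` the law is degenerate at ``m = M``
    (with the ``0**0 = 1`` convention).

    Raises
    ------
    ValueError
        If ``m > M``, any argument is negative, or ``N < 1``.
    """
    m = _check_int(m, "m")
    M = _check_int(M, "M")
    N = _check_int(N, "N")
    if m < 0 or M < 0:
        raise ValueError("m and M must be non-negative")
    if N < 1:
        raise ValueError("N must be >= 1")
    if m > M:
        raise ValueError(f"m={m} exceeds M={M}")
    if N == 1:
        return 1.0 if m == M else 0.0
    return float(stats.binom.pmf(m, M, 1.0 / N))


def allocation_variance(params: CompetitionParams, R: float, N: int) -> float:
    """Variance of the resource amount ``u*m`` allocated to one individual.

    For a fixed pool ``R = u*M`` shared by ``N`` individuals,
    ``Var[u*m] = u*R*(1 - 1/N)/N``: at fixed ``R`` the allocation variance —
    the inequality among individuals — is proportional to the unit size.
    """
    N = _check_int(N, "N")
    if R <= 0:
        raise ValueError("R must be > 0")
    if N < 1:
        raise ValueError("N must be >= 1")
    return params.u * R * (1.0 - 1.0 / N) / N


def success_prob(M: int, s: int, N: int) -> float:
    """Probability ``Q(M)`` that an individual gets at least ``s`` of ``M`` units.

    ``Q(M) = sum_{m=s}^{M} p_m(M)`` (zero when ``M < s``).  Evaluated through
    the binomial survival function (regularised incomplete beta) rather than
    term-by-term summation, so it stays accurate for large ``M``.
    """
    M = _check_int(M, "M")
    s = _check_int(s, "s")
    N = _check_int(N, "N")
    if M < 0 or s < 1 or N < 1:
        raise ValueError("require M >= 0, s >= 1, N >= 1")
    if M < s:
        return 0.0
    if N == 1:
        return 1.0  # sole individual takes the whole pool
    return float(stats.binom.sf(s - 1, M, 1.0 / N))


def unit_total_pmf(M: int, params: CompetitionParams) -> float:
    """Geometric pmf of the total unit count ``M = floor(R/u)``.

    With ``R`` exponential (mean ``Rbar``),
    ``P_M = (1 - e^{-u/Rbar}) e^{-M u/Rbar}``; the mean is
    ``1/(e^{u/Rbar} - 1)``.
    """
    M = _check_int(M, "M")
    if M < 0:
        raise ValueError("M must be >= 0")
    w = params.u / params.Rbar
    return float(-math.expm1(-w) * math.exp(-M * w))


def obtained_units_pmf(m: int, N: int, params: CompetitionParams) -> float:
    """Marginal pmf of one individual's unit count under an exponential pool.

    Marginalising the binomial count over the geometric pool size gives a
    geometric law with mean ``q = 1/((e^{u/Rbar}-1) N)``:

        p_hat_m = q^m (1 + q)^{-m-1} = (aN / (1 + aN)) * (1 + aN)^{-m},

    with ``a = e^{u/Rbar} - 1``.
    """
    m = _check_int(m, "m")
    N = _check_int(N, "N")
    if m < 0:
        raise ValueError("m must be >= 0")
    if N < 1:
        raise ValueError("N must be >= 1")
    aN = params.a * N
    x = 1.0 / (1.0 + aN)  # success ratio, < 1
    return float((aN * x) * x**m)


def obtained_units_pmf_mixture(
    m: int, N: int, params: CompetitionParams, tol: float = 1e-12
) -> float:
    """Direct mixture evaluation ``sum_M p_m(M) P_M`` of the marginal count law.

    Truncated-sum oracle for :func:`obtained_units_pmf`: sums the binomial
    pmf at fixed pool size against the geometric pool-size law until the
    remaining geometric tail mass is below ``tol``.
    """
    m = _check_int(m, "m")
    N = _check_int(N, "N")
    if m < 0 or N < 1:
        raise ValueError("require m >= 0 and N >= 1")
    w = params.u / params.Rbar
    M_max = _geometric_tail_cutoff(w, 1.0, tol)
    Ms = np.arange(m, M_max + 1)
    if N == 1:
        pm = np.where(Ms == m, 1.0, 0.0)  # degenerate allocation
    else:
        pm = stats.binom.pmf(m, Ms, 1.0 / N)
    PM = -math.expm1(-w) * np.exp(-Ms * w)
    return float(np.dot(pm, PM))


def threshold_pmf(s: int, law: ThresholdLaw) -> float:
    """Pmf of a negative-binomially varying reproduction threshold.

    ``s - s0`` is negative binomial with mean ``delta`` and shape ``k``;
    zero below the minimum threshold ``s0``.
    """
    s = _check_int(s, "s")
    if law.continuous:
        raise ValueError("threshold_pmf requires the discrete threshold law")
    if s < law.s0:
        return 0.0
    p = law.k / (law.k + law.delta)
    return float(stats.nbinom.pmf(s - law.s0, law.k, p))


def threshold_gamma_pdf(sprime: float, law: ThresholdLaw) -> float:
    """Density of the gamma-limit threshold law for the required amount ``s'``.

    Gamma with mean ``sbar_prime`` and shape ``k`` (variance
    ``sbar_prime**2/k``); zero for ``sprime <= 0``.
    """
    if not law.continuous:
        raise ValueError("threshold_gamma_pdf requires the gamma-limit law")
    if sprime <= 0:
        return 0.0
    return float(stats.gamma.pdf(sprime, a=law.k, scale=law.sbar_prime / law.k))


def fecundity_at(m: int, law: FecundityLaw) -> float:
    """Expected offspring of an individual holding ``m`` units.

    Zero below the threshold ``s``; above it,
    ``lam * (1 - e^{-gamma*u*(m-s+1)})``, saturating to ``lam``.
    """
    m = _check_int(m, "m")
    if m < law.s:
        return 0.0
    return float(law.lam * -math.expm1(-law.gamma * law.u * (m - law.s + 1)))


def _geometric_tail_cutoff(log_ratio: float, scale: float, tol: float) -> int:
    """Smallest cutoff ``M`` with ``scale * e^{-(M+1) log_ratio} < tol``.

    ``log_ratio`` is the per-term decay exponent of the geometric tail bound.
    Raises :class:`ConvergenceError` if more than ``MAX_TERMS`` terms would be
    needed.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if scale < tol:
        return 0
    M = int(math.ceil(math.log(scale / tol) / log_ratio))
    if M > MAX_TERMS:
        raise ConvergenceError(
            f"series needs ~{M} terms to reach tail bound {tol:g} "
            f"(cap {MAX_TERMS}); increase tol"
        )
    return M


def _series_fixed(N: int, params: CompetitionParams, s: int, tol: float) -> float:
    """Truncated ``sum_M lam*N*Q(M)*P_M`` with geometric tail bound."""
    lamN = params.lam * N
    w = params.u / params.Rbar
    M_max = _geometric_tail_cutoff(w, lamN, tol)
    Ms = np.arange(s, M_max + 1)  # Q(M) = 0 below s
    if Ms.size == 0:
        return 0.0
    if N == 1:
        Q = np.ones_like(Ms, dtype=float)
    else:
        Q = stats.binom.sf(s - 1, Ms, 1.0 / N)
    PM = -math.expm1(-w) * np.exp(-Ms * w)
    return float(lamN * np.dot(Q, PM))


def _series_variable_threshold(
    N: int, params: CompetitionParams, law: ThresholdLaw, tol: float
) -> float:
    """Truncated ``sum_s lam*N*(1+aN)^{-s} p_s`` over the threshold law."""
    if law.continuous:
        raise ValueError("variable-threshold series requires the discrete law")
    lamN = params.lam * N
    p_succ = law.k / (law.k + law.delta)
    # tail of the series is bounded by lamN * P(threshold > s_max)
    s_max = law.s0 + 10
    while lamN * stats.nbinom.sf(s_max - law.s0, law.k, p_succ) >= tol:
        s_max *= 2
        if s_max > MAX_TERMS:
            raise ConvergenceError(
                f"threshold series cannot reach tail bound {tol:g} "
                f"within {MAX_TERMS} terms"
            )
    ss = np.arange(law.s0, s_max + 1)
    ps = stats.nbinom.pmf(ss - law.s0, law.k, p_succ)
    x = 1.0 / (1.0 + params.a * N)
    return float(lamN * np.dot(ps, x**ss))


def _series_fecundity(
    N: int, params: CompetitionParams, law: FecundityLaw, tol: float
) -> float:
    """Truncated ``N * sum_{m>=s} lam_m p_hat_m`` for saturating fecundity."""
    if (law.u, law.s, law.lam) != (params.u, params.s, params.lam):
        raise ValueError("fecundity law (lam, u, s) must match CompetitionParams")
    lamN = params.lam * N
    aN = params.a * N
    # tail mass of p_hat beyond m_max is (1+aN)^{-(m_max+1)}
    m_max = _geometric_tail_cutoff(math.log1p(aN), lamN, tol)
    ms = np.arange(law.s, m_max + 1)
    if ms.size == 0:
        return 0.0
    x = 1.0 / (1.0 + aN)
    p_hat = (aN * x) * x**ms
    lam_m = law.lam * -np.expm1(-law.gamma * law.u * (ms - law.s + 1))
    return float(N * np.dot(lam_m, p_hat))


def series_expected_population(
    N: int,
    params: CompetitionParams,
    mode: str = "fixed_threshold",
    law: ThresholdLaw | FecundityLaw | None = None,
    tol: float = 1e-12,
) -> float:
    """Expected next-generation population by direct series summation.

    This is the oracle against which the closed-form maps are verified.  The
    infinite sum is truncated with a rigorous geometric tail bound below
    ``tol`` (each summand is at most ``lam*N`` times a geometric tail mass);
    if the bound cannot be met within the term cap, a
    :class:`ConvergenceError` is raised rather than returning a silently
    under-converged value.

    Parameters
    ----------
    N : int
        Current population size (``N = 0`` returns 0).
    params : CompetitionParams
        Core competition parameters.
    mode : {"fixed_threshold", "variable_threshold", "fecundity"}
        Which process variant to sum: the fixed threshold ``params.s``, a
        negative-binomial threshold law, or a saturating fecundity law.
    law : ThresholdLaw or FecundityLaw, optional
        Required for the two extension modes.
    tol : float
        Tail bound for the truncation; also the guaranteed agreement level
        with the matching closed form.
    """
    N = _check_int(N, "N")
    if N < 0:
        raise ValueError("N must be >= 0")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if N == 0:
        return 0.0
    if mode == "fixed_threshold":
        return _series_fixed(N, params, params.s, tol)
    if mode == "variable_threshold":
        if not isinstance(law, ThresholdLaw):
            raise ValueError("variable_threshold mode requires a ThresholdLaw")
        return _series_variable_threshold(N, params, law, tol)
    if mode == "fecundity":
        if not isinstance(law, FecundityLaw):
            raise ValueError("fecundity mode requires a FecundityLaw")
        return _series_fecundity(N, params, law, tol)
    raise ValueError(f"unknown mode {mode!r}")
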