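"""Seeded individual-based Monte-Carlo simulator of unit-resource competition.

One generation: draw the resource pool ``R`` (fixed, or exponential with mean
``Rbar``), split it into ``M = floor(R/u)`` units, hand each unit to a
uniformly random one of ``N`` individuals, then score each individual against
its reproduction threshold and fecundity rule.  The expectation of the
resulting offspring total is exactly what the closed-form maps in
:mod:`unitcomp.models` predict, which makes the simulator the ground-truth
cross-check for every derived map.

Unit assignment is realised as one ``N``-sided multinomial of size ``M`` —
the same law as the per-unit loop, at O(N) cost.

Note that the derived maps give the *expected* next population; they are not
meant for iterated deterministic prediction.  :func:`stochastic_trajectory`
therefore realises offspring numbers stochastically (Poisson by default) and
is labelled a stochastic extension of the one-generation model, not part of
the derivation itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import CompetitionParams, FecundityLaw, ThresholdLaw

__all__ = [
    "GenerationOutcome",
    "MonteCarloEstimate",
    "simulate_generation",
    "estimate_f",
    "stochastic_trajectory",
]


@dataclass(frozen=True)
class GenerationOutcome:
    """Result of one simulated generation.

    ``units_per_individual`` sums to ``M = floor(R_drawn/u)``;
    ``n_successes`` counts individuals at or above their (possibly
    individual-specific) threshold; ``offspring_expectation`` is the summed
    expected offspring ``sum_i lam_{m_i}``.
    """

    units_per_individual: np.ndarray
    n_successes: int
    offspring_expectation: float
    R_drawn: float
    M: int


@dataclass(frozen=True)
class MonteCarloEstimate:
    """Monte-Carlo mean with standard error (sample sd / sqrt(reps)).

    Re-running with the same integer seed reproduces ``mean`` bitwise.
    """

    mean: float
    stderr: float
    reps: int
    seed: int | None


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _seed_of(rng) -> int | None:
    return rng if isinstance(rng, (int, np.integer)) else None


def _draw_batch(
    reps: int,
    N: int,
    params: CompetitionParams,
    R: float | None,
    threshold_mode: str,
    threshold_law: ThresholdLaw | None,
    fecundity_mode: str,
    fecundity_law: FecundityLaw | None,
    rng: np.random.Generator,
):
    """Simulate ``reps`` independent generations; return per-rep arrays.

    Returns ``(counts, successes, offspring, R_drawn, M)`` where ``counts``
    has shape ``(reps, N)`` and the rest are length-``reps`` vectors
    (``successes`` is the per-rep success count).
    """
    if R is None:
        R_drawn = rng.exponential(params.Rbar, size=reps)
    else:
        if R < 0:
            raise ValueError("fixed R must be >= 0")
        R_drawn = np.full(reps, float(R))
    M = np.floor(R_drawn / params.u).astype(np.int64)
    counts = rng.multinomial(M, np.full(N, 1.0 / N))

    if threshold_mode == "fixed":
        success = counts >= params.s
    elif threshold_mode == "nb":
        if threshold_law is None or threshold_law.continuous:
            raise ValueError("nb threshold mode requires a discrete ThresholdLaw")
        p = threshold_law.k / (threshold_law.k + threshold_law.delta)
        s_i = threshold_law.s0 + rng.negative_binomial(
            threshold_law.k, p, size=(reps, N)
        )
        success = counts >= s_i
    elif threshold_mode == "gamma":
        # continuous requirement s'_i against continuous obtained amount u*m_i
        if threshold_law is None or not threshold_law.continuous:
            raise ValueError("gamma threshold mode requires a gamma-limit ThresholdLaw")
        sprime_i = rng.gamma(
            threshold_law.k,
            scale=threshold_law.sbar_prime / threshold_law.k,
            size=(reps, N),
        )
        success = params.u * counts >= sprime_i
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")

    if fecundity_mode == "step":
        offspring = params.lam * success.sum(axis=1)
    elif fecundity_mode == "saturating":
        if fecundity_law is None:
            raise ValueError("saturating fecundity mode requires a FecundityLaw")
        if threshold_mode == "fixed" and fecundity_law.s != params.s:
            raise ValueError("fecundity law threshold must match params.s")
        # lam_m = lam * (1 - e^{-gamma*u*(m - s + 1)}) above the threshold
        excess = counts - (fecundity_law.s if threshold_mode == "fixed" else s_i) + 1
        lam_m = np.where(
            success,
            fecundity_law.lam
            * -np.expm1(-fecundity_law.gamma * fecundity_law.u * excess),
            0.0,
        )
        offspring = lam_m.sum(axis=1)
    else:
        raise ValueError(f"unknown fecundity_mode {fecundity_mode!r}")

    return counts, success.sum(axis=1), offspring.astype(float), R_drawn, M


def simulate_generation(
    N: int,
    params: CompetitionParams,
    R: float | None = None,
    threshold_mode: str = "fixed",
    threshold_law: ThresholdLaw | None = None,
    fecundity_mode: str = "step",
    fecundity_law: FecundityLaw | None = None,
    rng=None,
) -> GenerationOutcome:
    """Simulate one generation of competition among ``N`` individuals.

    Parameters
    ----------
    N : int
        Number of competing individuals.  ``N = 0`` returns an empty outcome.
    params : CompetitionParams
        Core parameters (``lam``, ``u``, ``Rbar``, ``s``).
    R : float, optional
        Fixed total resource amount; by default ``R`` is drawn exponential
        with mean ``params.Rbar``.
    threshold_mode : {"fixed", "nb", "gamma"}
        Constant threshold ``params.s``, negative-binomial per-individual
        thresholds, or gamma-distributed required amounts (compared against
        the obtained amount ``u*m_i``).
    fecundity_mode : {"step", "saturating"}
        All-or-nothing fecundity ``lam``, or the saturating law.
    rng : int, numpy Generator, or None
        Seed or generator; an integer seed makes the outcome reproducible.
    """
    if N == 0:
        return GenerationOutcome(
            units_per_individual=np.zeros(0, dtype=np.int64),
            n_successes=0,
            offspring_expectation=0.0,
            R_drawn=0.0,
            M=0,
        )
    if N < 0:
        raise ValueError("N must be >= 0")
    gen = _as_rng(rng)
    counts, n_succ, offspring, R_drawn, M = _draw_batch(
        1, N, params, R, threshold_mode, threshold_law,
        fecundity_mode, fecundity_law, gen,
    )
    return GenerationOutcome(
        units_per_individual=counts[0],
        n_successes=int(n_succ[0]),
        offspring_expectation=float(offspring[0]),
        R_drawn=float(R_drawn[0]),
        M=int(M[0]),
    )


def estimate_f(
    N: int,
    params: CompetitionParams,
    reps: int,
    R: float | None = None,
    threshold_mode: str = "fixed",
    threshold_law: ThresholdLaw | None = None,
    fecundity_mode: str = "step",
    fecundity_law: FecundityLaw | None = None,
    rng=None,
) -> MonteCarloEstimate:
    """Monte-Carlo estimate of the expected next-generation population.

    Averages ``offspring_expectation`` over ``reps`` independent generations.
    With a fixed ``R`` the target is ``lam*N*Q(M)``; with an exponential pool
    it is the matching closed-form map.  ``reps >= 2`` is required so the
    standard error is defined.
    """
    if reps < 2:
        raise ValueError("reps must be >= 2 for a standard error")
    seed = _seed_of(rng)
    if N == 0:
        return MonteCarloEstimate(mean=0.0, stderr=0.0, reps=reps, seed=seed)
    gen = _as_rng(rng)
    _, _, offspring, _, _ = _draw_batch(
        reps, N, params, R, threshold_mode, threshold_law,
        fecundity_mode, fecundity_law, gen,
    )
    mean = float(offspring.mean())
    stderr = float(offspring.std(ddof=1) / math.sqrt(reps))
    return MonteCarloEstimate(mean=mean, stderr=stderr, reps=reps, seed=seed)


def stochastic_trajectory(
    N0: int,
    params: CompetitionParams,
    T: int,
    threshold_mode: str = "fixed",
    threshold_law: ThresholdLaw | None = None,
    fecundity_mode: str = "step",
    fecundity_law: FecundityLaw | None = None,
    offspring_realization: str = "poisson",
    rng=None,
) -> np.ndarray:
    """Iterate the stochastic generation process for ``T`` steps.

    Each generation's expected offspring total is realised as an integer
    population: a Poisson draw by default (each reproducer contributing
    independent Poisson(lam_m) offspring, whose sum is Poisson with mean
    equal to the offspring expectation), or deterministic rounding with
    ``offspring_realization="round_expectation"``.  Zero is absorbing.

    This is a stochastic realisation of the process — distinct from
    iterating the closed-form expected map, which would compound expectation
    over randomness it no longer tracks.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if N0 < 0:
        raise ValueError("N0 must be >= 0")
    if offspring_realization not in ("poisson", "round_expectation"):
        raise ValueError(f"unknown offspring_realization {offspring_realization!r}")
    gen = _as_rng(rng)
    series = np.zeros(T + 1, dtype=np.int64)
    series[0] = N0
    N = int(N0)
    for t in range(1, T + 1):
        if N == 0:
            break  # absorbing; series already zero-filled
        out = simulate_generation(
            N, params, R=None,
            threshold_mode=threshold_mode, threshold_law=threshold_law,
            fecundity_mode=fecundity_mode, fecundity_law=fecundity_law,
            rng=gen,
        )
        if offspring_realization == "poisson":
            N = int(gen.poisson(out.offspring_expectation))
        else:
            N = int(round(out.offspring_expectation))
        series[t] = N
    return series
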