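"""Parameter bundles for the unit-resource competition process.

The competition process: ``N`` individuals scramble for a resource pool of
total amount ``R`` that is consumed in indivisible units of size ``u``.  Each
of the ``M = floor(R/u)`` units goes to a uniformly random individual.  An
individual reproduces (expected ``lam`` offspring) once its haul reaches a
threshold of ``s`` units, i.e. an actual resource amount ``s' = u*s``.

The three dataclasses here hold, respectively, the core parameters of that
process, a law for a reproduction threshold that varies between individuals
(negative binomial in units, or its gamma continuum limit in amounts), and a
saturating resource-dependent fecundity law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CompetitionParams:
    """Core parameters of unit-resource competition.

    Parameters
    ----------
    lam : float
        Expected offspring per reproductive individual, ``lam > 0``.
    u : float
        Resource unit size (amount an individual can obtain at a time),
        ``u > 0``.
    Rbar : float
        Expected total resource amount, same units as ``u``, ``Rbar > 0``.
    s : int
        Reproduction threshold in units, a positive integer.
    """

    lam: float
    u: float
    Rbar: float
    s: int = 1

    def __post_init__(self) -> None:
        _require(self.lam > 0, f"lam must be > 0, got {self.lam}")
        _require(self.u > 0, f"u must be > 0, got {self.u}")
        _require(self.Rbar > 0, f"Rbar must be > 0, got {self.Rbar}")
        _require(
            isinstance(self.s, (int,)) and not isinstance(self.s, bool) and self.s >= 1,
            f"s must be a positive integer, got {self.s!r}",
        )

    @property
    def sprime(self) -> float:
        """Actual resource amount required for reproduction, ``s' = u*s``."""
        return self.u * self.s

    @property
    def a(self) -> float:
        """Density-dependence scale ``a = e^{u/Rbar} - 1`` of the derived map.

        Evaluated via ``expm1`` so that the equal-allocation (Ricker) limit
        ``u -> 0`` is reached smoothly without underflow.
        """
        return math.expm1(self.u / self.Rbar)


@dataclass(frozen=True)
class ThresholdLaw:
    """Distribution of the reproduction threshold across individuals.

    Discrete form: the threshold ``s`` (in units) satisfies ``s >= s0`` and
    ``s - s0`` is negative binomial with mean ``delta`` and shape ``k``, so

        mean      s_bar    = s0 + delta
        variance  sigma_s2 = delta + delta**2 / k

    Gamma-limit form (``continuous=True``): the required *amount*
    ``s'`` is gamma distributed with mean ``sbar_prime`` and shape ``k``
    (variance ``sbar_prime**2 / k``).  This is the ``u -> 0`` continuum limit
    of the discrete law and is constructed via :meth:`gamma_form`.
    """

    s0: int | None = None
    delta: float | None = None
    k: float = 1.0
    sbar_prime: float | None = None
    continuous: bool = False

    def __post_init__(self) -> None:
        _require(self.k > 0, f"k must be > 0, got {self.k}")
        if self.continuous:
            _require(
                self.sbar_prime is not None and self.sbar_prime > 0,
                "gamma-limit form requires sbar_prime > 0",
            )
        else:
            _require(
                self.s0 is not None and self.s0 >= 1 and int(self.s0) == self.s0,
                f"s0 must be a positive integer, got {self.s0!r}",
            )
            _require(
                self.delta is not None and self.delta > 0,
                f"delta must be > 0, got {self.delta!r}",
            )

    @classmethod
    def gamma_form(cls, sbar_prime: float, k: float) -> "ThresholdLaw":
        """Continuum (gamma) threshold law with mean ``sbar_prime``, shape ``k``."""
        return cls(k=k, sbar_prime=sbar_prime, continuous=True)

    @property
    def sbar(self) -> float:
        """Mean threshold in units (discrete form only)."""
        _require(not self.continuous, "sbar is defined for the discrete form")
        return self.s0 + self.delta

    @property
    def var_s(self) -> float:
        """Threshold variance in units^2 (discrete form only)."""
        _require(not self.continuous, "var_s is defined for the discrete form")
        return self.delta + self.delta**2 / self.k

    @property
    def var_sprime(self) -> float:
        """Variance of the required amount s' (gamma-limit form only)."""
        _require(self.continuous, "var_sprime is defined for the gamma-limit form")
        return self.sbar_prime**2 / self.k


@dataclass(frozen=True)
class FecundityLaw:
    """Saturating resource-dependent fecundity.

    An individual holding ``m >= s`` units produces an expected
    ``lam * (1 - exp(-gamma*u*(m - s + 1)))`` offspring, rising towards the
    ceiling ``lam`` at rate ``gamma`` per unit amount; below the threshold it
    produces none.  The derived maps involve only the combination
    ``xi = 1/(1 - e^{-gamma*u}) > 1``; ``xi -> 1`` recovers the step
    (all-or-nothing) fecundity.
    """

    lam: float
    gamma: float
    s: int
    u: float

    def __post_init__(self) -> None:
        _require(self.lam > 0, f"lam must be > 0, got {self.lam}")
        _require(self.gamma > 0, f"gamma must be > 0, got {self.gamma}")
        _require(self.u > 0, f"u must be > 0, got {self.u}")
        _require(
            isinstance(self.s, int) and not isinstance(self.s, bool) and self.s >= 1,
            f"s must be a positive integer, got {self.s!r}",
        )

    @property
    def xi(self) -> float:
        """Saturation factor ``xi = (1 - e^{-gamma*u})^{-1} > 1``."""
        return 1.0 / -math.expm1(-self.gamma * self.u)
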