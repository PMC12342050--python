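"""Closed-form steady-state moments of cell size.

Cell size grows exponentially at rate ``mu`` and divides with a hazard that
is a power law of size, ``k s^alpha``; at division the size is multiplied by
a random fraction beta (see :mod:`shsize.partition`).  This module evaluates
the stationary moments of the resulting lineage process:

* ``alpha = 1`` (the *adder*): all uncentered moments are exact and follow a
  first-order recursion; the squared CV of size is
  ``CV2_s = -1 + <log beta>/(<beta> - 1)``, independent of mu and k.
* general ``alpha > 0``: the transformed variable ``y = s^alpha`` is itself
  an adder with growth rate ``alpha*mu`` and partition fraction
  ``beta^alpha``, so all moments of y are exact.  For ``alpha = 1/q`` with
  integer q the moments of s are recovered exactly as high moments of y;
  for ``alpha >= 1`` a derivative-matching (log-normal) moment closure gives
  mean and CV2 approximately.
* the multi-stage model: the cell cycle traverses M stages, each left at a
  size-proportional hazard ``k_i s``; division occurs on leaving stage M.
  Mean and second moment are exact for arbitrary stage rates.

All noise quantities (CV2, skewness) are invariant under the rescaling
``(mu, k) -> (c mu, c k)``; the mean carries the scale ``(mu/k)^(1/alpha)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .partition import PartitionLaw, beta_power_moment, mean_log_beta

__all__ = [
    "SingleStepParams",
    "MultiStepParams",
    "MomentSummary",
    "adder_moments",
    "adder_moment_closed_form",
    "adder_cv2_exact",
    "adder_cv2_approx",
    "adder_skewness",
    "newborn_cv2",
    "powerlaw_y_moments",
    "powerlaw_exact_rational",
    "powerlaw_closure",
    "multistep_moments",
    "multistep_second_moment_pair_sum",
    "multistep_equal_rates",
    "multistep_cv2_limit",
]


@dataclass(frozen=True)
class SingleStepParams:
    """Single-step model: division hazard ``k * s**alpha``.

    mu : fractional growth rate (1/time), > 0.
    k : hazard constant (size^-alpha / time), > 0.
    alpha : power-law exponent, >= 0; 1 is the adder, 0 is size-independent
        timing, alpha -> infinity approaches a hard size threshold (sizer).
    """

    mu: float
    k: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"growth rate mu must be > 0, got {self.mu}")
        if self.k <= 0:
            raise ValueError(f"rate constant k must be > 0, got {self.k}")
        if self.alpha < 0:
            raise ValueError(f"exponent alpha must be >= 0, got {self.alpha}")


@dataclass(frozen=True)
class MultiStepParams:
    """Multi-stage cell-cycle model with per-stage hazards ``k_i * s``."""

    mu: float
    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"growth rate mu must be > 0, got {self.mu}")
        rates = tuple(float(r) for r in self.rates)
        if len(rates) < 1 or any(r <= 0 for r in rates):
            raise ValueError("rates must be a non-empty sequence of positive reals")
        object.__setattr__(self, "rates", rates)

    @property
    def n_stages(self) -> int:
        return len(self.rates)

    @classmethod
    def equal_rates(cls, mu: float, k: float, n_stages: int) -> "MultiStepParams":
        """Equal-rate special case: each stage hazard is ``k * M * s`` so the
        added size per cycle keeps mean ``mu/k`` for every M."""
        if n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        return cls(mu=mu, rates=(k * n_stages,) * n_stages)


@dataclass(frozen=True)
class MomentSummary:
    """Stationary size moments.

    ``moments[p-1]`` is the uncentered moment ``<s^p>``; ``exact`` is False
    when any value relies on the moment-closure approximation.
    """

    mean_size: float
    second_moment: float
    cv2: float
    skewness: float | None = None
    moments: tuple[float, ...] | None = field(default=None)
    exact: bool = True

    def __post_init__(self) -> None:
        if self.second_moment < self.mean_size**2 * (1 - 1e-12):
            raise ValueError("second moment below squared mean")
        implied = self.second_moment / self.mean_size**2 - 1.0
        if not math.isclose(implied, self.cv2, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError(f"inconsistent cv2: stored {self.cv2}, implied {implied}")


# ---------------------------------------------------------------------------
# single-step adder (alpha = 1)
# ---------------------------------------------------------------------------


def _adder_moment_sequence(
    mu: float, k: float, mean_log: float, pow_moment, max_order: int
) -> list[float]:
    """Uncentered moments <x^1..x^max_order> of a generic adder process.

    The stationary mean solves the log-moment balance, <x> = -mu/(k <log b>),
    and higher moments follow the exact recursion
    ``<x^(p+1)> = p mu <x^p> / (k (1 - <b^p>))``.
    """
    m = [-mu / (k * mean_log)]
    for p in range(1, max_order):
        m.append(p * mu * m[-1] / (k * (1.0 - pow_moment(p))))
    return m


def adder_moments(
    params: SingleStepParams, law: PartitionLaw, max_order: int = 3
) -> MomentSummary:
    """Exact stationary moments for the adder (``alpha = 1``)."""
    if params.alpha != 1:
        raise ValueError(f"adder_moments requires alpha = 1, got {params.alpha}")
    if max_order < 2:
        raise ValueError("max_order must be >= 2")
    L = mean_log_beta(law)
    m = _adder_moment_sequence(
        params.mu, params.k, L, lambda p: beta_power_moment(law, p), max_order
    )
    cv2 = m[1] / m[0] ** 2 - 1.0
    skew = _skewness_from_moments(m) if max_order >= 3 else None
    return MomentSummary(
        mean_size=m[0],
        second_moment=m[1],
        cv2=cv2,
        skewness=skew,
        moments=tuple(m),
        exact=True,
    )


def adder_moment_closed_form(
    params: SingleStepParams, law: PartitionLaw, order: int
) -> float:
    """Closed product form of the adder moment ``<s^order>``:

        <s^(p+1)> = -(mu/k)^(p+1) p! / ( <log beta> * prod_{i=1}^p (1 - <beta^i>) )

    Equivalent to the recursion; kept as an independent code path.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    p = order - 1
    L = mean_log_beta(law)
    prod = 1.0
    for i in range(1, p + 1):
        prod *= 1.0 - beta_power_moment(law, i)
    return -((params.mu / params.k) ** (p + 1)) * math.factorial(p) / (L * prod)


def adder_cv2_exact(law: PartitionLaw) -> float:
    """Exact adder size noise ``CV2_s = -1 + <log beta>/(<beta> - 1)``."""
    return -1.0 + mean_log_beta(law) / (law.mean_beta - 1.0)


def adder_cv2_approx(law: PartitionLaw) -> float:
    """Small-noise approximation of the adder size noise at ``<beta> = 1/2``:

        CV2_s ~= -1 + log 4 + CV2_beta / (1 - CV2_beta),

    monotonically increasing in the partitioning noise and exact at
    ``CV2_beta = 0`` (where it reduces to ``log 4 - 1``).
    """
    v = law.cv2_beta
    if v >= 1.0:
        raise ValueError(f"approximation requires cv2_beta < 1, got {v}")
    return -1.0 + math.log(4.0) + v / (1.0 - v)


def _skewness_from_moments(m: Sequence[float]) -> float:
    """Standard third standardized central moment from uncentered moments."""
    mean, m2, m3 = m[0], m[1], m[2]
    var = m2 - mean**2
    third_central = m3 - 3.0 * mean * m2 + 2.0 * mean**3
    return third_central / var**1.5


def adder_skewness(law: PartitionLaw) -> float:
    """Exact stationary skewness of adder cell size.

    Scale-free (independent of mu and k); approximately 1.68 for precise
    halving and nearly flat for partitioning noise below about 0.1.
    """
    summ = adder_moments(SingleStepParams(mu=1.0, k=1.0, alpha=1.0), law, max_order=3)
    return summ.skewness


def newborn_cv2(law: PartitionLaw, cv2_added: float = 1.0) -> float:
    """Noise in size at birth, ``CV2_sb``, at ``<beta> = 1/2``:

        CV2_sb = (4 CV2_beta + CV2_added (1 + CV2_beta)) / (3 - CV2_beta).

    ``cv2_added`` is the squared CV of the per-cycle added size: 1 for the
    single-step adder (exponential increments), 1/M for the equal-rate
    M-stage model (Erlang increments).  At zero partitioning noise the
    single-step value is 1/3.
    """
    if cv2_added < 0:
        raise ValueError("cv2_added must be >= 0")
    v = law.cv2_beta
    if v >= 3.0:
        raise ValueError(f"newborn noise formula requires cv2_beta < 3, got {v}")
    return (4.0 * v + cv2_added * (1.0 + v)) / (3.0 - v)


# ---------------------------------------------------------------------------
# power-law division rate (general alpha) via the y = s^alpha transform
# ---------------------------------------------------------------------------


def powerlaw_y_moments(
    params: SingleStepParams, law: PartitionLaw, max_order: int = 2
) -> MomentSummary:
    """Exact moments of ``y = s^alpha`` for hazard ``k s^alpha``.

    y follows an adder with growth rate ``alpha*mu``, hazard ``k*y`` and
    partition fraction ``beta^alpha``, so its moments come from the same
    exact recursion with ``<log beta^alpha> = alpha <log beta>`` and
    ``<(beta^alpha)^p> = <beta^(alpha p)>``.
    """
    a = params.alpha
    if a <= 0:
        raise ValueError("powerlaw transform requires alpha > 0")
    if max_order < 2:
        raise ValueError("max_order must be >= 2")
    L = mean_log_beta(law)
    m = _adder_moment_sequence(
        a * params.mu,
        params.k,
        a * L,
        lambda p: beta_power_moment(law, a * p),
        max_order,
    )
    cv2 = m[1] / m[0] ** 2 - 1.0
    skew = _skewness_from_moments(m) if max_order >= 3 else None
    return MomentSummary(
        mean_size=m[0],
        second_moment=m[1],
        cv2=cv2,
        skewness=skew,
        moments=tuple(m),
        exact=True,
    )


def powerlaw_exact_rational(
    params: SingleStepParams, law: PartitionLaw
) -> MomentSummary:
    """Exact mean and second moment of s for ``alpha = 1/q``, integer q >= 1.

    With ``y = s^(1/q)`` the size moments are high moments of y:
    ``<s> = <y^q>`` and ``<s^2> = <y^(2q)>``.
    """
    a = params.alpha
    q = round(1.0 / a) if a > 0 else 0
    if q < 1 or not math.isclose(a, 1.0 / q, rel_tol=1e-12):
        raise ValueError(
            f"alpha = {a} is not of the form 1/q for integer q; "
            "use powerlaw_closure for alpha >= 1"
        )
    y = powerlaw_y_moments(params, law, max_order=2 * q)
    mean = y.moments[q - 1]
    m2 = y.moments[2 * q - 1]
    return MomentSummary(
        mean_size=mean, second_moment=m2, cv2=m2 / mean**2 - 1.0, exact=True
    )


def powerlaw_closure(params: SingleStepParams, law: PartitionLaw) -> MomentSummary:
    """Derivative-matching closure for ``alpha >= 1``.

    Closing ``<s^alpha>`` and ``<s^(alpha+1)>`` as log-normal-consistent
    monomials of the first two moments yields

        <s>   ~= (mu / (k (1 - <beta>)))^(1/alpha) * R^(-(alpha+1)/(2 alpha))
        CV2_s ~= -1 + R^(1/alpha),    R := <log beta> / (<beta> - 1) > 1.

    Exact at ``alpha = 1``; for larger alpha it slightly underestimates the
    simulated noise.  CV2 decreases monotonically in alpha (sizer limit).
    """
    a = params.alpha
    if a < 1:
        raise ValueError(
            f"closure requires alpha >= 1, got {a}; use powerlaw_exact_rational"
        )
    L = mean_log_beta(law)
    ratio = L / (law.mean_beta - 1.0)  # > 1 for every valid law
    cv2 = -1.0 + ratio ** (1.0 / a)
    mean = (params.mu / (params.k * (1.0 - law.mean_beta))) ** (1.0 / a) * ratio ** (
        -(a + 1.0) / (2.0 * a)
    )
    m2 = (1.0 + cv2) * mean**2
    return MomentSummary(
        mean_size=mean, second_moment=m2, cv2=cv2, exact=(a == 1.0)
    )


# ---------------------------------------------------------------------------
# multi-stage cell cycle
# ---------------------------------------------------------------------------


def multistep_moments(params: MultiStepParams, law: PartitionLaw) -> MomentSummary:
    """Exact mean and second moment for arbitrary stage rates.

    Stage-occupancy flux balance pins each stage-restricted mean:
    ``<g_i s> = -mu/(k_i <log beta>)``, so the mean size is
    ``<s> = -(mu/<log beta>) sum_i 1/k_i``.  Stage-restricted second
    moments follow a forward recursion seeded by the division-stage value
    ``<g_M s^2> = mu <s> / (k_M (1 - <beta>))``:

        <g_1 s^2>     = -(mu/k_1)^2 / <log beta> + (k_M/k_1) <beta> <g_M s^2>
        <g_(i+1) s^2> = -(mu/k_(i+1))^2 / <log beta> + (k_i/k_(i+1)) <g_i s^2>.
    """
    mu = params.mu
    ks = params.rates
    M = params.n_stages
    L = mean_log_beta(law)
    m_beta = law.mean_beta

    mean = -(mu / L) * sum(1.0 / k for k in ks)
    gM_s2 = mu * mean / (ks[-1] * (1.0 - m_beta))
    if M == 1:
        m2 = gM_s2
    else:
        g_s2 = [0.0] * M
        g_s2[0] = -((mu / ks[0]) ** 2) / L + (ks[-1] / ks[0]) * m_beta * gM_s2
        for i in range(1, M):
            g_s2[i] = -((mu / ks[i]) ** 2) / L + (ks[i - 1] / ks[i]) * g_s2[i - 1]
        # the recursion's final stage reproduces the flux-balance seed
        assert math.isclose(g_s2[-1], gM_s2, rel_tol=1e-9)
        m2 = sum(g_s2)
    return MomentSummary(
        mean_size=mean, second_moment=m2, cv2=m2 / mean**2 - 1.0, exact=True
    )


def multistep_second_moment_pair_sum(
    params: MultiStepParams, law: PartitionLaw
) -> float:
    """Closed pair-sum form of the multi-stage second moment,

        <s^2> = mu <s> / (1 - <beta>) * sum_i 1/k_i
                + mu^2 / <log beta> * sum_{i<j} 1/(k_i k_j),

    algebraically equal to the stage recursion; kept as a cross-check path.
    """
    mu = params.mu
    ks = params.rates
    L = mean_log_beta(law)
    mean = -(mu / L) * sum(1.0 / k for k in ks)
    inv = [1.0 / k for k in ks]
    pair = 0.0
    for i in range(len(inv)):
        for j in range(i + 1, len(inv)):
            pair += inv[i] * inv[j]
    return mu * mean / (1.0 - law.mean_beta) * sum(inv) + mu**2 / L * pair


def multistep_equal_rates(
    mu: float, k: float, n_stages: int, law: PartitionLaw
) -> MomentSummary:
    """Exact closed form for M equal-rate stages (each hazard ``k M s``):

        <s>   = -mu / (k <log beta>)
        CV2_s = -1 + (1 + M + <beta> (M - 1)) / (2 M) * <log beta>/(<beta> - 1)

    The mean is M-independent; the noise decreases monotonically in M.
    """
    if n_stages < 1:
        raise ValueError("n_stages must be >= 1")
    L = mean_log_beta(law)
    m_beta = law.mean_beta
    M = n_stages
    mean = -mu / (k * L)
    cv2 = -1.0 + (1.0 + M + m_beta * (M - 1.0)) / (2.0 * M) * L / (m_beta - 1.0)
    m2 = (1.0 + cv2) * mean**2
    return MomentSummary(mean_size=mean, second_moment=m2, cv2=cv2, exact=True)


def multistep_cv2_limit(law: PartitionLaw) -> float:
    """Noise floor of the equal-rate model as the stage count grows:

        lim_{M->inf} CV2_s = -1 + (1 + <beta>)/2 * <log beta>/(<beta> - 1),

    about 0.04 for precise halving — the fundamental limit of noise
    reduction by subdividing the cell cycle.
    """
    L = mean_log_beta(law)
    return -1.0 + (1.0 + law.mean_beta) / 2.0 * L / (law.mean_beta - 1.0)
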