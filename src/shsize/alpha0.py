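"""Transient moments for a size-independent division rate (no homeostasis).

With a constant division hazard k the moment equations close at every
order.  The mean obeys ``d<s>/dt = (mu - k(1 - <beta>)) <s>`` and can be
held flat by balancing the rates, ``k = mu / (1 - <beta>)``.  Under that
balance the second moment still grows exponentially,

    d<s^2>/dt = mu <s^2> ((1 - <beta>)^2 + Var(beta)) / (1 - <beta>) > 0,

for every partition law — the variance of size diverges, which is why
active size sensing (a size-dependent hazard) is necessary for homeostasis
under exponential growth.  The closed solutions are exponentials, so no
numerical integrator is involved.
"""

from __future__ import annotations

import numpy as np

from .partition import PartitionLaw, beta_power_moment

__all__ = [
    "alpha0_balanced_rate",
    "alpha0_second_moment_exponent",
    "alpha0_moment_trajectory",
]


def alpha0_balanced_rate(mu: float, law: PartitionLaw) -> float:
    """Division rate that keeps the mean size constant: ``mu / (1 - <beta>)``."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return mu / (1.0 - law.mean_beta)


def alpha0_second_moment_exponent(mu: float, law: PartitionLaw) -> float:
    """Growth exponent of ``<s^2>(t)`` at the balanced division rate.

    Returns ``mu ((1 - <beta>)^2 + Var beta) / (1 - <beta>)``; strictly
    positive for every valid law, so ``<s^2>(t) = <s^2>(0) e^(rate t)``
    diverges.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    m = law.mean_beta
    var_beta = beta_power_moment(law, 2) - m**2
    return mu * ((1.0 - m) ** 2 + var_beta) / (1.0 - m)


def alpha0_moment_trajectory(
    mu: float, law: PartitionLaw, s0: float, times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic ``(<s>(t), <s^2>(t))`` at the balanced rate from ``s(0) = s0``.

    The mean stays at ``s0``; the second moment grows exponentially from
    ``s0**2`` with the closed-form exponent.
    """
    times = np.asarray(times, dtype=float)
    mean = np.full_like(times, float(s0))
    m2 = s0**2 * np.exp(alpha0_second_moment_exponent(mu, law) * times)
    return mean, m2
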