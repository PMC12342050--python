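"""Division-fraction (partition) law.

At division a tracked daughter inherits a fraction ``beta`` of the mother's
size.  ``beta`` is modelled either as a beta-distributed random variable on
(0, 1), parametrised by its mean ``<beta>`` and squared coefficient of
variation ``CV2_beta``, or as a deterministic point mass when ``CV2_beta = 0``
(perfectly precise partitioning).

The beta-shape parametrisation used throughout is

    z = (1 - <beta> (1 + CV2_beta)) / CV2_beta,
    shape_a = z,          shape_b = z (1/<beta> - 1),

so that shape_a / (shape_a + shape_b) = <beta> and the implied variance is
CV2_beta <beta>^2.  Feasibility of a (mean, CV2) pair on the unit interval
requires CV2_beta < (1 - <beta>) / <beta>.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "PartitionLaw",
    "make_partition_law",
    "mean_log_beta",
    "mean_log_beta_approx",
    "beta_power_moment",
    "sample_beta",
]

#: CV2_beta above which the small-noise expansion of <log beta> is unreliable.
SMALL_NOISE_WARN_THRESHOLD = 0.2


@dataclass(frozen=True)
class PartitionLaw:
    """Distribution of the inherited size fraction beta in (0, 1).

    Construct via :func:`make_partition_law`, which validates feasibility and
    fills in the beta shape parameters.

    Attributes
    ----------
    mean_beta : float
        Mean inherited fraction ``<beta>``; 1/2 for unbiased daughter choice.
    cv2_beta : float
        Squared coefficient of variation of beta (partitioning noise).
    shape_a, shape_b : float or None
        Beta-distribution shapes; ``None`` when the law is degenerate.
    degenerate : bool
        True iff ``cv2_beta == 0`` (point mass at ``mean_beta``).
    """

    mean_beta: float
    cv2_beta: float
    shape_a: float | None = field(default=None)
    shape_b: float | None = field(default=None)
    degenerate: bool = field(default=False)

    # -- convenience methods (thin wrappers over the module functions) -----

    def mean_log(self) -> float:
        return mean_log_beta(self)

    def power_moment(self, p: float) -> float:
        return beta_power_moment(self, p)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` variates using an existing generator."""
        if self.degenerate:
            return np.full(n, self.mean_beta)
        return rng.beta(self.shape_a, self.shape_b, size=n)


def make_partition_law(mean_beta: float, cv2_beta: float) -> PartitionLaw:
    """Build a :class:`PartitionLaw` from mean and noise.

    Parameters
    ----------
    mean_beta : float
        Mean fraction, strictly inside (0, 1).
    cv2_beta : float
        Squared CV of the fraction; must satisfy
        ``0 <= cv2_beta < (1 - mean_beta) / mean_beta`` for a beta
        distribution supported on (0, 1).

    Raises
    ------
    ValueError
        If the (mean, cv2) pair is infeasible.
    """
    if not 0.0 < mean_beta < 1.0:
        raise ValueError(f"mean_beta must lie strictly in (0, 1), got {mean_beta}")
    if cv2_beta < 0.0:
        raise ValueError(f"cv2_beta must be >= 0, got {cv2_beta}")
    if cv2_beta == 0.0:
        return PartitionLaw(mean_beta, 0.0, None, None, degenerate=True)

    bound = (1.0 - mean_beta) / mean_beta
    if cv2_beta >= bound:
        raise ValueError(
            "infeasible partition law: cv2_beta must be below "
            f"(1 - mean)/mean = {bound:.6g} for mean_beta = {mean_beta}, "
            f"got cv2_beta = {cv2_beta}"
        )
    z = (1.0 - mean_beta * (1.0 + cv2_beta)) / cv2_beta
    shape_a = z
    shape_b = z * (1.0 / mean_beta - 1.0)
    return PartitionLaw(mean_beta, cv2_beta, shape_a, shape_b, degenerate=False)


def mean_log_beta(law: PartitionLaw) -> float:
    """Exact expectation of ``log(beta)``.

    For the beta case this is ``psi(a) - psi(a + b)`` with the digamma
    function psi; for a point mass it is ``log(mean_beta)``.  Always
    strictly negative since beta < 1 almost surely.
    """
    if law.degenerate:
        return math.log(law.mean_beta)
    return float(special.digamma(law.shape_a) - special.digamma(law.shape_a + law.shape_b))


def mean_log_beta_approx(law: PartitionLaw) -> float:
    """Small-noise approximation of ``<log beta>``.

    Expands the digamma expression for ``CV2_beta << 1``:

        <log beta> ~= log<beta> - (1 - <beta>) CV2_beta
                       / (2 (1 - <beta> - <beta> CV2_beta)).

    Emits a warning when ``cv2_beta`` exceeds 0.2, where the expansion
    degrades.
    """
    m, v = law.mean_beta, law.cv2_beta
    if v > SMALL_NOISE_WARN_THRESHOLD:
        warnings.warn(
            f"small-noise approximation called with cv2_beta = {v} > "
            f"{SMALL_NOISE_WARN_THRESHOLD}; result may be inaccurate",
            stacklevel=2,
        )
    denom = 1.0 - m - m * v
    if denom <= 0.0:
        raise ValueError(
            "small-noise expansion undefined: 1 - mean - mean*cv2 must be "
            f"positive, got {denom:.6g}"
        )
    return math.log(m) - (1.0 - m) * v / (2.0 * denom)


def beta_power_moment(law: PartitionLaw, p: float) -> float:
    """Exact fractional moment ``<beta^p>`` for any real ``p > 0``.

    Uses log-gamma differences,
    ``<beta^p> = Gamma(a+p) Gamma(a+b) / (Gamma(a) Gamma(a+b+p))``,
    which stays accurate for non-integer p (needed for power-law division
    exponents).  Returns ``mean_beta**p`` in the degenerate case.
    """
    if p <= 0:
        raise ValueError(f"moment order p must be > 0, got {p}")
    if law.degenerate:
        return law.mean_beta**p
    a, b = law.shape_a, law.shape_b
    log_m = (
        special.gammaln(a + p)
        + special.gammaln(a + b)
        - special.gammaln(a)
        - special.gammaln(a + b + p)
    )
    return float(np.exp(log_m))


def sample_beta(law: PartitionLaw, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` reproducible variates of beta given an integer seed."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    return law.sample(n, rng)
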