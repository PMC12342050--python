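"""Moment-matching parameter estimation from observed cell-size samples.

Inverts the closed-form stationary moment formulas: the sample squared CV
of size pins the partitioning noise ``CV2_beta`` (via one-dimensional root
finding on the digamma expression for ``<log beta>``), the sample mean then
pins the scale ``mu/k``, and — when per-cycle added sizes or birth sizes
are available — the stage count M is selected by exhaustive search over
integers using the auxiliary moment (``CV2_added = 1/M`` for Erlang added
sizes, or the newborn-size noise formula).

With sizes alone, (M, CV2_beta) are not jointly identifiable: every stage
count at or below the noise level's feasibility ceiling admits a matching
partitioning noise.  The fitter then reports the whole feasible ridge
rather than silently picking a point.

The mean partition fraction is assumed to be 1/2 (unbiased daughter
choice) throughout.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .moments import multistep_equal_rates, newborn_cv2
from .partition import make_partition_law, mean_log_beta

__all__ = ["SizeSample", "FitResult", "fit_adder", "fit_multistep"]

MEAN_BETA = 0.5
#: cv2_beta search interval: the beta law for <beta>=1/2 needs cv2 < 1
_CV2_BETA_MAX = 1.0 - 1e-9
_MIN_SAMPLE = 30


@dataclass(frozen=True)
class SizeSample:
    """Observed sample of stationary cell sizes.

    ``added_sizes`` (division minus birth, per cycle) or ``birth_sizes``
    make the stage count identifiable; sizes alone do not.
    """

    sizes: np.ndarray
    added_sizes: np.ndarray | None = None
    birth_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes, dtype=float)
        if sizes.size == 0:
            raise ValueError("empty size sample")
        if np.any(sizes <= 0):
            raise ValueError("sizes must be strictly positive")
        object.__setattr__(self, "sizes", sizes)
        for name in ("added_sizes", "birth_sizes"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if np.any(arr <= 0):
                    raise ValueError(f"{name} must be strictly positive")
                object.__setattr__(self, name, arr)
        if sizes.size < _MIN_SAMPLE:
            warnings.warn(
                f"only {sizes.size} sizes; moment estimates will be unstable",
                stacklevel=2,
            )

    def cv2(self, ddof: int = 1) -> float:
        s = self.sizes
        return float(np.var(s, ddof=ddof) / np.mean(s) ** 2)

    def mean(self) -> float:
        return float(np.mean(self.sizes))


@dataclass(frozen=True)
class FitResult:
    """Outcome of a moment-matching fit.

    ``feasible`` is False when no parameter value can reproduce the sample
    noise under the requested model class (e.g. sample CV2 below the
    zero-partitioning-noise floor).  ``identifiable`` is False when sizes
    alone were given to the multi-stage fitter; ``ridge`` then lists the
    (M, cv2_beta, mu_over_k) combinations consistent with the sample.
    """

    mu_over_k: float
    M_hat: int
    cv2_beta_hat: float
    objective: float
    feasible: bool = True
    identifiable: bool = True
    ridge: tuple[tuple[int, float, float], ...] | None = None
    diagnostics: dict = field(default_factory=dict)


def _cv2_model(n_stages: int, cv2_beta: float) -> float:
    """Stationary size CV2 of the equal-rate M-stage model at <beta>=1/2."""
    law = make_partition_law(MEAN_BETA, cv2_beta)
    return multistep_equal_rates(1.0, 1.0, n_stages, law).cv2


def _invert_cv2(sample_cv2: float, n_stages: int) -> float | None:
    """Solve CV2_s(cv2_beta) = sample_cv2 for cv2_beta >= 0, or None.

    The model CV2 is strictly increasing in cv2_beta, so the root is unique
    when the sample noise sits above the cv2_beta = 0 floor.
    """
    floor = _cv2_model(n_stages, 0.0)
    if sample_cv2 < floor:
        return None
    if sample_cv2 == floor:
        return 0.0
    lo, hi = 0.0, 0.5
    while _cv2_model(n_stages, hi) < sample_cv2:
        hi = 0.5 * (hi + 1.0)
        if hi > _CV2_BETA_MAX:
            hi = _CV2_BETA_MAX
            break
    if _cv2_model(n_stages, hi) < sample_cv2:
        return None  # beyond the beta-law feasibility ceiling
    return float(
        optimize.brentq(
            lambda v: _cv2_model(n_stages, v) - sample_cv2, lo, hi, xtol=1e-12
        )
    )


def _mu_over_k(sample_mean: float, cv2_beta: float) -> float:
    """Scale from the mean-size formula ``<s> = -mu/(k <log beta>)``."""
    law = make_partition_law(MEAN_BETA, cv2_beta)
    return -sample_mean * mean_log_beta(law)


def fit_adder(sample: SizeSample) -> FitResult:
    """Fit the single-step adder (M = 1) by method of moments.

    Solves the exact noise formula for ``cv2_beta`` from the sample CV2 and
    the mean formula for ``mu/k``.  Sample noise below the perfect-
    partitioning floor ``log 4 - 1`` is flagged infeasible (parameters are
    reported at the boundary ``cv2_beta = 0``).
    """
    sample_cv2 = sample.cv2()
    v = _invert_cv2(sample_cv2, 1)
    feasible = v is not None
    v_hat = v if feasible else 0.0
    muk = _mu_over_k(sample.mean(), v_hat)
    resid = _cv2_model(1, v_hat) - sample_cv2
    return FitResult(
        mu_over_k=muk,
        M_hat=1,
        cv2_beta_hat=v_hat,
        objective=resid**2,
        feasible=feasible,
        diagnostics={"sample_cv2": sample_cv2, "cv2_residual": resid},
    )


def fit_multistep(
    sample: SizeSample,
    m_max: int = 200,
    cv2_beta_fixed: float | None = None,
) -> FitResult:
    """Fit the equal-rate M-stage model by method of moments.

    For each candidate stage count M the size noise is inverted for
    ``cv2_beta`` (unless ``cv2_beta_fixed`` is given) and the mean for
    ``mu/k``.  M is then chosen by the auxiliary moment:

    * added sizes: Erlang increments imply ``CV2_added = 1/M``;
    * birth sizes: newborn noise ``(4 v + (1+v)/M)/(3 - v)``;
    * ``cv2_beta_fixed``: the size CV2 itself discriminates M;
    * sizes only: not identifiable — the feasible ridge is returned and
      ``M_hat`` is the smallest feasible stage count.
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    sample_cv2 = sample.cv2()
    sample_mean = sample.mean()

    aux = None
    if cv2_beta_fixed is None:
        if sample.added_sizes is not None:
            d = sample.added_sizes
            aux = ("added", float(np.var(d, ddof=1) / np.mean(d) ** 2))
        elif sample.birth_sizes is not None:
            b = sample.birth_sizes
            aux = ("birth", float(np.var(b, ddof=1) / np.mean(b) ** 2))

    candidates: list[tuple[int, float, float, float]] = []  # (M, v, muk, objective)
    for M in range(1, m_max + 1):
        if cv2_beta_fixed is not None:
            v = cv2_beta_fixed
            obj = (_cv2_model(M, v) - sample_cv2) ** 2
        else:
            v = _invert_cv2(sample_cv2, M)
            if v is None:
                continue
            if aux is None:
                obj = 0.0
            elif aux[0] == "added":
                obj = (aux[1] - 1.0 / M) ** 2
            else:
                law = make_partition_law(MEAN_BETA, v)
                obj = (aux[1] - newborn_cv2(law, cv2_added=1.0 / M)) ** 2
        candidates.append((M, v, _mu_over_k(sample_mean, v), obj))

    if not candidates:
        # sample noise below even the M -> infinity floor: infeasible
        muk = _mu_over_k(sample_mean, 0.0)
        return FitResult(
            mu_over_k=muk,
            M_hat=m_max,
            cv2_beta_hat=0.0,
            objective=float("inf"),
            feasible=False,
            diagnostics={"sample_cv2": sample_cv2},
        )

    identifiable = aux is not None or cv2_beta_fixed is not None
    M_hat, v_hat, muk, obj = min(candidates, key=lambda c: (c[3], c[0]))

    diagnostics = {
        "sample_cv2": sample_cv2,
        "aux_moment": aux,
        "n_feasible_M": len(candidates),
        # estimator-choice sensitivity: does the biased (ddof=0) variance
        # move the selected stage count?
        "M_hat_ddof0": _refit_m(sample, m_max, cv2_beta_fixed, ddof=0),
    }
    ridge = None
    if not identifiable:
        ridge = tuple((m, v, mk) for m, v, mk, _ in candidates)
        warnings.warn(
            "sizes alone do not identify (M, cv2_beta); reporting the "
            "feasible ridge and the smallest feasible M",
            stacklevel=2,
        )
    return FitResult(
        mu_over_k=muk,
        M_hat=M_hat,
        cv2_beta_hat=v_hat,
        objective=obj,
        feasible=True,
        identifiable=identifiable,
        ridge=ridge,
        diagnostics=diagnostics,
    )


def _refit_m(
    sample: SizeSample, m_max: int, cv2_beta_fixed: float | None, ddof: int
) -> int | None:
    """Selected M when sample moments use the given variance ddof."""
    sample_cv2 = sample.cv2(ddof=ddof)
    best: tuple[float, int] | None = None
    aux_added = None
    if cv2_beta_fixed is None and sample.added_sizes is not None:
        d = sample.added_sizes
        aux_added = float(np.var(d, ddof=ddof) / np.mean(d) ** 2)
    for M in range(1, m_max + 1):
        if cv2_beta_fixed is not None:
            obj = (_cv2_model(M, cv2_beta_fixed) - sample_cv2) ** 2
        else:
            v = _invert_cv2(sample_cv2, M)
            if v is None:
                continue
            obj = (aux_added - 1.0 / M) ** 2 if aux_added is not None else 0.0
        if best is None or obj < best[0]:
            best = (obj, M)
    return best[1] if best else None
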