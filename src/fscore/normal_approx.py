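"""Delta-method normal surrogates for the score and difference
distributions, the closed-form calibration approximation, and the
automatic exact-vs-normal selector."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import norm

from .exact_core import _binom_window, DEFAULT_TRUNCATION_EPS

__all__ = [
    "NormalSurrogate",
    "approx_moments",
    "diff_surrogate",
    "approx_p_alpha",
    "select_mode",
    "projected_mass_points",
    "normal_interval",
    "normal_two_sided_pvalue",
    "DEFAULT_MASS_POINT_THRESHOLD",
]

#: exact enumeration is used in auto mode while the projected number of
#: mass points stays at or below this cutoff
DEFAULT_MASS_POINT_THRESHOLD = 20_000


@dataclass(frozen=True)
class NormalSurrogate:
    """Normal approximation N(mean, sd^2) replacing a discrete score pmf."""

    mean: float
    sd: float
    source: str = "score"

    def interval(self, level: float) -> tuple[float, float]:
        return normal_interval(self, level)


def approx_moments(
    S: int, M: int, ps: float, p_alpha: float, beta: float = 1.0
) -> NormalSurrogate:
    """First-order (delta-method) mean and sd of the estimated score.

    With mu = (M p_alpha / S, ps) and w(x, y) = (1+beta^2) y / (x + y + beta^2),
    the score is w evaluated at the scaled counts; the variance propagates
    diag((M/S) p_alpha (1-p_alpha), ps (1-ps)) / S through the gradient of w.
    """
    b2 = beta * beta
    x = (M / S) * p_alpha
    den = x + ps + b2
    mean = (1.0 + b2) * ps / den
    wx = -(1.0 + b2) * ps / den**2
    wy = (1.0 + b2) * (x + b2) / den**2
    var = (
        wx * wx * (M / S) * p_alpha * (1.0 - p_alpha)
        + wy * wy * ps * (1.0 - ps)
    ) / S
    return NormalSurrogate(mean=mean, sd=math.sqrt(max(0.0, var)), source="score")


def diff_surrogate(m1: NormalSurrogate, m2: NormalSurrogate) -> NormalSurrogate:
    """Surrogate for the difference of two independent scores."""
    return NormalSurrogate(
        mean=m1.mean - m2.mean,
        sd=math.hypot(m1.sd, m2.sd),
        source="difference",
    )


def approx_p_alpha(
    S: int, M: int, ps: float, target_fbeta: float, beta: float = 1.0
) -> float:
    """Closed-form large-sample inversion of the calibration equation.

    For beta = 1 this is (S/M) * (ps * (2/F - 1) - 1); the general form
    inverts mean = (1+beta^2) ps / (M p_alpha / S + ps + beta^2).
    """
    b2 = beta * beta
    pa = (S / M) * (ps * ((1.0 + b2) / target_fbeta - 1.0) - b2)
    return min(1.0, max(0.0, pa))


def projected_mass_points(
    S: int,
    M: int,
    ps: float,
    p_alpha: float,
    truncation_eps: float = DEFAULT_TRUNCATION_EPS,
) -> int:
    """Upper bound on the support size of the truncated exact pmf."""
    dlo, dhi = _binom_window(S, ps, truncation_eps)
    blo, bhi = _binom_window(M, p_alpha, truncation_eps)
    return (dhi - dlo + 1) * (bhi - blo + 1)


def select_mode(
    projected: int,
    user_mode: str = "auto",
    threshold: int = DEFAULT_MASS_POINT_THRESHOLD,
) -> str:
    """Choose 'exact' or 'normal' given a projected mass-point count.

    Auto mode stays exact while ``projected <= threshold`` (inclusive).
    Forcing the normal approximation on a small support emits a warning,
    since the discrete distribution is then poorly approximated.
    """
    if user_mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {user_mode!r}")
    if user_mode == "auto":
        return "exact" if projected <= threshold else "normal"
    if user_mode == "normal" and projected <= threshold:
        warnings.warn(
            f"normal approximation forced with only {projected} projected "
            "mass points; results may be unreliable",
            stacklevel=2,
        )
    return user_mode


def normal_interval(surrogate: NormalSurrogate, level: float) -> tuple[float, float]:
    """Equal-tail normal interval, clipped to the score range."""
    z = norm.ppf(0.5 + level / 2.0)
    lo = surrogate.mean - z * surrogate.sd
    hi = surrogate.mean + z * surrogate.sd
    floor = -1.0 if surrogate.source == "difference" else 0.0
    return max(floor, lo), min(1.0, hi)


def normal_two_sided_pvalue(surrogate: NormalSurrogate, observed: float) -> float:
    """2 * min(tail, 1 - tail) under the surrogate."""
    if surrogate.sd == 0.0:
        return 1.0 if observed == surrogate.mean else 0.0
    z = (observed - surrogate.mean) / surrogate.sd
    return float(min(1.0, 2.0 * min(norm.cdf(z), norm.sf(z))))
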