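"""Confidence intervals, hypothesis tests, and power / sample-size
calculations for the F-beta score of a single classifier."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exact_core import (
    ConfusionTable,
    InfeasibleTargetError,
    PerfParams,
    ScoreDistribution,
    equal_tail_interval,
    fbeta_value,
    min_tail_pvalues_at,
    score_pmf,
    solve_p_alpha,
)
from .normal_approx import (
    DEFAULT_MASS_POINT_THRESHOLD,
    approx_moments,
    normal_interval,
    normal_two_sided_pvalue,
    projected_mass_points,
    select_mode,
)

__all__ = [
    "IntervalEstimate",
    "TestResult",
    "PowerResult",
    "DesignResult",
    "corrected_rates",
    "ci_one",
    "test_one_point",
    "test_one_benchmark",
    "power_one",
    "sample_size_one",
]


@dataclass(frozen=True)
class IntervalEstimate:
    lower: float
    upper: float
    level: float
    method: str  # "exact" | "normal"
    corrected: bool = False
    estimate: float | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError("lower endpoint exceeds upper endpoint")

    def contains(self, value: float) -> bool:
        return self.lower - 1e-12 <= value <= self.upper + 1e-12

    @property
    def length(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class TestResult:
    p_value: float
    alternative: str
    null_spec: dict
    method: str
    observed: float
    search_trace: dict | None = None

    def reject(self, alpha: float) -> bool:
        return self.p_value < alpha


@dataclass(frozen=True)
class PowerResult:
    power: float
    alpha: float
    N: int
    S: int
    null_params: PerfParams | None
    alt_params: PerfParams
    beta: float
    method: str = "exact"


@dataclass(frozen=True)
class DesignResult:
    N: int
    S: int
    power: float
    target_power: float
    alpha: float
    trace: list = field(default_factory=list)


def corrected_rates(obs: ConfusionTable) -> tuple[float, float]:
    """Plug-in rates with the add-0.5 smoothing used for intervals.

    b is replaced by 0.5 when zero; the resulting rates equal posterior
    means under non-informative priors and stabilise small-sample
    intervals.
    """
    b_eff = obs.b if obs.b > 0 else 0.5
    ps = (obs.d + 0.5) / (obs.S + 1.0)
    pp = (obs.d + 0.5) / (b_eff + obs.d + 1.0)
    return ps, pp


def _score_dist_for(
    S: int,
    M: int,
    ps: float,
    pp: float,
    beta: float,
    truncation_eps: float,
) -> ScoreDistribution:
    target = fbeta_value(ps, pp, beta)
    pa = solve_p_alpha(S, M, ps, target, beta, truncation_eps=truncation_eps)
    return score_pmf(S, M, ps, pa, beta, truncation_eps=truncation_eps)


def ci_one(
    obs: ConfusionTable,
    beta: float = 1.0,
    level: float = 0.95,
    mode: str = "auto",
    mass_point_threshold: int = DEFAULT_MASS_POINT_THRESHOLD,
    truncation_eps: float = 1e-12,
) -> IntervalEstimate:
    """Equal-tail confidence interval for a single F-beta score."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    ps, pp = corrected_rates(obs)
    target = fbeta_value(ps, pp, beta)
    pa = solve_p_alpha(obs.S, obs.M, ps, target, beta, truncation_eps=truncation_eps)
    projected = projected_mass_points(obs.S, obs.M, ps, pa, truncation_eps)
    method = select_mode(projected, mode, mass_point_threshold)
    if method == "normal":
        surr = approx_moments(obs.S, obs.M, ps, pa, beta)
        lo, hi = normal_interval(surr, level)
    else:
        dist = score_pmf(obs.S, obs.M, ps, pa, beta, truncation_eps=truncation_eps)
        if dist.truncation_mass > 1e-10:  # widen and retry once
            dist = score_pmf(obs.S, obs.M, ps, pa, beta, truncation_eps=1e-15)
        lo, hi = equal_tail_interval(dist.support, dist.probs, level)
    return IntervalEstimate(
        lower=lo,
        upper=hi,
        level=level,
        method=method,
        corrected=True,
        estimate=obs.fbeta(beta),
    )


def test_one_point(
    obs: ConfusionTable,
    null: PerfParams,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    mode: str = "auto",
    mass_point_threshold: int = DEFAULT_MASS_POINT_THRESHOLD,
    truncation_eps: float = 1e-12,
) -> TestResult:
    """Exact test of H0: F-beta equals the score of a given (ps0, pp0).

    The two-sided p-value sums the null pmf over all support points whose
    minimum-tail statistic is at most that of the observed score (ties
    within 1e-12 included).  One-sided p-values are plain single-tail
    sums.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    beta = null.beta
    f_obs = obs.fbeta(beta)
    target = null.fbeta
    pa = solve_p_alpha(obs.S, obs.M, null.ps, target, beta, truncation_eps=truncation_eps)
    projected = projected_mass_points(obs.S, obs.M, null.ps, pa, truncation_eps)
    method = select_mode(projected, mode, mass_point_threshold)
    if method == "normal":
        surr = approx_moments(obs.S, obs.M, null.ps, pa, beta)
        if alternative == "two-sided":
            pv = normal_two_sided_pvalue(surr, f_obs)
        else:
            from scipy.stats import norm

            z = (f_obs - surr.mean) / surr.sd if surr.sd > 0 else math.inf
            pv = float(norm.sf(z) if alternative == "greater" else norm.cdf(z))
    else:
        dist = score_pmf(obs.S, obs.M, null.ps, pa, beta, truncation_eps=truncation_eps)
        if alternative == "two-sided":
            pv = float(min_tail_pvalues_at(dist.support, dist.probs, f_obs))
        elif alternative == "greater":
            pv = dist.sf(f_obs)
        else:
            pv = dist.cdf(f_obs)
    return TestResult(
        p_value=pv,
        alternative=alternative,
        null_spec={"ps0": null.ps, "pp0": null.pp, "fbeta0": target, "beta": beta},
        method=method,
        observed=f_obs,
    )


def _benchmark_curve_bounds(fbeta0: float, beta: float) -> tuple[float, float]:
    """Admissible precision range on the iso-score curve (ps <= 1)."""
    b2 = beta * beta
    pp_min = fbeta0 / (1.0 + b2 - b2 * fbeta0)
    return pp_min, 1.0


def _curve_sensitivity(pp: float, fbeta0: float, beta: float) -> float:
    """Sensitivity solving F_beta(ps, pp) = fbeta0 for a given precision."""
    b2 = beta * beta
    den = (1.0 + b2) * pp - fbeta0
    return fbeta0 * b2 * pp / den


def test_one_benchmark(
    obs: ConfusionTable,
    fbeta0: float,
    alpha: float = 0.05,
    beta: float = 1.0,
    grid_step: float = 1e-3,
    refine_step: float = 1e-5,
    mode: str = "auto",
    truncation_eps: float = 1e-12,
) -> TestResult:
    """Supremum p-value over all (ps, pp) sharing the benchmark score.

    The point-null p-value is maximised over a precision grid on the
    iso-score curve, then refined on a finer local grid around the best
    point; the p-value is piecewise constant along the curve, so grid
    search followed by refinement is adequate.
    """
    if not (0.0 < fbeta0 < 1.0):
        raise ValueError(f"benchmark score must be in (0, 1), got {fbeta0}")
    pp_min, pp_max = _benchmark_curve_bounds(fbeta0, beta)

    def pv_at(pp: float) -> float:
        ps = min(1.0, _curve_sensitivity(pp, fbeta0, beta))
        try:
            res = test_one_point(
                obs,
                PerfParams(ps=ps, pp=pp, beta=beta),
                alpha=alpha,
                mode=mode,
                truncation_eps=truncation_eps,
            )
        except InfeasibleTargetError:
            # some curve members cannot be calibrated at this (S, M);
            # they contribute nothing to the supremum
            return 0.0
        return res.p_value

    grid = np.arange(pp_min, pp_max + grid_step / 2, grid_step)
    grid = np.clip(grid, pp_min, pp_max)
    pvs = [pv_at(pp) for pp in grid]
    i_best = int(np.argmax(pvs))
    best_pp, best_pv = float(grid[i_best]), pvs[i_best]
    lo = max(pp_min, best_pp - grid_step)
    hi = min(pp_max, best_pp + grid_step)
    fine = np.arange(lo, hi + refine_step / 2, refine_step)
    for pp in fine:
        pv = pv_at(float(pp))
        if pv > best_pv:
            best_pv, best_pp = pv, float(pp)
    return TestResult(
        p_value=best_pv,
        alternative="two-sided",
        null_spec={"fbeta0": fbeta0, "beta": beta},
        method="exact" if mode != "normal" else "normal",
        observed=obs.fbeta(beta),
        search_trace={
            "best_pp": best_pp,
            "best_ps": min(1.0, _curve_sensitivity(best_pp, fbeta0, beta)),
            "grid_step": grid_step,
            "refine_step": refine_step,
        },
    )


def power_one(
    null: PerfParams,
    alt: PerfParams,
    N: int,
    S: int,
    alpha: float = 0.05,
    mode: str = "auto",
    mass_point_threshold: int = DEFAULT_MASS_POINT_THRESHOLD,
    truncation_eps: float = 1e-12,
) -> PowerResult:
    """Exact power of the point-null test at a specified alternative.

    The rejection region consists of the support points whose two-sided
    p-value under the null falls below alpha; the power is the
    alternative-distribution mass of that region.
    """
    if null.beta != alt.beta:
        raise ValueError("null and alternative must share the same beta")
    beta = null.beta
    M = N - S
    pa0 = solve_p_alpha(S, M, null.ps, null.fbeta, beta, truncation_eps=truncation_eps)
    pa1 = solve_p_alpha(S, M, alt.ps, alt.fbeta, beta, truncation_eps=truncation_eps)
    projected = max(
        projected_mass_points(S, M, null.ps, pa0, truncation_eps),
        projected_mass_points(S, M, alt.ps, pa1, truncation_eps),
    )
    method = select_mode(projected, mode, mass_point_threshold)
    if method == "normal":
        from scipy.stats import norm

        surr0 = approx_moments(S, M, null.ps, pa0, beta)
        surr1 = approx_moments(S, M, alt.ps, pa1, beta)
        z = norm.ppf(1.0 - alpha / 2.0)
        lo, hi = surr0.mean - z * surr0.sd, surr0.mean + z * surr0.sd
        power = float(
            norm.cdf((lo - surr1.mean) / surr1.sd)
            + norm.sf((hi - surr1.mean) / surr1.sd)
        )
    else:
        dist0 = score_pmf(S, M, null.ps, pa0, beta, truncation_eps=truncation_eps)
        dist1 = score_pmf(S, M, alt.ps, pa1, beta, truncation_eps=truncation_eps)
        pv = min_tail_pvalues_at(dist0.support, dist0.probs, dist1.support)
        power = float(dist1.probs[pv < alpha].sum())
    return PowerResult(
        power=power,
        alpha=alpha,
        N=N,
        S=S,
        null_params=null,
        alt_params=alt,
        beta=beta,
        method=method,
    )


def sample_size_one(
    null: PerfParams,
    alt: PerfParams,
    pI: float,
    target_power: float,
    alpha: float = 0.05,
    n_max: int = 1_000_000,
    lookahead: int = 3,
    mode: str = "auto",
) -> DesignResult:
    """Smallest N (with S = round(N * pI), S >= 1) achieving the target.

    Power is non-monotone in N for discrete tests, so the target must
    also hold for the next `lookahead` increments of N before a design is
    accepted.
    """
    return _search_sample_size(
        lambda N, S: power_one(null, alt, N, S, alpha, mode=mode).power,
        pI,
        target_power,
        alpha,
        n_max,
        lookahead,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _search_sample_size(power_fn, pI, target_power, alpha, n_max, lookahead):
    if not (0.0 < pI < 1.0):
        raise ValueError(f"positive fraction must be in (0, 1), got {pI}")
    if not (0.0 < target_power < 1.0):
        raise ValueError(f"target power must be in (0, 1), got {target_power}")

    def design(N: int) -> tuple[int, int]:
        S = max(1, _round_half_up(N * pI))
        if S >= N:
            S = N - 1
        return N, S

    def power_at(N: int) -> float:
        N, S = design(N)
        try:
            return power_fn(N, S)
        except Exception:
            return 0.0

    n_lo = max(3, int(math.ceil(1.0 / pI)))
    trace: list[tuple[int, float]] = []

    # bracket by doubling
    n_hi = n_lo
    while power_at(n_hi) < target_power:
        trace.append((n_hi, power_at(n_hi)))
        n_hi *= 2
        if n_hi > n_max:
            raise ResourceWarning(
                f"no design with N <= {n_max} reaches power {target_power}"
            )
    # first N in (n_lo, n_hi] meeting the target (approximate: power is
    # locally non-monotone, the lookahead guard below compensates)
    lo, hi = n_lo, n_hi
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    n = lo
    while n <= n_max:
        pw = power_at(n)
        trace.append((n, pw))
        if pw >= target_power and all(
            power_at(n + k) >= target_power for k in range(1, lookahead + 1)
        ):
            N, S = (max(1, _round_half_up(n * pI)), 0)
            N, S = n, max(1, _round_half_up(n * pI))
            return DesignResult(
                N=N,
                S=S,
                power=pw,
                target_power=target_power,
                alpha=alpha,
                trace=trace,
            )
        n += 1
    raise ResourceWarning(f"no stable design with N <= {n_max}")
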