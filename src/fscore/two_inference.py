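"""Inference for the difference in F-beta scores of two independent
classifiers evaluated on a shared test set.

Both classifiers see the same ``N`` instances and the same ``S`` actual
positives; their predictions are assumed independent (no covariance
modelling), which is the documented limitation of this framework.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .exact_core import (
    ConfusionTable,
    DiffDistribution,
    PerfParams,
    TIE_TOL,
    equal_tail_interval,
    diff_pmf,
    fbeta_value,
    min_tail_pvalues_at,
    score_pmf,
    solve_p_alpha,
)
from .normal_approx import (
    DEFAULT_MASS_POINT_THRESHOLD,
    approx_moments,
    diff_surrogate,
    normal_interval,
    normal_two_sided_pvalue,
    projected_mass_points,
    select_mode,
)
from .single_inference import (
    DesignResult,
    IntervalEstimate,
    PowerResult,
    TestResult,
    _search_sample_size,
    corrected_rates,
)

__all__ = [
    "PairedObservation",
    "ci_two",
    "test_two_pooled",
    "test_two_sup",
    "power_two",
    "sample_size_two",
]


@dataclass(frozen=True)
class PairedObservation:
    """Two classifiers' confusion tables on one shared test set."""

    obs1: ConfusionTable
    obs2: ConfusionTable

    def __post_init__(self) -> None:
        if self.obs1.N != self.obs2.N or self.obs1.S != self.obs2.S:
            raise ValueError(
                "paired observations must share the same test set "
                f"(N, S): got ({self.obs1.N}, {self.obs1.S}) vs "
                f"({self.obs2.N}, {self.obs2.S})"
            )

    @property
    def N(self) -> int:
        return self.obs1.N

    @property
    def S(self) -> int:
        return self.obs1.S

    def diff(self, beta: float = 1.0) -> float:
        return round(self.obs1.fbeta(beta) - self.obs2.fbeta(beta), 12)


def _margin_dist(S, M, ps, pp, beta, truncation_eps):
    target = fbeta_value(ps, pp, beta)
    pa = solve_p_alpha(S, M, ps, target, beta, truncation_eps=truncation_eps)
    return score_pmf(S, M, ps, pa, beta, truncation_eps=truncation_eps)


def _uncorrected_rates(obs: ConfusionTable) -> tuple[float, float]:
    ps = obs.d / obs.S
    pp = obs.d / (obs.b + obs.d) if obs.b + obs.d > 0 else 0.0
    return ps, pp


def ci_two(
    pair: PairedObservation,
    beta: float = 1.0,
    level: float = 0.95,
    mode: str = "auto",
    mass_point_threshold: int = DEFAULT_MASS_POINT_THRESHOLD,
    truncation_eps: float = 1e-12,
) -> IntervalEstimate:
    """Equal-tail interval for the difference in F-beta scores."""
    if not (0.0 < level < 1.0):
        raise ValueError(f"confidence level must be in (0, 1), got {level}")
    S, M = pair.S, pair.N - pair.S
    ps1, pp1 = corrected_rates(pair.obs1)
    ps2, pp2 = corrected_rates(pair.obs2)
    pa1 = solve_p_alpha(S, M, ps1, fbeta_value(ps1, pp1, beta), beta,
                        truncation_eps=truncation_eps)
    pa2 = solve_p_alpha(S, M, ps2, fbeta_value(ps2, pp2, beta), beta,
                        truncation_eps=truncation_eps)
    projected = max(
        projected_mass_points(S, M, ps1, pa1, truncation_eps),
        projected_mass_points(S, M, ps2, pa2, truncation_eps),
    )
    method = select_mode(projected, mode, mass_point_threshold)
    if method == "normal":
        surr = diff_surrogate(
            approx_moments(S, M, ps1, pa1, beta),
            approx_moments(S, M, ps2, pa2, beta),
        )
        lo, hi = normal_interval(surr, level)
    else:
        d1 = score_pmf(S, M, ps1, pa1, beta, truncation_eps=truncation_eps)
        d2 = score_pmf(S, M, ps2, pa2, beta, truncation_eps=truncation_eps)
        h = diff_pmf(d1, d2)
        lo, hi = equal_tail_interval(h.support, h.probs, level)
    return IntervalEstimate(
        lower=lo,
        upper=hi,
        level=level,
        method=method,
        corrected=True,
        estimate=pair.diff(beta),
    )


def _pooled_null_diff(
    S: int, M: int, ps_bar: float, pp_bar: float, beta: float, truncation_eps: float
) -> DiffDistribution:
    g0 = _margin_dist(S, M, ps_bar, pp_bar, beta, truncation_eps)
    return diff_pmf(g0, g0)


def test_two_pooled(
    pair: PairedObservation,
    beta: float = 1.0,
    alpha: float = 0.05,
    alternative: str = "two-sided",
    mode: str = "auto",
    mass_point_threshold: int = DEFAULT_MASS_POINT_THRESHOLD,
    truncation_eps: float = 1e-12,
) -> TestResult:
    """Test of equal scores with the pooled-estimate null.

    The null sets both margins to the pooled rates (uncorrected plug-in
    averages) and uses the minimum-tail convention on the difference
    support.
    """
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    S, M = pair.S, pair.N - pair.S
    ps1, pp1 = _uncorrected_rates(pair.obs1)
    ps2, pp2 = _uncorrected_rates(pair.obs2)
    if pair.obs1.d == 0 and pair.obs2.d == 0:
        warnings.warn(
            "both classifiers have zero true positives; the pooled null "
            "is degenerate and the test is uninformative",
            stacklevel=2,
        )
        return TestResult(
            p_value=1.0,
            alternative=alternative,
            null_spec={"ps_bar": 0.0, "pp_bar": 0.0, "beta": beta},
            method="degenerate",
            observed=pair.diff(beta),
        )
    ps_bar = (ps1 + ps2) / 2.0
    pp_bar = (pp1 + pp2) / 2.0
    d_obs = pair.diff(beta)
    pa_bar = solve_p_alpha(S, M, ps_bar, fbeta_value(ps_bar, pp_bar, beta), beta,
                           truncation_eps=truncation_eps)
    projected = projected_mass_points(S, M, ps_bar, pa_bar, truncation_eps)
    method = select_mode(projected, mode, mass_point_threshold)
    if method == "normal":
        m0 = approx_moments(S, M, ps_bar, pa_bar, beta)
        surr = diff_surrogate(m0, m0)  # symmetric about zero
        if alternative == "two-sided":
            pv = normal_two_sided_pvalue(surr, d_obs)
        else:
            from scipy.stats import norm

            z = (d_obs - surr.mean) / surr.sd if surr.sd > 0 else math.inf
            pv = float(norm.sf(z) if alternative == "greater" else norm.cdf(z))
    else:
        g0 = score_pmf(S, M, ps_bar, pa_bar, beta, truncation_eps=truncation_eps)
        h0 = diff_pmf(g0, g0)
        if alternative == "two-sided":
            pv = float(min_tail_pvalues_at(h0.support, h0.probs, d_obs))
        else:
            cum = np.cumsum(h0.probs)
            i_r = np.searchsorted(h0.support, d_obs + TIE_TOL, side="right")
            i_l = np.searchsorted(h0.support, d_obs - TIE_TOL, side="left")
            pv = (
                float(1.0 - (cum[i_l - 1] if i_l > 0 else 0.0))
                if alternative == "greater"
                else float(cum[i_r - 1] if i_r > 0 else 0.0)
            )
    return TestResult(
        p_value=pv,
        alternative=alternative,
        null_spec={"ps_bar": ps_bar, "pp_bar": pp_bar, "beta": beta},
        method=method,
        observed=d_obs,
    )


def test_two_sup(
    pair: PairedObservation,
    beta: float = 1.0,
    alpha: float = 0.05,
    outer_grid_step: float = 1e-2,
    pp_grid_step: float = 1e-2,
    mode: str = "auto",
    truncation_eps: float = 1e-12,
) -> TestResult:
    """Benchmark-free test: supremum over all common score values.

    The outer search over the common score F0 is restricted to the
    [2.5th, 97.5th] percentile range of the pooled single-score
    distribution (candidates: pooled support points in the window plus a
    uniform grid); for each F0 the inner supremum runs over the
    iso-score curve.  The result dominates the pooled-null p-value.
    """
    S, M = pair.S, pair.N - pair.S
    ps1, pp1 = _uncorrected_rates(pair.obs1)
    ps2, pp2 = _uncorrected_rates(pair.obs2)
    ps_bar = (ps1 + ps2) / 2.0
    pp_bar = (pp1 + pp2) / 2.0
    d_obs = pair.diff(beta)
    g_bar = _margin_dist(S, M, ps_bar, pp_bar, beta, truncation_eps)
    cum = np.cumsum(g_bar.probs)
    f_lo = float(g_bar.support[np.searchsorted(cum, 0.025)])
    f_hi = float(g_bar.support[min(np.searchsorted(cum, 0.975), len(cum) - 1)])
    f_lo = max(f_lo, 1e-6)
    f_hi = min(f_hi, 1.0 - 1e-6)
    in_window = (g_bar.support >= f_lo) & (g_bar.support <= f_hi)
    candidates = set(np.round(g_bar.support[in_window], 12).tolist())
    candidates.update(np.arange(f_lo, f_hi + outer_grid_step / 2, outer_grid_step))

    b2 = beta * beta

    def inner_sup(f0: float) -> float:
        pp_min = f0 / (1.0 + b2 - b2 * f0)
        pps = np.arange(pp_min, 1.0 + pp_grid_step / 2, pp_grid_step)
        pps = np.clip(pps, pp_min, 1.0)
        best = 0.0
        for pp in pps:
            den = (1.0 + b2) * pp - f0
            ps = min(1.0, f0 * b2 * pp / den)
            try:
                pa = solve_p_alpha(S, M, ps, f0, beta, truncation_eps=truncation_eps)
            except Exception:
                continue
            g = score_pmf(S, M, ps, pa, beta, truncation_eps=truncation_eps)
            h = diff_pmf(g, g)
            pv = float(min_tail_pvalues_at(h.support, h.probs, d_obs))
            if pv > best:
                best = pv
        return best

    best_pv, best_f0 = 0.0, None
    for f0 in sorted(candidates):
        pv = inner_sup(float(f0))
        if pv > best_pv:
            best_pv, best_f0 = pv, float(f0)
        if best_pv >= 1.0:
            break
    return TestResult(
        p_value=best_pv,
        alternative="two-sided",
        null_spec={"sup_over": "fbeta0", "window": (f_lo, f_hi), "beta": beta},
        method="exact" if mode != "normal" else "normal",
        observed=d_obs,
        search_trace={
            "best_fbeta0": best_f0,
            "outer_grid_step": outer_grid_step,
            "pp_grid_step": pp_grid_step,
        },
    )


def power_two(
    params1: PerfParams,
    params2: PerfParams,
    N: int,
    S: int,
    alpha: float = 0.05,
    mode: str = "auto",
    mass_point_threshold: int = DEFAULT_MASS_POINT_THRESHOLD,
    truncation_eps: float = 1e-12,
) -> PowerResult:
    """Exact power for detecting a difference between two classifiers.

    The rejection region comes from the pooled null at the averaged
    rates; the power is the mass of that region under the difference
    distribution with each margin at its own design rates.
    """
    if params1.beta != params2.beta:
        raise ValueError("both parameter sets must share the same beta")
    beta = params1.beta
    M = N - S
    ps_bar = (params1.ps + params2.ps) / 2.0
    pp_bar = (params1.pp + params2.pp) / 2.0
    pa_bar = solve_p_alpha(S, M, ps_bar, fbeta_value(ps_bar, pp_bar, beta), beta,
                           truncation_eps=truncation_eps)
    pa1 = solve_p_alpha(S, M, params1.ps, params1.fbeta, beta,
                        truncation_eps=truncation_eps)
    pa2 = solve_p_alpha(S, M, params2.ps, params2.fbeta, beta,
                        truncation_eps=truncation_eps)
    projected = max(
        projected_mass_points(S, M, ps_bar, pa_bar, truncation_eps),
        projected_mass_points(S, M, params1.ps, pa1, truncation_eps),
        projected_mass_points(S, M, params2.ps, pa2, truncation_eps),
    )
    method = select_mode(projected, mode, mass_point_threshold)
    if method == "normal":
        from scipy.stats import norm

        m0 = approx_moments(S, M, ps_bar, pa_bar, beta)
        null_surr = diff_surrogate(m0, m0)
        alt_surr = diff_surrogate(
            approx_moments(S, M, params1.ps, pa1, beta),
            approx_moments(S, M, params2.ps, pa2, beta),
        )
        z = norm.ppf(1.0 - alpha / 2.0)
        lo, hi = -z * null_surr.sd, z * null_surr.sd
        power = float(
            norm.cdf((lo - alt_surr.mean) / alt_surr.sd)
            + norm.sf((hi - alt_surr.mean) / alt_surr.sd)
        )
    else:
        g0 = score_pmf(S, M, ps_bar, pa_bar, beta, truncation_eps=truncation_eps)
        h0 = diff_pmf(g0, g0)
        g1 = score_pmf(S, M, params1.ps, pa1, beta, truncation_eps=truncation_eps)
        g2 = score_pmf(S, M, params2.ps, pa2, beta, truncation_eps=truncation_eps)
        h1 = diff_pmf(g1, g2)
        pv = min_tail_pvalues_at(h0.support, h0.probs, h1.support)
        power = float(h1.probs[pv < alpha].sum())
    return PowerResult(
        power=power,
        alpha=alpha,
        N=N,
        S=S,
        null_params=None,
        alt_params=params1,
        beta=beta,
        method=method,
    )


def sample_size_two(
    params1: PerfParams,
    params2: PerfParams,
    pI: float,
    target_power: float,
    alpha: float = 0.05,
    n_max: int = 1_000_000,
    lookahead: int = 3,
    mode: str = "auto",
) -> DesignResult:
    """Smallest N (S = round(N * pI)) reaching the target two-classifier power."""
    return _search_sample_size(
        lambda N, S: power_two(params1, params2, N, S, alpha, mode=mode).power,
        pI,
        target_power,
        alpha,
        n_max,
        lookahead,
    )
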