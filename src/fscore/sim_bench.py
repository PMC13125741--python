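"""Seeded synthetic confusion-table generator and Monte-Carlo harness.

Replicates coverage, interval-length, type-I-error and empirical-power
summaries over the model ``d ~ Bin(S, ps)``, ``b ~ Bin(N-S, p_fp)`` with
the false-positive rate either calibrated so the expected estimated
score hits the target (default, model-consistent with the calibration
equation) or set to the precision-targeting large-sample rate
``S ps (1-pp) / ((N-S) pp)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .exact_core import ConfusionTable, PerfParams, fbeta_value, solve_p_alpha
from .single_inference import ci_one, power_one, test_one_point
from .two_inference import PairedObservation, ci_two, power_two, test_two_pooled

__all__ = [
    "Scenario",
    "simulate_tables",
    "run_coverage",
    "run_power",
    "named_scenarios",
]


@dataclass(frozen=True)
class Scenario:
    """One simulation cell: design counts, rates, level, replicate count."""

    params1: PerfParams
    N: int
    S: int
    params2: PerfParams | None = None
    null_params: PerfParams | None = None
    beta: float = 1.0
    alpha: float = 0.05
    level: float = 0.95
    reps: int = 1000
    seed: int = 0
    fp_rate: str = "calibrated"  # or "precision"

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def _fp_rate(scenario: Scenario, params: PerfParams) -> float:
    S, M = scenario.S, scenario.N - scenario.S
    if scenario.fp_rate == "precision":
        if params.pp == 0:
            raise ValueError("precision-targeting rate undefined at pp = 0")
        return min(1.0, S * params.ps * (1.0 - params.pp) / (M * params.pp))
    return solve_p_alpha(S, M, params.ps, params.fbeta, scenario.beta)


def simulate_tables(
    scenario: Scenario,
) -> Iterator[ConfusionTable | PairedObservation]:
    """Yield `reps` seeded confusion tables (pairs when params2 is set)."""
    S, M = scenario.S, scenario.N - scenario.S
    rng = np.random.default_rng(scenario.seed)
    pa1 = _fp_rate(scenario, scenario.params1)
    if scenario.params2 is None:
        d = rng.binomial(S, scenario.params1.ps, size=scenario.reps)
        b = rng.binomial(M, pa1, size=scenario.reps)
        for k in range(scenario.reps):
            yield ConfusionTable(N=scenario.N, S=S, d=int(d[k]), b=int(b[k]))
    else:
        pa2 = _fp_rate(scenario, scenario.params2)
        d1 = rng.binomial(S, scenario.params1.ps, size=scenario.reps)
        b1 = rng.binomial(M, pa1, size=scenario.reps)
        d2 = rng.binomial(S, scenario.params2.ps, size=scenario.reps)
        b2 = rng.binomial(M, pa2, size=scenario.reps)
        for k in range(scenario.reps):
            yield PairedObservation(
                ConfusionTable(N=scenario.N, S=S, d=int(d1[k]), b=int(b1[k])),
                ConfusionTable(N=scenario.N, S=S, d=int(d2[k]), b=int(b2[k])),
            )


def run_coverage(scenario: Scenario, mode: str = "auto") -> dict:
    """Coverage and interval-length summary of the equal-tail interval.

    Coverage counts intervals containing the true target score (or true
    difference for paired scenarios).
    """
    beta = scenario.beta
    if scenario.params2 is None:
        truth = fbeta_value(scenario.params1.ps, scenario.params1.pp, beta)
    else:
        truth = fbeta_value(
            scenario.params1.ps, scenario.params1.pp, beta
        ) - fbeta_value(scenario.params2.ps, scenario.params2.pp, beta)
    hits = 0
    lengths = []
    for obs in simulate_tables(scenario):
        if scenario.params2 is None:
            ci = ci_one(obs, beta=beta, level=scenario.level, mode=mode)
        else:
            ci = ci_two(obs, beta=beta, level=scenario.level, mode=mode)
        hits += ci.contains(truth)
        lengths.append(ci.length)
    coverage = hits / scenario.reps
    return {
        "coverage": coverage,
        "coverage_se": math.sqrt(coverage * (1.0 - coverage) / scenario.reps),
        "mean_length": float(np.mean(lengths)),
        "sd_length": float(np.std(lengths, ddof=1)) if len(lengths) > 1 else 0.0,
        "reps": scenario.reps,
        "truth": truth,
    }


def run_power(scenario: Scenario, mode: str = "auto") -> dict:
    """Empirical rejection fraction of the exact test at the scenario alpha.

    For single-classifier scenarios the null is `null_params` and the
    rejection rule (a fixed region of the null support) is precomputed
    once.  For paired scenarios the pooled-null test is data-dependent
    and rerun per replicate.  When the generating parameters satisfy the
    null this estimates the type-I error.
    """
    rejections = 0
    if scenario.params2 is None:
        if scenario.null_params is None:
            raise ValueError("single-classifier power needs null_params")
        for obs in simulate_tables(scenario):
            res = test_one_point(
                obs, scenario.null_params, alpha=scenario.alpha, mode=mode
            )
            rejections += res.p_value < scenario.alpha
    else:
        for pair in simulate_tables(scenario):
            res = test_two_pooled(pair, beta=scenario.beta,
                                  alpha=scenario.alpha, mode=mode)
            rejections += res.p_value < scenario.alpha
    rate = rejections / scenario.reps
    return {
        "power": rate,
        "power_se": math.sqrt(rate * (1.0 - rate) / scenario.reps),
        "reps": scenario.reps,
    }


# -- named scenario grids ---------------------------------------------------

_SINGLE_DESIGNS = [(150, 60), (100, 40), (50, 20), (1000, 20)]
_PAIRED_DESIGNS = [(250, 100), (100, 40), (50, 20), (1000, 20)]


def named_scenarios(name: str, reps: int = 1000, seed: int = 0) -> list[Scenario]:
    """Simulation grids mirroring the benchmark tables.

    coverage-single: 95% CI of one score at (pp, ps) = (0.6, 0.9).
    power-single:    test of (pp0, ps0) = (0.5, 0.8) under (0.6, 0.9).
    power-paired:    (0.5, 0.8) vs (0.6, 0.9) pooled-null test.
    analytic-single / analytic-paired: the same grids for beta in
    {0.5, 1, 2} used to validate the analytic power routines.
    """
    out: list[Scenario] = []
    if name in ("coverage-single", "table3"):
        for k, (n, s) in enumerate(_SINGLE_DESIGNS):
            out.append(
                Scenario(
                    params1=PerfParams(ps=0.9, pp=0.6),
                    N=n,
                    S=s,
                    reps=reps,
                    seed=seed + k,
                )
            )
    elif name in ("power-single", "table4"):
        for k, (n, s) in enumerate(_SINGLE_DESIGNS):
            out.append(
                Scenario(
                    params1=PerfParams(ps=0.9, pp=0.6),
                    null_params=PerfParams(ps=0.8, pp=0.5),
                    N=n,
                    S=s,
                    reps=reps,
                    seed=seed + k,
                )
            )
    elif name in ("power-paired", "table5"):
        for k, (n, s) in enumerate(_PAIRED_DESIGNS):
            out.append(
                Scenario(
                    params1=PerfParams(ps=0.8, pp=0.5),
                    params2=PerfParams(ps=0.9, pp=0.6),
                    N=n,
                    S=s,
                    reps=reps,
                    seed=seed + k,
                )
            )
    elif name in ("analytic-single", "table6"):
        for j, beta in enumerate((0.5, 1.0, 2.0)):
            for k, (n, s) in enumerate(_SINGLE_DESIGNS):
                out.append(
                    Scenario(
                        params1=PerfParams(ps=0.9, pp=0.6, beta=beta),
                        null_params=PerfParams(ps=0.8, pp=0.5, beta=beta),
                        N=n,
                        S=s,
                        beta=beta,
                        reps=reps,
                        seed=seed + 10 * j + k,
                    )
                )
    elif name in ("analytic-paired", "table7"):
        for j, beta in enumerate((0.5, 1.0, 2.0)):
            for k, (n, s) in enumerate(_PAIRED_DESIGNS):
                out.append(
                    Scenario(
                        params1=PerfParams(ps=0.8, pp=0.5, beta=beta),
                        params2=PerfParams(ps=0.9, pp=0.6, beta=beta),
                        N=n,
                        S=s,
                        beta=beta,
                        reps=reps,
                        seed=seed + 10 * j + k,
                    )
                )
    else:
        raise ValueError(f"unknown scenario grid {name!r}")
    return out


def analytic_power(scenario: Scenario, mode: str = "auto") -> float:
    """Analytic counterpart of :func:`run_power` for a scenario."""
    if scenario.params2 is None:
        return power_one(
            scenario.null_params,
            scenario.params1,
            scenario.N,
            scenario.S,
            scenario.alpha,
            mode=mode,
        ).power
    return power_two(
        scenario.params1,
        scenario.params2,
        scenario.N,
        scenario.S,
        scenario.alpha,
        mode=mode,
    ).power
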