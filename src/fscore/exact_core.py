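"""Exact discrete distributions of estimated F-beta scores.

The estimated score of a binary classifier on a test set with ``S`` actual
positives and ``M = N - S`` actual negatives is

    f_beta = (1 + beta^2) * d / (b + d + beta^2 * S),

where ``d`` (true positives) and ``b`` (false positives) are modelled as
independent binomials ``d ~ Bin(S, ps)`` and ``b ~ Bin(M, p_alpha)``.  The
per-negative false-positive rate ``p_alpha`` is calibrated so that the
expected estimated score matches the target score implied by a
(sensitivity, precision) pair.  This module solves that calibration
equation, enumerates the exact probability mass function of the score and
of the difference of two independent scores, and provides a slow
rational-arithmetic oracle used by the test-suite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ConfusionTable",
    "PerfParams",
    "ScoreDistribution",
    "DiffDistribution",
    "InfeasibleTargetError",
    "ResourceLimitError",
    "fbeta_value",
    "fbeta_estimate",
    "solve_p_alpha",
    "expected_score",
    "score_pmf",
    "diff_pmf",
    "brute_force_pmf",
    "brute_force_pmf_exact",
    "read_confusion_tsv",
    "write_confusion_tsv",
    "read_confusion_json",
    "write_confusion_json",
]

#: probability mass allowed outside each truncated binomial window
DEFAULT_TRUNCATION_EPS = 1e-12
#: refuse convolutions beyond this many support pairs (chunked evaluation
#: keeps memory bounded, so the cap is generous)
DEFAULT_MAX_PAIRS = 50_000_000
#: refuse single-score enumerations beyond this many (b, d) cells
DEFAULT_MAX_POINTS = 20_000_000
#: decimal places used to group score differences (and scores for
#: non-rational beta); well below the minimal support spacing at any
#: tractable N, so distinct values never merge spuriously
GROUP_DECIMALS = 12


class InfeasibleTargetError(ValueError):
    """No false-positive rate can achieve the requested expected score."""


class ResourceLimitError(RuntimeError):
    """Exact enumeration would exceed the configured size cap."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionTable:
    """Observed counts of one classifier on one test set.

    Parameters
    ----------
    N : int
        Total number of classified instances.
    S : int
        Number of actual positives (``0 < S < N``).
    d : int
        True positives (``0 <= d <= S``).
    b : int
        False positives (``0 <= b <= N - S``).
    """

    N: int
    S: int
    d: int
    b: int

    def __post_init__(self) -> None:
        if not (0 < self.S < self.N):
            raise ValueError(f"require 0 < S < N, got S={self.S}, N={self.N}")
        if not (0 <= self.d <= self.S):
            raise ValueError(f"require 0 <= d <= S, got d={self.d}, S={self.S}")
        if not (0 <= self.b <= self.N - self.S):
            raise ValueError(
                f"require 0 <= b <= N - S, got b={self.b}, N-S={self.N - self.S}"
            )

    @property
    def M(self) -> int:
        """Number of actual negatives."""
        return self.N - self.S

    @property
    def a(self) -> int:
        """True negatives."""
        return self.M - self.b

    @property
    def c(self) -> int:
        """False negatives."""
        return self.S - self.d

    @property
    def sensitivity(self) -> float:
        return self.d / self.S

    @property
    def precision(self) -> float:
        return self.d / (self.b + self.d) if self.b + self.d > 0 else 0.0

    def fbeta(self, beta: float = 1.0) -> float:
        """Estimated F-beta score ``(1+beta^2) d / (b + d + beta^2 S)``."""
        return fbeta_estimate(self.S, self.b, self.d, beta)


@dataclass(frozen=True)
class PerfParams:
    """A (sensitivity, precision, beta) triple defining a target score."""

    ps: float
    pp: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ps <= 1.0):
            raise ValueError(f"sensitivity must be in [0, 1], got {self.ps}")
        if not (0.0 <= self.pp <= 1.0):
            raise ValueError(f"precision must be in [0, 1], got {self.pp}")
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")

    @property
    def fbeta(self) -> float:
        """Target score implied by the (sensitivity, precision) pair."""
        return fbeta_value(self.ps, self.pp, self.beta)


@dataclass
class ScoreDistribution:
    """Exact pmf of the estimated score on its discrete support."""

    support: np.ndarray
    probs: np.ndarray
    p_alpha: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.support)

    @property
    def truncation_mass(self) -> float:
        return self.meta.get("truncation_mass", 0.0)

    def mean(self) -> float:
        return float(np.sum(self.support * self.probs) / np.sum(self.probs))

    def var(self) -> float:
        m = self.mean()
        return float(
            np.sum((self.support - m) ** 2 * self.probs) / np.sum(self.probs)
        )

    def sd(self) -> float:
        return math.sqrt(self.var())

    def cdf(self, x: float) -> float:
        """P(f <= x)."""
        i = np.searchsorted(self.support, x + 1e-12, side="right")
        return float(np.sum(self.probs[:i]))

    def sf(self, x: float) -> float:
        """P(f >= x)."""
        i = np.searchsorted(self.support, x - 1e-12, side="left")
        return float(np.sum(self.probs[i:]))


@dataclass
class DiffDistribution:
    """Exact pmf of the difference of two independent estimated scores."""

    support: np.ndarray
    probs: np.ndarray
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.support)

    @property
    def truncation_mass(self) -> float:
        return self.meta.get("truncation_mass", 0.0)

    def mean(self) -> float:
        return float(np.sum(self.support * self.probs) / np.sum(self.probs))


# ---------------------------------------------------------------------------
# score algebra
# ---------------------------------------------------------------------------


def fbeta_value(ps: float, pp: float, beta: float = 1.0) -> float:
    """Weighted harmonic mean ``(1+beta^2) pp ps / (beta^2 pp + ps)``.

    Returns 0 when ``ps * pp == 0`` (limit convention).
    """
    if ps * pp == 0.0:
        return 0.0
    b2 = beta * beta
    return (1.0 + b2) * pp * ps / (b2 * pp + ps)


def fbeta_estimate(S: int, b: float, d: float, beta: float = 1.0) -> float:
    """Plug-in score ``(1+beta^2) d / (b + d + beta^2 S)`` from counts."""
    num, den = _score_fraction(S, b, d, beta)
    if num == 0:
        return 0.0
    return num / den


def _beta_fraction(beta: float, max_den: int = 1000) -> tuple[int, int] | None:
    """Return (p, q) with beta = p/q exactly, or None for non-rational beta."""
    frac = Fraction(beta).limit_denominator(max_den)
    if float(frac) == beta:
        return frac.numerator, frac.denominator
    return None


def _score_fraction(S: int, b: float, d: float, beta: float):
    """Numerator/denominator of the score, exact for rational beta."""
    pq = _beta_fraction(beta)
    if pq is not None and float(b).is_integer() and float(d) == int(d):
        p, q = pq
        num = (p * p + q * q) * int(d)
        den = q * q * (int(b) + int(d)) + p * p * S
        g = math.gcd(num, den)
        return num // g, den // g
    b2 = beta * beta
    return (1.0 + b2) * d, b + d + b2 * S


# ---------------------------------------------------------------------------
# binomial windows
# ---------------------------------------------------------------------------


def _binom_pmf(k: np.ndarray, n: int, p: float) -> np.ndarray:
    """Vectorised binomial pmf (gammaln form; avoids scipy call overhead)."""
    k = np.asarray(k)
    if p <= 0.0:
        return (k == 0).astype(float)
    if p >= 1.0:
        return (k == n).astype(float)
    logpmf = (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + k * math.log(p)
        + (n - k) * math.log1p(-p)
    )
    return np.exp(logpmf)


def _binom_window(n: int, p: float, eps: float) -> tuple[int, int]:
    """Central [lo, hi] holding at least 1 - eps of Bin(n, p) mass.

    Uses a conservative normal-tail bound z = sqrt(-2 ln(eps/4)) plus a
    fixed count margin; the omitted mass is tracked downstream, so a
    slightly generous window only costs a few extra cells.
    """
    if p <= 0.0:
        return 0, 0
    if p >= 1.0:
        return n, n
    if n <= 32:
        return 0, n
    from scipy.stats import binom

    lo = int(binom.ppf(eps / 4.0, n, p))
    hi = int(binom.isf(eps / 4.0, n, p))
    return max(0, lo - 2), min(n, hi + 2)


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------


def expected_score(
    S: int,
    M: int,
    ps: float,
    p_alpha: float,
    beta: float = 1.0,
    truncation_eps: float = DEFAULT_TRUNCATION_EPS,
) -> float:
    """E[(1+beta^2) d / (b + d + beta^2 S)] under the binomial model."""
    dlo, dhi = _binom_window(S, ps, truncation_eps)
    blo, bhi = _binom_window(M, p_alpha, truncation_eps)
    d = np.arange(dlo, dhi + 1)
    b = np.arange(blo, bhi + 1)
    pd = _binom_pmf(d, S, ps)
    pb = _binom_pmf(b, M, p_alpha)
    b2 = beta * beta
    f = (1.0 + b2) * d[:, None] / (b[None, :] + d[:, None] + b2 * S)
    w = pd[:, None] * pb[None, :]
    return float((w * f).sum() / w.sum())


def solve_p_alpha(
    S: int,
    M: int,
    ps: float,
    target_fbeta: float,
    beta: float = 1.0,
    tol: float = 1e-10,
    truncation_eps: float = DEFAULT_TRUNCATION_EPS,
) -> float:
    """Calibrate the per-negative false-positive rate.

    Finds the root of ``E[f_beta | p_alpha] = target_fbeta`` by bisection;
    the expectation is strictly decreasing in ``p_alpha``, so the root is
    unique whenever it exists.

    Raises
    ------
    InfeasibleTargetError
        If even ``p_alpha = 0`` leaves the expected score below the
        target.  Increasing ``S`` or adjusting the (sensitivity,
        precision) pair makes the target attainable.
    """
    if not (0.0 <= target_fbeta <= 1.0):
        raise ValueError(f"target score must be in [0, 1], got {target_fbeta}")
    if not (0.0 <= ps <= 1.0):
        raise ValueError(f"sensitivity must be in [0, 1], got {ps}")
    e_hi = expected_score(S, M, ps, 0.0, beta, truncation_eps)
    if e_hi < target_fbeta - tol:
        raise InfeasibleTargetError(
            f"no p_alpha can achieve the target score {target_fbeta:.6g}: "
            f"even with zero false positives the expected score is only "
            f"{e_hi:.6g} (S={S}, M={M}, ps={ps:.6g}, beta={beta:.6g}). "
            "Increase the number of positives S or adjust the specified "
            "sensitivity/precision."
        )
    if e_hi <= target_fbeta + tol:
        return 0.0
    e_lo = expected_score(S, M, ps, 1.0, beta, truncation_eps)
    if e_lo >= target_fbeta + tol:
        raise InfeasibleTargetError(
            f"target score {target_fbeta:.6g} lies below the expected score "
            f"{e_lo:.6g} at p_alpha = 1 (S={S}, M={M}, ps={ps:.6g})."
        )
    # the d margin and the score matrix do not depend on p_alpha; hoist
    # them out of the bisection loop (the b window is taken at full width
    # here, trimmed only for large M)
    dlo, dhi = _binom_window(S, ps, truncation_eps)
    d = np.arange(dlo, dhi + 1)
    pd = _binom_pmf(d, S, ps)
    b = np.arange(0, M + 1)
    b2 = beta * beta
    f_weighted = pd[:, None] * (
        (1.0 + b2) * d[:, None] / (b[None, :] + d[:, None] + b2 * S)
    )
    col_mass = pd.sum()

    def expectation(pa: float) -> float:
        pb = _binom_pmf(b, M, pa)
        return float((f_weighted @ pb).sum()) / (col_mass * pb.sum())

    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        e_mid = expectation(mid)
        if abs(e_mid - target_fbeta) <= tol:
            return mid
        if e_mid > target_fbeta:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-16:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# exact pmfs
# ---------------------------------------------------------------------------


def _group_by_value(values: np.ndarray, weights: np.ndarray):
    u, inv = np.unique(values, return_inverse=True)
    return u, np.bincount(inv, weights=weights)


def score_pmf(
    S: int,
    M: int,
    ps: float,
    p_alpha: float,
    beta: float = 1.0,
    truncation_eps: float = DEFAULT_TRUNCATION_EPS,
    max_points: int = DEFAULT_MAX_POINTS,
    allow_truncation: bool = True,
) -> ScoreDistribution:
    """Enumerate the exact pmf of the estimated score.

    Admissible (b, d) pairs are restricted to central binomial windows
    holding at least ``1 - truncation_eps`` of the mass of each margin;
    the omitted mass is recorded in ``meta['truncation_mass']``.  Support
    values are grouped exactly: for rational ``beta`` the score is reduced
    to lowest terms in integer arithmetic, so ties such as
    ``2*1/(0+1+3) == 2*2/(2+2+4)`` merge without floating-point hazards.
    """
    if S <= 0 or M <= 0:
        raise ValueError("S and M must be positive")
    if not allow_truncation:
        dlo, dhi, blo, bhi = 0, S, 0, M
    else:
        dlo, dhi = _binom_window(S, ps, truncation_eps)
        blo, bhi = _binom_window(M, p_alpha, truncation_eps)
    n_cells = (dhi - dlo + 1) * (bhi - blo + 1)
    if n_cells > max_points:
        raise ResourceLimitError(
            f"exact enumeration needs {n_cells} cells, cap is {max_points}; "
            "use the normal approximation instead"
        )
    d = np.arange(dlo, dhi + 1)
    b = np.arange(blo, bhi + 1)
    pd = _binom_pmf(d, S, ps)
    pb = _binom_pmf(b, M, p_alpha)
    D, B = np.meshgrid(d, b, indexing="ij")
    pq = _beta_fraction(beta)
    if pq is not None:
        p, q = pq
        num = (p * p + q * q) * D
        den = q * q * (B + D) + p * p * S
        g = np.gcd(num, den)
        vals = (num // g).astype(float) / (den // g).astype(float)
    else:
        b2 = beta * beta
        vals = np.round((1.0 + b2) * D / (B + D + b2 * S), GROUP_DECIMALS)
    w = (pd[:, None] * pb[None, :]).ravel()
    support, probs = _group_by_value(vals.ravel(), w)
    if len(support) > 2000:
        # drop individually negligible points (window-corner cells); the
        # dropped mass is bounded by truncation_eps and recorded below
        keep = probs >= truncation_eps / len(support)
        support, probs = support[keep], probs[keep]
    total = float(probs.sum())
    meta = {
        "N": S + M,
        "S": S,
        "ps": ps,
        "beta": beta,
        "truncation_mass": max(0.0, 1.0 - total),
        "truncation_eps": truncation_eps,
        "d_window": (int(dlo), int(dhi)),
        "b_window": (int(blo), int(bhi)),
    }
    return ScoreDistribution(support=support, probs=probs, p_alpha=p_alpha, meta=meta)


def diff_pmf(
    dist1: ScoreDistribution,
    dist2: ScoreDistribution,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    chunk_pairs: int = 4_000_000,
) -> DiffDistribution:
    """Exact distribution of ``f1 - f2`` for independent scores.

    Both inputs must be built on the same (N, S).  The convolution is
    evaluated in chunks; support values of the difference are grouped
    after rounding to 12 decimals, which merges exact rational ties (the
    per-margin supports are reduced fractions, so equal differences agree
    to machine precision) without merging genuinely distinct values.
    """
    if (dist1.meta.get("N"), dist1.meta.get("S")) != (
        dist2.meta.get("N"),
        dist2.meta.get("S"),
    ):
        raise ValueError("both score distributions must share the same (N, S)")
    n_pairs = len(dist1) * len(dist2)
    if n_pairs > max_pairs:
        raise ResourceLimitError(
            f"difference support needs {n_pairs} pairs, cap is {max_pairs}; "
            "use the normal approximation instead"
        )
    s1, p1 = dist1.support, dist1.probs
    s2, p2 = dist2.support, dist2.probs
    step = max(1, chunk_pairs // max(1, len(s2)))
    parts_v: list[np.ndarray] = []
    parts_w: list[np.ndarray] = []
    for i in range(0, len(s1), step):
        sl = slice(i, i + step)
        vals = np.round(s1[sl, None] - s2[None, :], GROUP_DECIMALS).ravel()
        w = (p1[sl, None] * p2[None, :]).ravel()
        u, q = _group_by_value(vals, w)
        parts_v.append(u)
        parts_w.append(q)
    support, probs = _group_by_value(np.concatenate(parts_v), np.concatenate(parts_w))
    meta = {
        "meta1": dist1.meta,
        "meta2": dist2.meta,
        "truncation_mass": max(0.0, 1.0 - float(probs.sum())),
    }
    return DiffDistribution(support=support, probs=probs, meta=meta)


# ---------------------------------------------------------------------------
# brute-force oracle (tests only)
# ---------------------------------------------------------------------------

_BRUTE_FORCE_CAP = 10_000


def brute_force_pmf_exact(
    S: int, M: int, ps: float, p_alpha: float, beta: float = 1.0
) -> dict[Fraction, Fraction]:
    """Untruncated pmf as a {score: probability} map in exact rationals.

    Probabilities are exact because any float rate converts to an exact
    binary fraction; the total mass is exactly 1 by the binomial theorem.
    Only intended for tiny instances (``S * M <= 10_000``).
    """
    if S * M > _BRUTE_FORCE_CAP:
        raise ResourceLimitError(
            f"brute force restricted to S*M <= {_BRUTE_FORCE_CAP}, got {S * M}"
        )
    pq = _beta_fraction(beta)
    if pq is None:
        raise ValueError("brute-force oracle requires a rational beta")
    p, q = pq
    fps = Fraction(ps)
    fpa = Fraction(p_alpha)
    pd = [
        math.comb(S, d) * fps**d * (1 - fps) ** (S - d) for d in range(S + 1)
    ]
    pb = [
        math.comb(M, b) * fpa**b * (1 - fpa) ** (M - b) for b in range(M + 1)
    ]
    out: dict[Fraction, Fraction] = {}
    for d in range(S + 1):
        for b in range(M + 1):
            f = Fraction((p * p + q * q) * d, q * q * (b + d) + p * p * S)
            out[f] = out.get(f, Fraction(0)) + pd[d] * pb[b]
    return out


def brute_force_pmf(
    S: int, M: int, ps: float, p_alpha: float, beta: float = 1.0
) -> ScoreDistribution:
    """Float view of :func:`brute_force_pmf_exact` (testing oracle)."""
    exact = brute_force_pmf_exact(S, M, ps, p_alpha, beta)
    items = sorted(exact.items())
    support = np.array([float(f) for f, _ in items])
    probs = np.array([float(pr) for _, pr in items])
    meta = {
        "N": S + M,
        "S": S,
        "ps": ps,
        "beta": beta,
        "truncation_mass": 0.0,
    }
    return ScoreDistribution(support=support, probs=probs, p_alpha=p_alpha, meta=meta)


# ---------------------------------------------------------------------------
# tail utilities shared by the inference modules
# ---------------------------------------------------------------------------

TIE_TOL = 1e-12


def min_tail_stats(probs: np.ndarray) -> np.ndarray:
    """C_i = min(P(f <= f_i), P(f >= f_i)) for a sorted support."""
    lo = np.cumsum(probs)
    hi = lo[-1] - lo + probs
    return np.minimum(lo, hi)


def min_tail_pvalues_at(
    support: np.ndarray, probs: np.ndarray, x: np.ndarray | float
) -> np.ndarray | float:
    """Two-sided minimum-tail p-values of arbitrary observed values.

    For each ``x`` the statistic ``C(x) = min(P(f <= x), P(f >= x))`` is
    evaluated from the cumulative sums of the null distribution, and the
    p-value is the null mass of ``{f : C(f) <= C(x) + tol}``.  Values that
    fall outside the (possibly truncated) support receive a near-zero
    tail and hence a near-zero p-value.
    """
    scalar = np.isscalar(x)
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    cum = np.cumsum(probs)
    upc = cum[-1] - cum + probs
    C = np.minimum(cum, upc)
    order = np.argsort(C, kind="stable")
    c_sorted = C[order]
    mass_sorted = np.cumsum(probs[order])
    i_right = np.searchsorted(support, xa + TIE_TOL, side="right") - 1
    lo_x = np.where(i_right >= 0, cum[np.clip(i_right, 0, None)], 0.0)
    i_left = np.searchsorted(support, xa - TIE_TOL, side="left")
    up_x = np.where(
        i_left < len(support), upc[np.clip(i_left, 0, len(support) - 1)], 0.0
    )
    c_x = np.minimum(lo_x, up_x)
    pos = np.searchsorted(c_sorted, c_x + TIE_TOL, side="right") - 1
    pv = np.where(pos >= 0, mass_sorted[np.clip(pos, 0, None)], 0.0)
    return float(pv[0]) if scalar else pv


def equal_tail_interval(
    support: np.ndarray, probs: np.ndarray, level: float
) -> tuple[float, float]:
    """Equal-tail interval on a discrete support.

    Lower endpoint: largest support point whose inclusive lower tail does
    not exceed ``alpha/2``.  Upper endpoint: smallest support point whose
    *strict* upper tail does not exceed ``alpha/2`` (the upper
    ``alpha/2``-quantile).  The pair brackets at least ``level`` of the
    mass.
    """
    a2 = (1.0 - level) / 2.0
    cum = np.cumsum(probs)
    ok_l = np.nonzero(cum <= a2 + TIE_TOL)[0]
    lower = support[ok_l[-1]] if len(ok_l) else support[0]
    i_u = np.searchsorted(cum, (1.0 - a2) - TIE_TOL, side="left")
    upper = support[min(i_u, len(support) - 1)]
    return float(lower), float(upper)


# ---------------------------------------------------------------------------
# confusion-table IO
# ---------------------------------------------------------------------------

_TSV_HEADER = ["N", "S", "tp", "fp"]


def read_confusion_tsv(path) -> list[ConfusionTable]:
    """Read confusion tables from a TSV with columns N, S, tp, fp."""
    tables = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != _TSV_HEADER:
            raise ValueError(f"expected header {_TSV_HEADER}, got {header}")
        for line in fh:
            if not line.strip():
                continue
            n, s, tp, fp = (int(x) for x in line.strip().split("\t"))
            tables.append(ConfusionTable(N=n, S=s, d=tp, b=fp))
    return tables


def write_confusion_tsv(path, tables) -> None:
    if isinstance(tables, ConfusionTable):
        tables = [tables]
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for t in tables:
            fh.write(f"{t.N}\t{t.S}\t{t.d}\t{t.b}\n")


def read_confusion_json(path) -> ConfusionTable:
    with open(path) as fh:
        rec = json.load(fh)
    return ConfusionTable(N=rec["N"], S=rec["S"], d=rec["tp"], b=rec["fp"])


def write_confusion_json(path, table: ConfusionTable) -> None:
    with open(path, "w") as fh:
        json.dump({"N": table.N, "S": table.S, "tp": table.d, "fp": table.b}, fh)
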