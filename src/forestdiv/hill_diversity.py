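"""Hill-number diversity with rarefaction/extrapolation and bootstrap CIs.

Hill numbers of order q are effective numbers of species:

* q = 0 — species richness,
* q = 1 — exponential of Shannon entropy,
* q = 2 — inverse Simpson concentration,

computed on relative abundances p_i = n_i/N (individual-based data) or on
relative incidence frequencies Y_i/U over T sampling units (sample-based
data). Diversities are standardized to a common sample size m (or coverage)
by interpolation below the reference sample and analytic short-range
extrapolation up to twice the reference, the "unified" sampling-theory
curves popularized by the iNEXT family of estimators:

* q = 0 uses the exact hypergeometric rarefaction expectation below the
  reference and a Chao1/Chao2-anchored exponential approach to the
  asymptote above it;
* q = 1 uses the exact expected plug-in entropy of a subsample below the
  reference, and above it a weighted mixture of the observed entropy and
  an asymptotic (Chao–Jost-type) entropy estimate;
* q = 2 has a single closed-form estimator valid on both sides.

Sample coverage (Good–Turing) is estimated from singleton and doubleton
counts. Confidence bands come from a bootstrap that augments the observed
community with the estimated unseen-species component, resamples, and
applies a normal approximation around the analytic point estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.special import digamma, gammaln

from .plot_data import AbundanceTable, IncidenceTable

__all__ = [
    "DiversityEstimate",
    "hill_number",
    "hill_number_incidence",
    "coverage_estimate",
    "rarefy",
    "extrapolate",
    "estimate_at",
    "knot_grid",
    "doubling_rule",
    "bootstrap_ci",
    "diversity_profile",
]

Data = Union[np.ndarray, Sequence[int], AbundanceTable, IncidenceTable]


@dataclass(frozen=True)
class DiversityEstimate:
    """One standardized diversity point on a rarefaction/extrapolation curve."""

    q: int
    m: int
    coverage: float
    estimate: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    kind: str = "observed"  # interpolated | observed | extrapolated


# ---------------------------------------------------------------------------
# reference-sample Hill numbers


def _clean_counts(counts: Iterable[float]) -> np.ndarray:
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("abundance vector has no positive counts")
    return x


def hill_number(counts: Iterable[float], q: int) -> float:
    """Observed Hill number of order q for a pooled abundance vector."""
    x = _clean_counts(counts)
    p = x / x.sum()
    if q == 0:
        return float(p.size)
    if q == 1:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 2:
        return float(1.0 / np.sum(p**2))
    raise ValueError("q must be 0, 1 or 2")


def hill_number_incidence(table: IncidenceTable, q: int) -> float:
    """Observed incidence-based Hill number, on p_i = Y_i / U."""
    return hill_number(table.frequencies(), q)


# ---------------------------------------------------------------------------
# internal helpers


def _lchoose(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log C(a, b), -inf outside the support. Integer-valued floats."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    bad = (b < 0) | (b > a)
    return np.where(bad, -np.inf, out)


def _f1_f2(x: np.ndarray) -> tuple[int, int]:
    return int(np.sum(x == 1)), int(np.sum(x == 2))


def _unseen_richness(f1: int, f2: int, n: int) -> float:
    """Chao1-style estimated number of unseen species (bias-corrected at f2=0)."""
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


def _chao_jost_entropy(x: np.ndarray, n: int) -> float:
    """Asymptotic Shannon entropy estimate from a sample of counts."""
    f1, f2 = _f1_f2(x)
    xs = x[x <= n - 1]
    part1 = float(np.sum(xs / n * (digamma(n) - digamma(xs))))
    if f1 == 0:
        return part1
    if f2 > 0:
        A = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
    else:
        A = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    if A >= 1.0:
        return part1
    r = np.arange(1, n)
    tail = -np.log(A) - float(np.sum((1.0 - A) ** r / r))
    part2 = f1 / n * (1.0 - A) ** (1 - n) * tail
    return part1 + part2


# ---------------------------------------------------------------------------
# abundance-based estimators


def _D_abundance(x: np.ndarray, q: int, m: int) -> float:
    n = int(round(x.sum()))
    if m < 1:
        raise ValueError("m must be >= 1")
    if q == 2:
        s2 = float(np.sum(x * (x - 1))) / (n * (n - 1)) if n > 1 else 0.0
        denom = 1.0 / m + (1.0 - 1.0 / m) * s2
        return 1.0 if denom == 0 else float(1.0 / denom)

    if m == n:  # reference point: expectations reduce to the observed sample
        return hill_number(x, q)
    if m < n:  # interpolation (exact expectations under subsampling)
        if q == 0:
            lognum = _lchoose(n - x, np.full_like(x, m))
            return float(x.size - np.sum(np.exp(lognum - _lchoose(n, m))))
        # q == 1: exact expected plug-in entropy of a size-m subsample
        kmax = int(min(m, x.max()))
        k = np.arange(1, kmax + 1)
        logEf = (
            _lchoose(x[None, :], k[:, None].astype(float))
            + _lchoose(n - x[None, :], float(m) - k[:, None])
            - _lchoose(np.asarray(float(n)), np.asarray(float(m)))
        )
        Efk = np.exp(logEf).sum(axis=1)
        w = -(k / m) * np.log(k / m)
        return float(np.exp(np.sum(w * Efk)))

    # extrapolation beyond the reference sample
    mstar = m - n
    f1, f2 = _f1_f2(x)
    if q == 0:
        f0 = _unseen_richness(f1, f2, n)
        if f0 == 0.0 or f1 == 0:
            return float(x.size)
        grow = 1.0 - (1.0 - f1 / (n * f0 + f1)) ** mstar
        return float(x.size + f0 * grow)
    # q == 1
    p = x / n
    h_obs = float(-np.sum(p * np.log(p)))
    h_asy = max(_chao_jost_entropy(x, n), h_obs)
    w = n / (n + mstar)
    return float(np.exp(w * h_obs + (1.0 - w) * h_asy))


def coverage_estimate(counts: Iterable[float], m: int | None = None) -> float:
    """Estimated sample coverage of a size-m sample (default: reference size).

    At the reference size n the Good–Turing estimate
    ``1 - (f1/n) * (n-1)f1 / ((n-1)f1 + 2 f2)`` is used; below n the exact
    expected coverage of a subsample; above n (up to 2n) the geometric
    extension of the Good–Turing rate.
    """
    x = _clean_counts(counts)
    n = int(round(x.sum()))
    f1, f2 = _f1_f2(x)

    def _ref_rate() -> float:
        if f1 == 0:
            return 0.0
        return (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2))

    if m is None or m == n:
        return 1.0 - _ref_rate()
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > 2 * n:
        raise ValueError(f"m={m} beyond supported extrapolation range 2n={2 * n}")
    if m < n:
        lognum = _lchoose(n - x, np.full_like(x, m))
        logden = _lchoose(np.asarray(float(n - 1)), np.asarray(float(m)))
        return float(1.0 - np.sum((x / n) * np.exp(lognum - logden)))
    # m > n
    if f1 == 0:
        return 1.0
    rate = (n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2)
    return float(1.0 - (f1 / n) * rate ** (m - n + 1))


# ---------------------------------------------------------------------------
# incidence-based estimators


def _D_incidence(y: np.ndarray, T: int, q: int, t: int) -> float:
    U = float(y.sum())
    if t < 1:
        raise ValueError("t must be >= 1")
    if q == 2:
        s2 = float(np.sum(y * (y - 1))) / (T * (T - 1)) if T > 1 else 0.0
        ut = t * U / T
        total = ut + t * (t - 1) * s2
        return float(ut**2 / total) if total > 0 else 1.0

    if t == T:
        return hill_number(y, q)
    if t < T:
        if q == 0:
            lognum = _lchoose(T - y, np.full_like(y, t))
            return float(y.size - np.sum(np.exp(lognum - _lchoose(float(T), float(t)))))
        # q == 1
        ut = t * U / T
        kmax = int(min(t, y.max()))
        k = np.arange(1, kmax + 1)
        logEQ = (
            _lchoose(y[None, :], k[:, None].astype(float))
            + _lchoose(float(T) - y[None, :], float(t) - k[:, None])
            - _lchoose(np.asarray(float(T)), np.asarray(float(t)))
        )
        EQk = np.exp(logEQ).sum(axis=1)
        w = -(k / ut) * np.log(k / ut)
        return float(np.exp(np.sum(w * EQk)))

    # extrapolation
    tstar = t - T
    Q1, Q2 = _f1_f2(y)
    if q == 0:
        Q0 = _unseen_richness(Q1, Q2, T)
        if Q0 == 0.0 or Q1 == 0:
            return float(y.size)
        grow = 1.0 - (1.0 - Q1 / (T * Q0 + Q1)) ** tstar
        return float(y.size + Q0 * grow)
    # q == 1: mixture of plug-in and asymptotic entropy on p_i = Y_i/U
    p = y / U
    h_obs = float(-np.sum(p * np.log(p)))
    h_rel_asy = _chao_jost_entropy(y, T)  # entropy estimate on Y_i/T scale
    h_asy = max(T / U * h_rel_asy + np.log(U / T), h_obs)
    w = T / (t)
    return float(np.exp(w * h_obs + (1.0 - w) * h_asy))


def coverage_estimate_incidence(table: IncidenceTable, t: int | None = None) -> float:
    """Incidence-based sample coverage of t sampling units."""
    y = table.frequencies().astype(float)
    T = table.T
    U = float(y.sum())
    Q1, Q2 = _f1_f2(y)

    def _ref_rate() -> float:
        if Q1 == 0:
            return 0.0
        return (Q1 / U) * ((T - 1) * Q1 / ((T - 1) * Q1 + 2.0 * Q2))

    if t is None or t == T:
        return 1.0 - _ref_rate()
    if t < 1:
        raise ValueError("t must be >= 1")
    if t > 2 * T:
        raise ValueError(f"t={t} beyond supported extrapolation range 2T={2 * T}")
    if t < T:
        lognum = _lchoose(T - y, np.full_like(y, t))
        logden = _lchoose(np.asarray(float(T - 1)), np.asarray(float(t)))
        return float(1.0 - np.sum((y / U) * np.exp(lognum - logden)))
    if Q1 == 0:
        return 1.0
    rate = (T - 1) * Q1 / ((T - 1) * Q1 + 2.0 * Q2)
    return float(1.0 - (Q1 / U) * rate ** (t - T + 1))


# ---------------------------------------------------------------------------
# public dispatch


def _as_data(data: Data) -> tuple[str, np.ndarray, int]:
    """Normalize input to ('abundance', x, n) or ('incidence', y, T)."""
    if isinstance(data, IncidenceTable):
        y = data.frequencies().astype(float)
        return "incidence", y, data.T
    if isinstance(data, AbundanceTable):
        x = data.pooled_vector().astype(float)
        return "abundance", x, int(x.sum())
    x = _clean_counts(data)
    return "abundance", x, int(round(x.sum()))


def reference_size(data: Data) -> int:
    """Reference sample size: individuals (abundance) or units (incidence)."""
    return _as_data(data)[2]


def _coverage(basis: str, vec: np.ndarray, ref: int, m: int) -> float:
    if basis == "abundance":
        return coverage_estimate(vec, m)
    return coverage_estimate_incidence(IncidenceTable(_series(vec), ref), m)


def _series(vec: np.ndarray):
    import pandas as pd

    return pd.Series(vec.astype(int), index=[f"sp{i}" for i in range(vec.size)])


def estimate_at(data: Data, q: int, m: int) -> DiversityEstimate:
    """Standardized diversity of order q at sample size m (1 <= m <= 2*ref)."""
    basis, vec, ref = _as_data(data)
    if m < 1 or m > 2 * ref:
        raise ValueError(f"m={m} outside [1, {2 * ref}]")
    if basis == "abundance":
        est = _D_abundance(vec, q, m)
    else:
        est = _D_incidence(vec, ref, q, m)
    kind = "interpolated" if m < ref else ("observed" if m == ref else "extrapolated")
    return DiversityEstimate(q=q, m=m, coverage=_coverage(basis, vec, ref, m), estimate=est, kind=kind)


def rarefy(data: Data, q: int, m: int) -> DiversityEstimate:
    """Interpolated diversity at m at or below the reference sample size."""
    ref = reference_size(data)
    if not 1 <= m <= ref:
        raise ValueError(f"rarefaction needs 1 <= m <= reference ({ref}); got {m}")
    return estimate_at(data, q, m)


def extrapolate(data: Data, q: int, m: int) -> DiversityEstimate:
    """Extrapolated diversity above the reference size, at most doubling it."""
    ref = reference_size(data)
    if not ref < m <= 2 * ref:
        raise ValueError(f"extrapolation needs reference < m <= 2*reference ({ref}); got {m}")
    return estimate_at(data, q, m)


def doubling_rule(reference_sizes: Iterable[int]) -> int:
    """Common extrapolation limit when comparing assemblages: 2x the smaller
    reference sample size."""
    return 2 * min(int(r) for r in reference_sizes)


def knot_grid(reference: int, knots: int = 40, limit: int | None = None) -> list[int]:
    """Evenly spaced integer sample sizes from 1 to the extrapolation limit
    (default 2x reference), always including the reference itself."""
    if limit is None:
        limit = 2 * reference
    grid = np.unique(np.round(np.linspace(1, limit, knots)).astype(int))
    grid = np.unique(np.concatenate([grid, [reference]]))
    return [int(g) for g in grid if 1 <= g <= limit]


# ---------------------------------------------------------------------------
# bootstrap


def _bootstrap_population_abundance(x: np.ndarray) -> np.ndarray:
    """Augmented relative-abundance vector (observed + estimated unseen)."""
    n = int(round(x.sum()))
    f1, f2 = _f1_f2(x)
    chat = coverage_estimate(x)
    f0 = int(np.ceil(_unseen_richness(f1, f2, n)))
    p = x / n
    if f0 == 0 or chat >= 1.0:
        return p
    w = float(np.sum(p * (1.0 - p) ** n))
    lam = (1.0 - chat) / w if w > 0 else 0.0
    p_adj = p * (1.0 - lam * (1.0 - p) ** n)
    p_unseen = np.full(f0, (1.0 - chat) / f0)
    return np.concatenate([p_adj, p_unseen])


def _bootstrap_population_incidence(y: np.ndarray, T: int) -> np.ndarray:
    """Augmented detection-probability vector for incidence bootstrap."""
    U = float(y.sum())
    Q1, Q2 = _f1_f2(y)
    chat = coverage_estimate_incidence(IncidenceTable(_series(y), T))
    Q0 = int(np.ceil(_unseen_richness(Q1, Q2, T)))
    pi = y / T
    if Q0 == 0 or chat >= 1.0:
        return pi
    w = float(np.sum((y / U) * (1.0 - pi) ** T))
    lam = (1.0 - chat) / w if w > 0 else 0.0
    pi_adj = pi * (1.0 - lam * (1.0 - pi) ** T)
    pi_unseen = np.full(Q0, (U / T) * (1.0 - chat) / Q0)
    return np.concatenate([pi_adj, np.minimum(pi_unseen, 1.0)])


def bootstrap_ci(
    data: Data,
    q: int | Sequence[int] = (0, 1, 2),
    m_grid: Sequence[int] | None = None,
    replications: int = 200,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
):
    """Rarefaction/extrapolation curves with bootstrap confidence bands.

    The point estimates are analytic; the bootstrap resamples an augmented
    community (observed species with coverage-adjusted probabilities plus
    the estimated unseen component), recomputes each curve, and the CI is
    the normal approximation ``estimate +/- z * SD`` of the replicates.
    Deterministic under a fixed seed.

    Returns a long-format DataFrame with columns
    ``basis, q, m, coverage, estimate, ci_low, ci_high, kind``.
    """
    import pandas as pd
    from scipy.stats import norm

    if replications < 2:
        raise ValueError("need at least 2 bootstrap replications")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qs = [q] if isinstance(q, int) else list(q)
    basis, vec, ref = _as_data(data)
    if m_grid is None:
        m_grid = knot_grid(ref)
    z = norm.ppf(0.5 + level / 2.0)

    if basis == "abundance":
        pop = _bootstrap_population_abundance(vec)
        n = int(round(vec.sum()))
        draws = rng.multinomial(n, pop, size=replications)
        evaluate = lambda counts, qq, m: _D_abundance(counts[counts > 0].astype(float), qq, m)
        cov_of = lambda counts, m: coverage_estimate(counts[counts > 0], m)
    else:
        pop = _bootstrap_population_incidence(vec, ref)
        draws = rng.binomial(ref, pop[None, :].repeat(replications, axis=0))
        evaluate = lambda ys, qq, t: _D_incidence(ys[ys > 0].astype(float), ref, qq, t)

        def cov_of(ys, t):
            ys = ys[ys > 0]
            return coverage_estimate_incidence(IncidenceTable(_series(ys), ref), t)

    rows = []
    for qq in qs:
        point = [estimate_at(data, qq, m) for m in m_grid]
        boot = np.empty((replications, len(m_grid)))
        for b in range(replications):
            counts = draws[b]
            if not (counts > 0).any():
                boot[b, :] = np.nan
                continue
            for j, m in enumerate(m_grid):
                boot[b, j] = evaluate(counts, qq, m)
        sd = np.nanstd(boot, axis=0, ddof=1)
        for est, s in zip(point, sd):
            rows.append(
                {
                    "basis": basis,
                    "q": qq,
                    "m": est.m,
                    "coverage": est.coverage,
                    "estimate": est.estimate,
                    "ci_low": est.estimate - z * s,
                    "ci_high": est.estimate + z * s,
                    "kind": est.kind,
                }
            )
    return pd.DataFrame(rows)


def diversity_profile(
    data: Data,
    qs: Sequence[int] = (0, 1, 2),
    knots: int = 40,
    limit: int | None = None,
    replications: int = 200,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
):
    """Full size-standardized diversity profile (all q, CI bands)."""
    ref = reference_size(data)
    grid = knot_grid(ref, knots=knots, limit=limit)
    return bootstrap_ci(data, q=qs, m_grid=grid, replications=replications, level=level, seed=seed)
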