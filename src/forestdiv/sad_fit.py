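"""Species-abundance-distribution (SAD) model fitting and selection.

Six classical models for the expected abundance of the species of rank r
(rank 1 = most abundant, S species, N individuals):

* broken-stick          a_r = (N/S) * sum_{k=r..S} 1/k            (0 free params)
* niche preemption      a_r = N * alpha * (1-alpha)^(r-1)         (1)
* log-normal            a_r = exp(ln mu + ln sigma * Phi_r)       (2)
* Zipf                  a_r = N * p1 * r^gamma                    (1; p1 tied to rank 1)
* Zipf-Mandelbrot       a_r = N * c * (r+beta)^gamma              (3)
* neutral theory        expected rank curve derived from phi_n,
                        the Volkov sampling-formula integral       (2: theta, m)

Phi_r is the standard normal quantile at the mid-rank plotting position
(S - r + 0.5)/S. All models are fitted by maximizing a Poisson likelihood
of the observed ranked abundances given the model expectations (the
convention of standard rank-abundance fitters), which puts log L and
AIC = -2 log L + 2k on a common footing across models. Goodness of fit is
additionally summarized by a two-sample Kolmogorov-Smirnov statistic
between the observed and expected abundance distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import ks_2samp, norm

__all__ = [
    "MODELS",
    "RankedAbundance",
    "SADFitResult",
    "expected_broken_stick",
    "expected_preemption",
    "expected_lognormal",
    "expected_zipf",
    "expected_zm",
    "neutral_phi",
    "neutral_expected_rank",
    "ks_discrepancy",
    "fit_sad",
    "compare_models",
    "aic",
]

MODELS = ("broken-stick", "niche-preemption", "log-normal", "zipf", "zipf-mandelbrot", "neutral")

_MIN_EXPECTED = 1e-9  # floor for model expectations inside the likelihood


@dataclass(frozen=True)
class RankedAbundance:
    """Observed abundances sorted in descending rank order."""

    a: np.ndarray

    @classmethod
    def from_counts(cls, counts: Iterable[float]) -> "RankedAbundance":
        x = np.asarray(list(counts), dtype=float)
        x = np.sort(x[x > 0])[::-1]
        if x.size == 0:
            raise ValueError("no positive abundances")
        return cls(a=x)

    @property
    def N(self) -> int:
        return int(round(self.a.sum()))

    @property
    def S(self) -> int:
        return int(self.a.size)


@dataclass
class SADFitResult:
    model: str
    params: dict[str, float] = field(default_factory=dict)
    k: int = 0
    logL: float = np.nan
    AIC: float = np.nan
    ks_stat: float = np.nan
    ks_p: float = np.nan
    expected: np.ndarray | None = None
    converged: bool = True
    message: str = ""


def aic(logL: float, k: int) -> float:
    """Akaike information criterion, AIC = -2 log L + 2k."""
    return -2.0 * logL + 2.0 * k


# ---------------------------------------------------------------------------
# expected rank-abundance curves


def expected_broken_stick(N: float, S: int) -> np.ndarray:
    """MacArthur's broken-stick expectations; partial harmonic tail sums."""
    k = np.arange(1, S + 1, dtype=float)
    tail = np.cumsum((1.0 / k)[::-1])[::-1]  # sum_{k=r..S} 1/k
    return N / S * tail


def expected_preemption(N: float, S: int, alpha: float) -> np.ndarray:
    """Geometric-series (niche preemption) expectations."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("preemption parameter alpha must lie in (0, 1)")
    r = np.arange(1, S + 1, dtype=float)
    return N * alpha * (1.0 - alpha) ** (r - 1.0)


def expected_lognormal(S: int, mu: float, sigma: float) -> np.ndarray:
    """Log-normal expectations via normal quantiles at mid-rank positions."""
    if sigma <= 1.0:
        raise ValueError("log-normal convention requires sigma > 1 (log sigma > 0)")
    r = np.arange(1, S + 1, dtype=float)
    pos = (S - r + 0.5) / S
    if np.any((pos <= 0) | (pos >= 1)):
        raise ValueError("invalid plotting position")
    phi = norm.ppf(pos)
    return np.exp(np.log(mu) + np.log(sigma) * phi)


def expected_zipf(N: float, S: int, p1: float, gamma: float) -> np.ndarray:
    if gamma >= 0:
        raise ValueError("Zipf exponent gamma must be negative")
    if p1 <= 0:
        raise ValueError("p1 must be positive")
    r = np.arange(1, S + 1, dtype=float)
    return N * p1 * r**gamma


def expected_zm(N: float, S: int, c: float, beta: float, gamma: float) -> np.ndarray:
    if gamma >= 0:
        raise ValueError("Zipf-Mandelbrot exponent gamma must be negative")
    if beta <= -1:
        raise ValueError("beta must exceed -1")
    if c <= 0:
        raise ValueError("c must be positive")
    r = np.arange(1, S + 1, dtype=float)
    return N * c * (r + beta) ** gamma


# ---------------------------------------------------------------------------
# neutral model (Volkov sampling formula)


def neutral_phi(
    n: int | np.ndarray,
    theta: float,
    m: float,
    J: int,
    nodes: int = 240,
) -> float | np.ndarray:
    """Expected number of species with abundance n in a neutral local community.

    Evaluates the sampling-formula integral over y in [0, gamma] with
    gamma = m(J-1)/(1-m), entirely in the log domain (log-Gamma arithmetic
    and Gauss-Legendre quadrature), so it stays finite for community sizes
    in the thousands.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    if not 0.0 < m < 1.0:
        raise ValueError("migration rate m must lie in (0, 1)")
    narr = np.atleast_1d(np.asarray(n, dtype=float))
    if np.any((narr < 1) | (narr > J)):
        raise ValueError("n must lie in [1, J]")
    g = m * (J - 1.0) / (1.0 - m)

    yy, ww = np.polynomial.legendre.leggauss(nodes)
    y = 0.5 * g * (yy + 1.0)  # map [-1,1] -> [0,g]
    logw = np.log(0.5 * g * ww)

    # log integrand, shape (n, nodes)
    li = (
        gammaln(narr[:, None] + y[None, :])
        - gammaln(1.0 + y[None, :])
        + gammaln(J - narr[:, None] + g - y[None, :])
        - gammaln(g - y[None, :])
        - y[None, :] * theta / g
    )
    log_int = logsumexp(li + logw[None, :], axis=1)
    if not np.all(np.isfinite(log_int)):
        raise ArithmeticError("neutral quadrature did not converge (non-finite integral)")
    logphi = (
        np.log(theta)
        + gammaln(J + 1.0)
        - gammaln(narr + 1.0)
        - gammaln(J - narr + 1.0)
        + gammaln(g)
        - gammaln(J + g)
        + log_int
    )
    phi = np.exp(logphi)
    return float(phi[0]) if np.isscalar(n) else phi


def _neutral_phi_all(theta: float, m: float, J: int) -> np.ndarray:
    """phi_n for n = 1..J; exact for small J, log-grid interpolated above."""
    if J <= 400:
        return np.asarray(neutral_phi(np.arange(1, J + 1), theta, m, J))
    grid = np.unique(
        np.concatenate(
            [np.arange(1, 33), np.round(np.geomspace(33, J, 140)).astype(int)]
        )
    )
    phi_g = np.asarray(neutral_phi(grid, theta, m, J))
    logphi = np.interp(np.log(np.arange(1, J + 1)), np.log(grid), np.log(np.maximum(phi_g, 1e-300)))
    return np.exp(logphi)


def neutral_expected_rank(theta: float, m: float, J: int, S: int) -> np.ndarray:
    """Expected ranked abundances implied by the neutral SAD.

    The cumulative expected species count F(a) = sum_{n>=a} phi_n is
    inverted at the mid-rank levels r - 1/2: the expected abundance of the
    rank-r species is the level a where F(a) crosses r - 1/2 (monotone
    interpolation on log abundance). Ranks beyond the expected richness
    receive a vanishing expectation.
    """
    phi = _neutral_phi_all(theta, m, J)
    n = np.arange(1, J + 1, dtype=float)
    F = np.cumsum(phi[::-1])[::-1]  # F[i] = sum_{n >= i+1} phi_n, decreasing
    levels = np.arange(1, S + 1, dtype=float) - 0.5
    # interpolate log(a) as a function of F (F decreasing in a)
    Fr = F[::-1]
    log_a = np.interp(levels, Fr, np.log(n)[::-1])
    a_hat = np.exp(log_a)
    a_hat[levels > F[0]] = _MIN_EXPECTED  # beyond expected richness
    return np.sort(a_hat)[::-1]


# ---------------------------------------------------------------------------
# fitting


def ks_discrepancy(observed, expected) -> tuple[float, float]:
    """Two-sample K-S statistic (and asymptotic p) between the observed and
    expected species-abundance distributions; 0 iff identical. The p-value
    is asymptotic and conservative under discrete ties."""
    res = ks_2samp(np.asarray(observed, float), np.asarray(expected, float), method="asymp")
    return float(res.statistic), float(res.pvalue)


def _poisson_logL(a: np.ndarray, a_hat: np.ndarray) -> float:
    mu = np.maximum(np.asarray(a_hat, dtype=float), _MIN_EXPECTED)
    return float(np.sum(a * np.log(mu) - mu - gammaln(a + 1.0)))


def _as_ranked(observed) -> RankedAbundance:
    if isinstance(observed, RankedAbundance):
        return observed
    return RankedAbundance.from_counts(observed)


def _fit_broken_stick(obs: RankedAbundance) -> tuple[dict, np.ndarray, bool, str]:
    return {}, expected_broken_stick(obs.N, obs.S), True, ""


def _fit_preemption(obs: RankedAbundance) -> tuple[dict, np.ndarray, bool, str]:
    def nll(alpha: float) -> float:
        return -_poisson_logL(obs.a, expected_preemption(obs.N, obs.S, alpha))

    res = minimize_scalar(nll, bounds=(1e-8, 1 - 1e-8), method="bounded",
                          options={"xatol": 1e-10})
    return {"alpha": float(res.x)}, expected_preemption(obs.N, obs.S, res.x), res.success, ""


def _fit_lognormal(obs: RankedAbundance) -> tuple[dict, np.ndarray, bool, str]:
    la = np.log(obs.a)

    def nll(p: np.ndarray) -> float:
        log_mu, t = p
        log_sigma = np.exp(t)  # enforce sigma > 1
        a_hat = np.exp(log_mu + log_sigma * norm.ppf((obs.S - np.arange(1, obs.S + 1) + 0.5) / obs.S))
        return -_poisson_logL(obs.a, a_hat)

    x0 = np.array([la.mean(), np.log(max(la.std(), 0.1))])
    res = minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000})
    mu, sigma = float(np.exp(res.x[0])), float(np.exp(np.exp(res.x[1])))
    return {"mu": mu, "sigma": sigma}, expected_lognormal(obs.S, mu, sigma), res.success, res.message


def _fit_zipf(obs: RankedAbundance, free_p1: bool = False) -> tuple[dict, np.ndarray, bool, str]:
    p1_obs = obs.a[0] / obs.N

    if not free_p1:
        def nll(g: float) -> float:
            return -_poisson_logL(obs.a, expected_zipf(obs.N, obs.S, p1_obs, -np.exp(g)))

        res = minimize_scalar(nll, bounds=(np.log(1e-3), np.log(10.0)), method="bounded",
                              options={"xatol": 1e-10})
        gamma = -float(np.exp(res.x))
        params = {"p1": float(p1_obs), "gamma": gamma}
        return params, expected_zipf(obs.N, obs.S, p1_obs, gamma), res.success, ""

    def nll2(p: np.ndarray) -> float:
        lp1, g = p
        return -_poisson_logL(obs.a, expected_zipf(obs.N, obs.S, np.exp(lp1), -np.exp(g)))

    res = minimize(nll2, np.array([np.log(p1_obs), 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 2000})
    p1, gamma = float(np.exp(res.x[0])), -float(np.exp(res.x[1]))
    return {"p1": p1, "gamma": gamma}, expected_zipf(obs.N, obs.S, p1, gamma), res.success, res.message


def _fit_zm(obs: RankedAbundance) -> tuple[dict, np.ndarray, bool, str]:
    # parametrization: c = exp(lc), beta = exp(b) - 1 (> -1), gamma = -exp(g)
    def nll(p: np.ndarray) -> float:
        lc, b, g = p
        beta = np.expm1(b)
        if not np.isfinite(beta):
            return np.inf
        try:
            a_hat = expected_zm(obs.N, obs.S, np.exp(lc), beta, -np.exp(g))
        except (ValueError, FloatingPointError):
            return np.inf
        return -_poisson_logL(obs.a, a_hat)

    # deterministic multi-start around the Zipf solution
    zp, _, _, _ = _fit_zipf(obs)
    starts = [
        np.array([np.log(zp["p1"]), np.log(1e-6 + 1.0) - 1.0, np.log(-zp["gamma"])]),
        np.array([np.log(zp["p1"]), np.log(2.0), np.log(max(-zp["gamma"] * 2, 0.1))]),
        np.array([np.log(0.5), np.log(5.0), np.log(1.0)]),
        np.array([np.log(0.1), np.log(0.5), np.log(0.5)]),
    ]
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-8, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    c = float(np.exp(best.x[0]))
    beta = float(np.expm1(best.x[1]))
    gamma = -float(np.exp(best.x[2]))
    ok = bool(best.success and np.isfinite(best.fun))
    msg = "" if ok else f"optimizer did not converge after {len(starts)} restarts"
    return {"c": c, "beta": beta, "gamma": gamma}, expected_zm(obs.N, obs.S, c, beta, gamma), ok, msg


def _ewens_theta(S: int, J: int) -> float:
    """Solve S = theta * ln(1 + J/theta) for a starting biodiversity number."""
    lo, hi = 1e-3, 1e5
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if mid * np.log1p(J / mid) < S:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _fit_neutral(obs: RankedAbundance) -> tuple[dict, np.ndarray, bool, str]:
    J, S = obs.N, obs.S

    def nll(theta: float, m: float) -> float:
        try:
            a_hat = neutral_expected_rank(theta, m, J, S)
        except (ArithmeticError, FloatingPointError):
            return np.inf
        return -_poisson_logL(obs.a, a_hat)

    theta0 = _ewens_theta(S, J)
    theta_grid = theta0 * np.array([0.33, 0.67, 1.0, 1.5, 3.0])
    m_grid = np.array([0.02, 0.1, 0.3, 0.6, 0.9])
    best_val, best_tm = np.inf, (theta0, 0.3)
    for th in theta_grid:
        for mm in m_grid:
            v = nll(th, mm)
            if v < best_val:
                best_val, best_tm = v, (th, mm)

    def nll_vec(p: np.ndarray) -> float:
        th = np.exp(p[0])
        mm = 1.0 / (1.0 + np.exp(-p[1]))  # logit^-1, keeps m in (0,1)
        if not (1e-4 < mm < 1 - 1e-9):
            return np.inf
        return nll(th, mm)

    x0 = np.array([np.log(best_tm[0]), np.log(best_tm[1] / (1 - best_tm[1]))])
    res = minimize(nll_vec, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
    theta = float(np.exp(res.x[0]))
    m = float(1.0 / (1.0 + np.exp(-res.x[1])))
    ok = bool(np.isfinite(res.fun))
    return (
        {"theta": theta, "m": m, "J": float(J)},
        neutral_expected_rank(theta, m, J, S),
        ok,
        "" if ok else "neutral optimization non-convergent",
    )


_FITTERS = {
    "broken-stick": (_fit_broken_stick, 0),
    "niche-preemption": (_fit_preemption, 1),
    "log-normal": (_fit_lognormal, 2),
    "zipf": (_fit_zipf, 1),
    "zipf-mandelbrot": (_fit_zm, 3),
    "neutral": (_fit_neutral, 2),
}


def fit_sad(observed, model: str, **kwargs) -> SADFitResult:
    """Fit one SAD model to ranked abundances; Poisson ML, K-S, AIC.

    Optimizer failure is reported through ``converged``/``message`` on the
    result, never as a silent wrong answer.
    """
    obs = _as_ranked(observed)
    if model not in _FITTERS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if model != "broken-stick" and obs.S < 3:
        raise ValueError("parametric SAD fits need at least 3 species")
    fitter, k = _FITTERS[model]
    if model == "zipf" and kwargs.get("free_p1"):
        k = 2
    try:
        params, expected, ok, msg = fitter(obs, **kwargs)
    except Exception as exc:  # fit failure is a result, not a crash
        return SADFitResult(model=model, k=k, converged=False, message=str(exc))
    logL = _poisson_logL(obs.a, expected)
    ks_stat, ks_p = ks_discrepancy(obs.a, expected)
    return SADFitResult(
        model=model,
        params=params,
        k=k,
        logL=logL,
        AIC=aic(logL, k),
        ks_stat=ks_stat,
        ks_p=ks_p,
        expected=expected,
        converged=ok,
        message=msg,
    )


def compare_models(observed, models: Sequence[str] = MODELS) -> list[SADFitResult]:
    """Fit every model and rank by AIC (ascending); failed fits sort last."""
    obs = _as_ranked(observed)
    fits = [fit_sad(obs, m) for m in models]
    return sorted(
        fits,
        key=lambda f: (not f.converged, f.AIC if np.isfinite(f.AIC) else np.inf),
    )


def comparison_table(fits: Sequence[SADFitResult]):
    """Model-comparison summary as a DataFrame (one row per model)."""
    import pandas as pd

    rows = []
    for f in fits:
        rows.append(
            {
                "model": f.model,
                "k": f.k,
                "logL": f.logL,
                "AIC": f.AIC,
                "ks_stat": f.ks_stat,
                "ks_p": f.ks_p,
                "converged": f.converged,
                "params": ";".join(f"{k}={v:.6g}" for k, v in f.params.items()),
                "message": f.message,
            }
        )
    return pd.DataFrame(rows)
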