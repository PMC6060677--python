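"""STOCSY and the univariate statistics layer.

STOCSY (statistical total correlation spectroscopy) correlates one spectral
variable — the driver — against every other variable across samples; peaks
of the same molecule show near-unit correlation, which is the basis of
metabolite assignment.  The univariate layer carries the cohort-level tests:
Mann-Whitney (exact by enumeration at small n, tie-corrected normal
approximation otherwise), Spearman rank correlation, one/two-tailed t-tests
with optional log transform (Welch by default), Pearson chi-square on count
tables, geometric means with t-based confidence intervals on the log scale,
and covariate-adjusted logistic regression with explicit separation
reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "StocsyResult",
    "TestResult",
    "LogisticResult",
    "stocsy",
    "mann_whitney",
    "spearman",
    "t_test",
    "chi_square",
    "geometric_mean_ci",
    "logistic_adjusted",
]


@dataclass
class StocsyResult:
    driver_ppm: float
    driver_index: int
    r: np.ndarray
    cov: np.ndarray


@dataclass
class TestResult:
    statistic: float
    p_value: float
    tail: str
    method: str
    n: tuple[int, ...]


def stocsy(X: np.ndarray, ppm: np.ndarray, driver_ppm: float) -> StocsyResult:
    """Correlate the driver column (nearest grid point) with every column.

    Returns per-variable Pearson r and covariance (n-1 denominator) across
    samples — r for colouring, covariance for the spectrum-like profile.
    Zero-variance columns get r = 0; a zero-variance driver is an error.
    """
    X = np.asarray(X, dtype=float)
    ppm = np.asarray(ppm, dtype=float)
    if X.ndim != 2 or X.shape[1] != ppm.size:
        raise ValueError("X columns must match the ppm axis")
    if X.shape[0] < 3:
        raise ValueError("STOCSY needs at least 3 samples")
    j = int(np.argmin(np.abs(ppm - float(driver_ppm))))
    d = X[:, j] - X[:, j].mean()
    dn = float(np.linalg.norm(d))
    if dn == 0.0:
        raise ValueError(f"driver column at {ppm[j]:g} ppm has zero variance")
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ d) / (X.shape[0] - 1)
    norms = np.linalg.norm(Xc, axis=0)
    r = np.zeros(ppm.size)
    ok = norms > 0
    r[ok] = (Xc[:, ok].T @ d) / (norms[ok] * dn)
    return StocsyResult(driver_ppm=float(ppm[j]), driver_index=j, r=r, cov=cov)


# ---------------------------------------------------------------------------
# rank tests


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a (pairs where a < b count 0), with midranks for ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    ra = float(ranks[: a.size].sum())
    return ra - a.size * (a.size + 1) / 2.0


def mann_whitney(a, b, tail: str = "two", exact_max_n: int = 10) -> TestResult:
    """Mann-Whitney U test.

    Uses exact enumeration over all ``C(n_a+n_b, n_a)`` group assignments
    when the pooled size is at most ``exact_max_n`` (valid under ties),
    otherwise the tie-corrected normal approximation with continuity
    correction.  ``tail="one"`` reports the tail in the direction of the
    observed shift; ``"two"`` doubles it (capped at 1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    u_obs = _u_statistic(a, b)
    n_tot = a.size + b.size
    if n_tot <= exact_max_n:
        pooled = np.concatenate([a, b])
        idx = np.arange(n_tot)
        us = []
        for comb in combinations(idx, a.size):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(comb)] = True
            us.append(_u_statistic(pooled[mask], pooled[~mask]))
        us = np.asarray(us)
        tol = 1e-9
        p_low = float(np.mean(us <= u_obs + tol))
        p_high = float(np.mean(us >= u_obs - tol))
        p_one = min(p_low, p_high)
        method = "mann-whitney (exact enumeration)"
    else:
        mu = a.size * b.size / 2.0
        pooled = np.concatenate([a, b])
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / (n_tot * (n_tot - 1))
        var = a.size * b.size / 12.0 * (n_tot + 1 - tie_term)
        if var <= 0:
            p_one = 0.5
        else:
            # continuity-corrected z toward the observed direction
            z = (abs(u_obs - mu) - 0.5) / np.sqrt(var)
            p_one = float(sps.norm.sf(max(z, 0.0)))
        method = "mann-whitney (normal approximation)"
    p = p_one if tail == "one" else min(1.0, 2.0 * p_one)
    return TestResult(statistic=u_obs, p_value=p, tail=tail, method=method, n=(a.size, b.size))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation: midrank-Pearson rho, t-approximation p.

    Pairs with a missing member are dropped; needs >= 3 complete pairs and
    non-constant vectors.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), p_value=float(p), tail="two",
                      method="spearman", n=(x.size,))


def t_test(a, b, log_transform: bool = False, tail: str = "two", welch: bool = True) -> TestResult:
    """Two-sample t-test, optionally on log-transformed values.

    Welch (unequal-variance) by default; ``tail="one"`` is the tail in the
    direction of the observed mean difference (p_two / 2).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    if log_transform:
        for name, g in (("a", a), ("b", b)):
            if np.any(g <= 0):
                i = int(np.argmax(g <= 0))
                raise ValueError(
                    f"log transform requires positive values; group {name} "
                    f"entry {i} is {g[i]:g}"
                )
        a, b = np.log(a), np.log(b)
    res = sps.ttest_ind(a, b, equal_var=not welch)
    p = float(res.pvalue)
    if tail == "one":
        p = p / 2.0
    return TestResult(
        statistic=float(res.statistic),
        p_value=p,
        tail=tail,
        method="welch t" if welch else "pooled t",
        n=(a.size, b.size),
    )


def chi_square(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2 x k count table (no continuity correction
    by default)."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2 x k with k >= 2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise ValueError("degenerate table: a row or column sums to zero")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=yates)
    return TestResult(statistic=float(chi2), p_value=float(p), tail="two",
                      method="pearson chi2" + (" (yates)" if yates else ""),
                      n=(int(table.sum()),))


def geometric_mean_ci(x, level: float = 0.95) -> tuple[float, float, float]:
    """Geometric mean with a t-based CI computed on the log scale.

    All-equal input degenerates gracefully to a zero-width interval.
    """
    x = np.asarray(x, dtype=float).ravel()
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    if x.size < 2:
        raise ValueError("need at least 2 values")
    logs = np.log(x)
    m = logs.mean()
    s = logs.std(ddof=1)
    gm = float(np.exp(m))
    if s == 0.0:
        return gm, gm, gm
    tcrit = float(sps.t.ppf(0.5 + level / 2.0, df=x.size - 1))
    half = tcrit * s / np.sqrt(x.size)
    return gm, float(np.exp(m - half)), float(np.exp(m + half))


# ---------------------------------------------------------------------------
# adjusted logistic regression


@dataclass
class LogisticResult:
    params: np.ndarray | None  # (const, metabolite, covariate)
    p_values: np.ndarray | None
    converged: bool
    separation: bool
    term_names: tuple[str, ...] = ("const", "metabolite", "covariate")


def logistic_adjusted(outcome, metabolite, covariate) -> LogisticResult:
    """Logistic regression of a binary outcome on metabolite + covariate.

    Maximum-likelihood fit (Newton/IRLS) with Wald p-values per coefficient.
    Perfect or quasi-perfect separation is flagged rather than returned as a
    spuriously huge coefficient.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    yv = np.asarray(outcome, dtype=float).ravel()
    met = np.asarray(metabolite, dtype=float).ravel()
    cov = np.asarray(covariate, dtype=float).ravel()
    if not (yv.size == met.size == cov.size):
        raise ValueError("outcome, metabolite and covariate must be the same length")
    if yv.size < 10:
        raise ValueError("need at least 10 observations")
    if not set(np.unique(yv)) == {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1 with both classes present")
    X = sm.add_constant(np.column_stack([met, cov]))
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(yv, X).fit(disp=0, method="newton", maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticResult(params=None, p_values=None, converged=False, separation=True)
    params = np.asarray(fit.params)
    # quasi-separation shows up as runaway coefficients / fitted probs at 0 or 1
    probs = fit.predict(X)
    separated = bool(
        np.max(np.abs(params[1:])) > 25
        or np.all((probs > 0.999) == (yv == 1))
        and np.all((probs < 0.001) == (yv == 0))
        and np.all((probs > 0.999) | (probs < 0.001))
    )
    if separated:
        return LogisticResult(params=params, p_values=None, converged=bool(fit.mle_retvals.get("converged", False)), separation=True)
    return LogisticResult(
        params=params,
        p_values=np.asarray(fit.pvalues),
        converged=bool(fit.mle_retvals.get("converged", True)),
        separation=False,
    )
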