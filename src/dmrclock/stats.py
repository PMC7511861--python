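"""Shared statistical primitives.

Small wrappers with a uniform :class:`TestResult` return type: Pearson
correlation with its t-transform p-value, the critical correlation for a
given alpha and n, Welch's unequal-variance t-test (with a strain-paired
variant), OLS with partial (Type-II) F-tests, and the hypergeometric tail
used for genomic-feature enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "TestResult",
    "pearson_with_p",
    "critical_r",
    "welch_t",
    "paired_t",
    "ols_partial_f",
    "hypergeometric_tail",
    "hypergeometric_lower_tail",
]


@dataclass(frozen=True)
class TestResult:
    """A scalar test: statistic, p-value, point estimate, degrees of freedom.

    ``estimate`` is the quantity of scientific interest (r, a mean
    difference, or a regression coefficient); ``df`` may be fractional
    (Welch) or a (num, den) tuple for F-tests.
    """

    statistic: float
    p_value: float
    estimate: float
    df: float | tuple[float, float]

    def __post_init__(self):
        p = self.p_value
        if not (np.isnan(p) or 0.0 <= p <= 1.0):
            raise ValueError(f"p_value out of [0,1]: {p}")


def pearson_with_p(x, y) -> TestResult:
    """Pearson correlation with the two-sided t-transform p at n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if 1.0 - r * r < 1e-15:
        t = math.copysign(math.inf, r)
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return TestResult(statistic=float(t), p_value=float(p), estimate=r, df=float(n - 2))


def critical_r(alpha: float, n: int) -> float:
    """|r| whose two-sided correlation p equals ``alpha`` at sample size n.

    r* = t* / sqrt(n - 2 + t*^2) with t* the (1 - alpha/2) t quantile at
    n - 2 df. critical_r(0.05, 52) = 0.27: the nominal cis-correlation
    threshold for 52 paired methylome/transcriptome samples.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n < 3:
        raise ValueError("need n >= 3")
    t = float(sps.t.ppf(1 - alpha / 2, n - 2))
    return t / np.sqrt(n - 2 + t * t)


def welch_t(a, b) -> TestResult:
    """Welch's unequal-variance two-sample t with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    diff = float(np.mean(a) - np.mean(b))
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no variance anywhere; no evidence either way
        return TestResult(statistic=0.0, p_value=1.0, estimate=diff, df=float(len(a) + len(b) - 2))
    t, p = sps.ttest_ind(a, b, equal_var=False)
    va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return TestResult(statistic=float(t), p_value=float(p), estimate=diff, df=float(df))


def paired_t(a, b) -> TestResult:
    """Paired t-test on matched observations (e.g. strain-matched diets)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need matched vectors with n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        p = 1.0 if d[0] == 0 else 0.0
        return TestResult(statistic=np.inf if d[0] else 0.0, p_value=p, estimate=float(d.mean()), df=float(len(d) - 1))
    t, p = sps.ttest_rel(a, b)
    return TestResult(statistic=float(t), p_value=float(p), estimate=float(d.mean()), df=float(len(d) - 1))


def ols_partial_f(response, design: pd.DataFrame, term: str) -> TestResult:
    """Partial (Type-II style) F-test for one named term in an OLS fit.

    ``design`` holds named covariate columns; categorical (object) columns
    are dummy-expanded, so a k-level factor contributes k-1 numerator df.
    The F compares the full model to the model with the term's columns
    dropped. ``estimate`` is the term's coefficient when the term is a
    single numeric column, else NaN.
    """
    y = np.asarray(response, dtype=float)
    if term not in design.columns:
        raise ValueError(f"term {term!r} not in design")
    X_full = pd.get_dummies(design, drop_first=True, dtype=float)
    term_cols = [
        c for c in X_full.columns if c == term or c.startswith(f"{term}_")
    ]
    if term in design.columns and design[term].dtype.kind in "if":
        term_cols = [term]
    if not term_cols:
        raise ValueError(f"term {term!r} produced no design columns")
    X_full = sm.add_constant(X_full, has_constant="add")
    rank = np.linalg.matrix_rank(X_full.to_numpy())
    if rank < X_full.shape[1]:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X_full.shape[1]} columns); "
            f"check collinearity among {list(design.columns)}"
        )
    full = sm.OLS(y, X_full).fit()
    X_red = X_full.drop(columns=term_cols)
    red = sm.OLS(y, X_red).fit()
    df_num = len(term_cols)
    df_den = float(full.df_resid)
    if full.ssr == 0:
        f = np.inf if red.ssr > 0 else 0.0
    else:
        f = (red.ssr - full.ssr) / df_num / (full.ssr / df_den)
    p = float(sps.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    est = float(full.params[term_cols[0]]) if df_num == 1 else float("nan")
    return TestResult(statistic=float(f), p_value=p, estimate=est, df=(float(df_num), df_den))


def _check_hypergeom(N: int, K: int, n: int, k: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= n and k <= K):
        raise ValueError(f"incoherent hypergeometric counts N={N} K={K} n={n} k={k}")
    if n - k > N - K:
        raise ValueError(f"more failures drawn ({n - k}) than exist ({N - K})")


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) drawing n from N with K successes (enrichment)."""
    _check_hypergeom(N, K, n, k)
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def hypergeometric_lower_tail(N: int, K: int, n: int, k: int) -> float:
    """Lower-tail P(X <= k) (depletion)."""
    _check_hypergeom(N, K, n, k)
    return float(sps.hypergeom.cdf(k, N, K, n))
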