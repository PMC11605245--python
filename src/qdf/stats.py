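"""Comparison statistics for per-cell signal tables.

The shape-dependence analysis regresses per-cell signal (darkfield or QDF per
unit dry mass) on mass per area — a proxy for cell rounding — and tests the
fit against a constant-signal null with an F-test; the population comparison
contrasts two per-cell signal distributions with a two-sample t-test and the
Kullback-Leibler divergence of their shared-bin histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError


@dataclass
class RegressionResult:
    """Simple linear regression with an F-test against the flat (zero-slope) null."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    f_statistic: float
    p_value: float
    n: int


def fit_vs_flat(x, y) -> RegressionResult:
    """Ordinary least squares y = a + b x, tested against a flat line.

    The null model is the constant y = mean(y); the F statistic
    ``(SS_flat - SS_fit) / (SS_fit / (n - 2))`` follows F(1, n-2) under the
    null, and its upper tail gives the p-value (equivalently the two-sided
    slope t-test).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise DataError("need at least 3 points for the F-test")
    if np.ptp(x) == 0:
        raise DataError("x is constant; slope undefined")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_fit = float(np.sum(resid**2))
    ss_flat = float(np.sum((y - ym) ** 2))
    if ss_flat == 0.0:
        # y constant: the fit is exact and flat; no evidence against the null
        return RegressionResult(0.0, ym, 0.0, 0.0, 0.0, 1.0, n)
    r2 = 1.0 - ss_fit / ss_flat
    r = float(np.sign(slope) * np.sqrt(max(r2, 0.0)))
    if ss_fit == 0.0:
        return RegressionResult(slope, intercept, 1.0, r, np.inf, 0.0, n)
    f = (ss_flat - ss_fit) / (ss_fit / (n - 2))
    p = float(sps.f.sf(f, 1, n - 2))
    return RegressionResult(slope, intercept, r2, r, float(f), p, n)


def binned_fit(x, y, bin_width: float) -> pd.DataFrame:
    """Per-bin mean and standard deviation of y over half-open x bins.

    Bins are ``[k*w, (k+1)*w)``; empty bins are omitted. Std is the
    population standard deviation (ddof=0), so a single-point bin reports 0.
    """
    if bin_width <= 0:
        raise ConfigError("bin_width must be positive")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise DataError("x and y must have equal length")
    k = np.floor(x / bin_width).astype(np.int64)
    rows = []
    for kk in np.unique(k):
        sel = k == kk
        rows.append(
            {
                "bin_left": kk * bin_width,
                "bin_right": (kk + 1) * bin_width,
                "n": int(sel.sum()),
                "mean": float(y[sel].mean()),
                "std": float(y[sel].std(ddof=0)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class DivergenceResult:
    """Histogram Kullback-Leibler divergence D_KL(P || Q).

    P and Q share bin edges; probabilities come from add-one (Laplace)
    smoothed counts so empty Q bins never produce infinities. ``log_base``
    states the unit (2 = bits, e = nats).
    """

    dkl: float
    bin_edges: np.ndarray
    p_probs: np.ndarray
    q_probs: np.ndarray
    log_base: float


def kl_from_probs(p_probs, q_probs, log_base: float = 2.0) -> float:
    """D_KL(P || Q) for two probability vectors on shared bins.

    Terms with p_i = 0 contribute nothing; q_i = 0 with p_i > 0 is infinite
    by definition (the histogram front-end avoids this via smoothing).
    """
    p = np.asarray(p_probs, dtype=np.float64)
    q = np.asarray(q_probs, dtype=np.float64)
    if p.shape != q.shape:
        raise DataError("probability vectors must share a shape")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-12):
            raise DataError(f"{name} is not a probability vector")
    sel = p > 0
    with np.errstate(divide="ignore"):
        terms = p[sel] * (np.log(p[sel] / q[sel]) / np.log(log_base))
    return float(np.sum(terms))


def kl_divergence(
    p_samples, q_samples, n_bins: int = 32, log_base: float = 2.0
) -> DivergenceResult:
    """D_KL between the binned distributions of two sample sets.

    Shared bin edges span the pooled 1st-99th percentile range (degenerate
    ranges are widened symmetrically); counts are Laplace-smoothed before
    normalisation. Larger D_KL means more separated distributions; the
    measure is asymmetric in its arguments.
    """
    p = np.asarray(p_samples, dtype=np.float64).ravel()
    q = np.asarray(q_samples, dtype=np.float64).ravel()
    if p.size == 0 or q.size == 0:
        raise DataError("both sample sets must be nonempty")
    pooled = np.concatenate([p, q])
    lo, hi = np.percentile(pooled, [1.0, 99.0])
    if lo == hi:
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, n_bins + 1)
    p_counts, _ = np.histogram(np.clip(p, lo, hi), bins=edges)
    q_counts, _ = np.histogram(np.clip(q, lo, hi), bins=edges)
    p_probs = (p_counts + 1.0) / (p_counts.sum() + n_bins)
    q_probs = (q_counts + 1.0) / (q_counts.sum() + n_bins)
    dkl = kl_from_probs(p_probs, q_probs, log_base)
    return DivergenceResult(
        dkl=max(dkl, 0.0) if np.isclose(dkl, 0.0, atol=1e-15) else dkl,
        bin_edges=edges,
        p_probs=p_probs,
        q_probs=q_probs,
        log_base=log_base,
    )


def two_sample_t(a_samples, b_samples, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test (pooled variance by default, Welch by flag).

    Degenerate zero-variance input: equal means give (0, 1); unequal means
    give (inf, 0) with a warning, since the test statistic is unbounded.
    """
    a = np.asarray(a_samples, dtype=np.float64).ravel()
    b = np.asarray(b_samples, dtype=np.float64).ravel()
    if a.size < 2 or b.size < 2:
        raise DataError("each sample set needs at least 2 values")
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means; p-value degenerate")
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)
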