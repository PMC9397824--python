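"""Reliability and design statistics.

- ICC(2,k): two-way random-effects, absolute-agreement, average-measures
  intraclass correlation (McGraw & Wong's ICC(A,k)), with the F-based 95%
  confidence interval and p-value, for test-retest reliability of
  per-participant scores across sessions.
- Bland–Altman limits of agreement for paired measurements.
- Exact-binomial power and sample size for the triangle discrimination
  test (chance level 1/3).

The ICC is computed here directly from the two-way ANOVA mean squares so
the statistic, its CI, and its p-value are transparent; the formulas are
the standard published ones, so any mainstream implementation can serve as
a cross-check.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    icc_value: float
    ci_low: float
    ci_high: float
    p_value: float
    n_subjects: int
    k_raters: int

    @property
    def classification(self) -> str:
        return classify_icc(self.icc_value)


def classify_icc(icc: float) -> str:
    """Qualitative reliability band: poor / moderate / good / excellent."""
    if not math.isfinite(icc):
        return "undefined"
    if icc > 0.90:
        return "excellent"
    if icc > 0.75:
        return "good"
    if icc > 0.50:
        return "moderate"
    return "poor"


def icc_2k(measurements: np.ndarray, alpha: float = 0.05) -> ICCResult:
    """ICC(2,k) of an n-subjects × k-sessions matrix.

    Two-way random effects, absolute agreement, average of k measurements:

        ICC = (MS_R − MS_E) / (MS_R + (MS_C − MS_E) / n)

    from the row (subject), column (session) and residual mean squares of
    the two-way ANOVA decomposition.  The confidence interval uses the
    F-based single-measure interval with Satterthwaite degrees of freedom,
    stepped up to average measures; the p-value tests ICC = 0 via
    F = MS_R / MS_E on (n−1, (n−1)(k−1)) df.
    """
    data = np.asarray(measurements, dtype=float)
    if data.ndim != 2:
        raise ValueError("measurements must be a 2-D n_subjects × k matrix")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError(f"need at least 3 subjects and 2 sessions, got {data.shape}")
    if np.isnan(data).any():
        raise ValueError("missing cells are not allowed")

    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    if ss_total == 0 or (msr == 0 and mse == 0):
        warnings.warn("zero total variance: ICC undefined")
        return ICCResult(math.nan, math.nan, math.nan, math.nan, n, k)

    icc_k = (msr - mse) / (msr + (msc - mse) / n)
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)

    if mse == 0:
        # zero residual variance: agreement is limited only by column offsets
        return ICCResult(float(icc_k), float(icc_k), float(icc_k), 0.0, n, k)

    f_stat = msr / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    p_value = float(sps.f.sf(f_stat, df1, df2))

    # Satterthwaite df for the single-measure absolute-agreement interval
    fj = msc / mse
    vn = df2 * (k * icc_1 * fj + n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
    vd = df1 * k**2 * icc_1**2 * fj**2 + (n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2
    v = vn / vd
    f_u = sps.f.ppf(1 - alpha / 2, df1, v)
    f_l = sps.f.ppf(1 - alpha / 2, v, df1)
    l1 = n * (msr - f_u * mse) / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
    u1 = n * (f_l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_l * msr)
    # step up single-measure bounds to average measures
    ci_low = l1 * k / (1 + l1 * (k - 1))
    ci_high = u1 * k / (1 + u1 * (k - 1))

    return ICCResult(
        icc_value=float(icc_k),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=p_value,
        n_subjects=n,
        k_raters=k,
    )


# ---------------------------------------------------------------------------
# Bland–Altman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    differences: np.ndarray
    n_outside: int


def bland_altman(x1: Sequence[float], x2: Sequence[float]) -> BlandAltman:
    """Limits of agreement mean ± 1.96 SD of the paired differences x1 − x2."""
    a = np.asarray(x1, dtype=float)
    b = np.asarray(x2, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean - 1.96 * sd, mean + 1.96 * sd
    outside = int(np.count_nonzero((d < lo) | (d > hi)))
    return BlandAltman(
        mean_diff=mean, sd_diff=sd, loa_low=lo, loa_high=hi,
        differences=d, n_outside=outside,
    )


# ---------------------------------------------------------------------------
# Triangle-test power and sample size
# ---------------------------------------------------------------------------

CHANCE = 1.0 / 3.0


def triangle_power(
    n_trials: int, p_alt: float, alpha: float = 0.05
) -> float:
    """Power of the exact one-sided binomial triangle test.

    The critical count is c = min{k : P(X ≥ k | n, 1/3) ≤ alpha}; power is
    P(X ≥ c | n, p_alt).  Returns 0 (with a warning) when no critical
    region of size ≤ alpha exists.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if not CHANCE < p_alt <= 1 and p_alt != CHANCE:
        raise ValueError("p_alt must satisfy 1/3 < p_alt <= 1 (or equal 1/3 for size checks)")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    k = np.arange(n_trials + 1)
    upper_tail = sps.binom.sf(k - 1, n_trials, CHANCE)   # P(X >= k)
    valid = np.nonzero(upper_tail <= alpha)[0]
    if valid.size == 0:
        warnings.warn(
            f"no critical region at alpha={alpha} for n={n_trials}; power is 0"
        )
        return 0.0
    c = int(k[valid[0]])
    return float(sps.binom.sf(c - 1, n_trials, p_alt))


def triangle_sample_size(
    p_alt: float,
    alpha: float = 0.05,
    target_power: float = 0.95,
    mode: str = "first",
    n_max: int = 10_000,
) -> int:
    """Smallest trial count whose exact-binomial power reaches the target.

    The power curve is a sawtooth in n (the discrete critical value
    shifts), so two readings exist: ``mode="first"`` returns the first n
    with power ≥ target (the common convention); ``mode="stable"`` returns
    the first n from which the power never again drops below the target
    (checked up to ``n_max``).
    """
    if p_alt <= CHANCE:
        raise ValueError(f"p_alt must exceed the 1/3 chance level, got {p_alt}")
    if mode not in ("first", "stable"):
        raise ValueError("mode must be 'first' or 'stable'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        powers = {}
        n_first = None
        for n in range(1, n_max + 1):
            powers[n] = triangle_power(n, p_alt, alpha)
            if powers[n] >= target_power:
                n_first = n
                break
        if n_first is None:
            raise ValueError(f"target power not reached by n_max={n_max}")
        if mode == "first":
            return n_first
        # scan onwards until the sawtooth stays above the target
        n_stable = n_first
        horizon = 200  # consecutive qualifying n required
        run = 0
        n = n_first
        while run < horizon and n < n_max:
            n += 1
            if triangle_power(n, p_alt, alpha) >= target_power:
                run += 1
            else:
                n_stable = n + 1
                run = 0
        return n_stable
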