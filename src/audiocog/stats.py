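"""Reliability and dependent-correlation statistics.

Implements the analysis toolkit for paired in-person/web measurements:

* preprocessing (log transform of precision measures, z-scoring, strict
  complete-case handling — missing values are never imputed);
* Pearson r with a Fisher-z (or bootstrap) confidence interval;
* two-way intraclass correlation from the mean-squares decomposition,
  absolute-agreement ICC(2,1) by default or consistency ICC(3,1);
* the Williams–Steiger t test for two dependent correlations sharing a
  variable;
* bootstrap percentile CIs for differences between correlation coefficients
  (row resampling with replacement, default B=1000);
* Pearson chi-square tests on 2x2 proportion tables;
* OLS residualization for controlled (partial) correlations.

No multiple-testing correction is applied anywhere, by design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    StandardizationError,
    ValidationError,
)

__all__ = [
    "PearsonResult",
    "IccResult",
    "SteigerResult",
    "BootstrapDiffResult",
    "Chi2Result",
    "preprocess",
    "pearson_with_ci",
    "icc_two_way",
    "steiger_dependent_corr",
    "bootstrap_corr_diff",
    "chi_square_2x2",
    "residualize",
    "partial_corr",
    "simulate_retest_recovery",
]


@dataclass(frozen=True)
class PearsonResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    ci_method: str


@dataclass(frozen=True)
class IccResult:
    icc: float
    kind: str  # "agreement" (two-way random, absolute) or "consistency"
    n: int
    negative: bool  # estimate came out below zero (returned as computed)


@dataclass(frozen=True)
class SteigerResult:
    statistic: float
    df: int
    p_value: float
    r_jk: float
    r_jh: float
    r_kh: float
    n: int


@dataclass(frozen=True)
class BootstrapDiffResult:
    observed_diff: float
    mean_diff: float
    ci_low: float
    ci_high: float
    B: int
    n: int
    significant: bool
    n_redrawn: int


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    df: int
    p_value: float


def preprocess(
    table: pd.DataFrame,
    log_columns=(),
    z_columns=None,
    id_columns=("participant_id", "setting", "cohort", "hearing_category"),
) -> pd.DataFrame:
    """Analysis-scale transform of a measures table.

    ``log_columns`` (precision measures) are natural-log transformed;
    ``z_columns`` (default: every numeric column not in ``id_columns``) are
    standardized to mean 0, SD 1 over their non-missing values.  Missing
    values propagate untouched — downstream statistics are complete-case per
    statistic, never imputed.

    Raises
    ------
    ValidationError
        A log column contains non-positive values.
    StandardizationError
        A z column has zero variance (names the column).
    """
    out = table.copy()
    for col in log_columns:
        vals = out[col]
        if (vals.dropna() <= 0).any():
            raise ValidationError(f"column {col!r} has non-positive values; cannot log")
        out[col] = np.log(vals)
    if z_columns is None:
        z_columns = [
            c
            for c in out.columns
            if c not in id_columns and pd.api.types.is_numeric_dtype(out[c])
        ]
    for col in z_columns:
        vals = out[col].astype(float)
        sd = vals.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise StandardizationError(f"column {col!r} has zero variance; cannot z-score")
        out[col] = (vals - vals.mean()) / sd
    return out


def _complete_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def pearson_with_ci(
    x, y, alpha: float = 0.05, ci_method: str = "fisher", B: int = 1000, rng=None
) -> PearsonResult:
    """Pearson correlation with two-sided p and a confidence interval.

    The CI is Fisher-z by default (``atanh(r) ± z_{1-alpha/2}/sqrt(n-3)``);
    ``ci_method="bootstrap"`` uses a percentile interval over ``B`` row
    resamples (requires a seeded ``rng``).  Incomplete pairs are dropped.
    """
    x, y = _complete_pairs(x, y)
    n = x.size
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidParameterError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if ci_method == "fisher":
        if abs(r) >= 1.0:  # degenerate: Fisher z infinite
            lo = hi = r
        else:
            zcrit = sps.norm.ppf(1 - alpha / 2)
            z = np.arctanh(r)
            half = zcrit / np.sqrt(n - 3)
            lo, hi = np.tanh(z - half), np.tanh(z + half)
    elif ci_method == "bootstrap":
        if rng is None:
            raise InvalidParameterError("bootstrap CI requires a seeded rng")
        rs = []
        while len(rs) < B:
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            if np.ptp(xb) == 0 or np.ptp(yb) == 0:
                continue
            rs.append(np.corrcoef(xb, yb)[0, 1])
        lo, hi = np.percentile(rs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        raise InvalidParameterError(f"unknown ci_method {ci_method!r}")
    return PearsonResult(
        r=r, ci_low=float(lo), ci_high=float(hi), p_value=float(p), n=int(n),
        ci_method=ci_method,
    )


def icc_two_way(ratings, kind: str = "agreement") -> IccResult:
    """Two-way single-measurement intraclass correlation from mean squares.

    ``ratings`` is an (n_subjects, k_raters) array with no missing cells
    (complete cases only; here the two "raters" are the two test settings).
    ``kind="agreement"`` gives the two-way random-effects absolute-agreement
    form ICC(2,1); ``kind="consistency"`` gives ICC(3,1).  Negative estimates
    are returned as computed and flagged.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("ratings must be an n x k array with k >= 2")
    if np.isnan(x).any():
        raise ValidationError("missing cells not allowed; pass complete cases only")
    n, k = x.shape
    if n < 5:
        raise InsufficientDataError(f"need >= 5 subjects, got {n}")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))

    if kind == "agreement":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif kind == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise InvalidParameterError(f"unknown ICC kind {kind!r}")
    if denom == 0:
        raise InvalidParameterError("ICC undefined: zero denominator (no variance)")
    icc = float((msr - mse) / denom)
    return IccResult(icc=icc, kind=kind, n=int(n), negative=icc < 0)


def steiger_dependent_corr(r_jk: float, r_jh: float, r_kh: float, n: int) -> SteigerResult:
    """Williams–Steiger t test for two dependent correlations sharing variable j.

    Tests H0: rho_jk = rho_jh given that variables k and h correlate r_kh in
    the same sample of size n.  The statistic is Williams' t with n-3 degrees
    of freedom,

        t = (r_jk - r_jh) * sqrt( (n-1)(1+r_kh) /
              ( 2 |R| (n-1)/(n-3) + rbar^2 (1-r_kh)^3 ) )

    with ``|R| = 1 - r_jk^2 - r_jh^2 - r_kh^2 + 2 r_jk r_jh r_kh`` the
    determinant of the implied 3x3 correlation matrix and ``rbar`` the mean of
    the two compared correlations.
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 <= r <= 1.0:
            raise InvalidParameterError(f"{name}={r} outside [-1, 1]")
    if n <= 3:
        raise InsufficientDataError(f"need n > 3, got {n}")
    det = 1 - r_jk**2 - r_jh**2 - r_kh**2 + 2 * r_jk * r_jh * r_kh
    if det <= 0:
        raise InvalidParameterError(
            f"implied correlation matrix not positive definite (|R|={det:.3g})"
        )
    rbar = (r_jk + r_jh) / 2.0
    denom = 2 * det * (n - 1) / (n - 3) + rbar**2 * (1 - r_kh) ** 3
    t = (r_jk - r_jh) * np.sqrt((n - 1) * (1 + r_kh) / denom)
    df = n - 3
    p = 2 * sps.t.sf(abs(t), df)
    return SteigerResult(
        statistic=float(t), df=int(df), p_value=float(p),
        r_jk=float(r_jk), r_jh=float(r_jh), r_kh=float(r_kh), n=int(n),
    )


def bootstrap_corr_diff(
    table: pd.DataFrame,
    pair_a: tuple,
    pair_b: tuple,
    B: int = 1000,
    rng=None,
    alpha: float = 0.05,
    max_redraws: int = 1000,
) -> BootstrapDiffResult:
    """Bootstrap CI for the difference between two correlation coefficients.

    Rows complete on all four columns are resampled with replacement ``B``
    times; each resample contributes ``r(pair_a) - r(pair_b)``.  Reported are
    the mean difference and the 2.5/97.5 percentile CI; the difference is
    flagged significant when the CI excludes zero.  A resample with a constant
    column is redrawn (counted; capped at ``max_redraws`` extra draws).
    """
    if B < 100:
        raise InvalidParameterError(f"B must be >= 100, got {B}")
    if rng is None:
        raise InvalidParameterError("bootstrap requires a seeded rng")
    cols = list(dict.fromkeys([*pair_a, *pair_b]))
    data = table[cols].astype(float).dropna()
    n = len(data)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete rows, got {n}")
    arr = data.to_numpy()
    col_idx = {c: i for i, c in enumerate(cols)}
    ia = (col_idx[pair_a[0]], col_idx[pair_a[1]])
    ib = (col_idx[pair_b[0]], col_idx[pair_b[1]])

    def corr(a, i, j):
        return np.corrcoef(a[:, i], a[:, j])[0, 1]

    observed = corr(arr, *ia) - corr(arr, *ib)

    diffs = np.empty(B)
    redraws = 0
    b = 0
    while b < B:
        sub = arr[rng.integers(0, n, n)]
        if any(np.ptp(sub[:, i]) == 0 for i in range(sub.shape[1])):
            redraws += 1
            if redraws > max_redraws:
                raise ValidationError("too many degenerate bootstrap resamples")
            continue
        diffs[b] = corr(sub, *ia) - corr(sub, *ib)
        b += 1
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapDiffResult(
        observed_diff=float(observed),
        mean_diff=float(diffs.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        B=int(B),
        n=int(n),
        significant=bool(not (lo <= 0.0 <= hi)),
        n_redrawn=int(redraws),
    )


def chi_square_2x2(counts, yates: bool = False) -> Chi2Result:
    """Pearson chi-square test on a 2x2 table of counts (df = 1).

    No continuity correction by default; set ``yates=True`` to apply it.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"counts must be 2x2, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.rint(t)):
        raise ValidationError("counts must be non-negative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValidationError("chi-square undefined: zero margin")
    stat, p, df, _ = sps.chi2_contingency(t, correction=yates)
    return Chi2Result(statistic=float(stat), df=int(df), p_value=float(p))


def residualize(y, covariates) -> np.ndarray:
    """OLS residuals of y on an intercept plus covariates (complete cases required).

    Correlating two residualized variables gives the partial correlation
    controlling for the covariates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValidationError("y and covariates must have matching length")
    if np.isnan(y).any() or np.isnan(X).any():
        raise ValidationError("missing values not allowed; pass complete cases")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("rank-deficient design matrix")
    return np.asarray(sm.OLS(y, design).fit().resid)


def partial_corr(x, y, covariates, alpha: float = 0.05) -> PearsonResult:
    """Partial correlation of x and y controlling for covariates, via residualization."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    mask = np.isfinite(x) & np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    return pearson_with_ci(
        residualize(x[mask], C[mask]), residualize(y[mask], C[mask]), alpha=alpha
    )


def simulate_retest_recovery(rho: float, n: int, replicates: int, rng) -> float:
    """Mean sample Pearson r of bivariate-normal paired data.

    Draws ``replicates`` independent samples of ``n`` pairs with population
    correlation ``rho`` and returns the mean sample correlation — the parameter
    recovery harness used to check the analysis chain against its generating
    values.
    """
    if not -1.0 < rho < 1.0:
        raise InvalidParameterError(f"rho must be in (-1, 1), got {rho}")
    x = rng.standard_normal((replicates, n))
    e = rng.standard_normal((replicates, n))
    y = rho * x + np.sqrt(1 - rho**2) * e
    xm = x - x.mean(axis=1, keepdims=True)
    ym = y - y.mean(axis=1, keepdims=True)
    rs = (xm * ym).sum(axis=1) / np.sqrt((xm**2).sum(axis=1) * (ym**2).sum(axis=1))
    return float(rs.mean())
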