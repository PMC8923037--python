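"""ROI summaries and cohort statistics.

Summaries (mean, median, histogram over a robust percentile range) are
computed per tissue region of interest.  Group comparisons use the classic
pooled-variance two-sample t-test (Welch optional) and the paired t-test.
Associations with clinical covariates use a partial Spearman correlation:
values and covariates are rank-transformed (midranks for ties), the ranks
of x and y are residualized on the ranked covariates by linear regression,
and the product-moment correlation of the residuals is reported with a
two-sided p-value from the t approximation on n - 2 - n_covariates degrees
of freedom.  A Bonferroni-adjusted significance threshold is available for
post-hoc reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ROISummary",
    "TTestResult",
    "roi_summary",
    "two_sample_t",
    "spearman_partial",
    "bonferroni_threshold",
    "cohort_ttests",
    "cohort_partial_spearman",
]


@dataclass
class ROISummary:
    roi_label: str
    n_voxels: int
    mean: float
    median: float
    hist_counts: np.ndarray
    bin_edges: np.ndarray


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def roi_summary(
    values_map: np.ndarray,
    mask: np.ndarray,
    label: str = "ROI",
    bins: int = 64,
    hist_range: Optional[tuple[float, float]] = None,
) -> ROISummary:
    """Mean, median and histogram of a map over the valid voxels of a mask.

    Invalid (NaN) voxels are excluded; an empty effective mask raises with
    the ROI named.  The default histogram uses ``bins`` uniform bins over
    the robust 1st-99th percentile range of the ROI values.
    """
    values_map = np.asarray(values_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = values_map[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"ROI {label!r}: no valid voxels under the mask")
    if hist_range is None:
        lo, hi = np.percentile(vals, [1, 99])
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        hist_range = (float(lo), float(hi))
    counts, edges = np.histogram(vals, bins=bins, range=hist_range)
    return ROISummary(
        roi_label=label,
        n_voxels=int(vals.size),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        hist_counts=counts,
        bin_edges=edges,
    )


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    welch: bool = False,
) -> TTestResult:
    """Two-sample (pooled-variance by default, Welch optional) or paired t-test.

    Two-sided p-value.  A paired test with zero-variance differences raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if paired:
        if x.size != y.size:
            raise ValueError("paired test requires equal-length samples")
        d = x - y
        if np.var(d, ddof=1) == 0:
            raise ValueError("paired differences have zero variance")
        res = sps.ttest_rel(x, y)
        return TTestResult(float(res.statistic), float(x.size - 1), float(res.pvalue))
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = float(res.df)
    return TTestResult(float(res.statistic), df, float(res.pvalue))


def spearman_partial(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[np.ndarray] = None,
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    Ranks (midranks for ties) of x, y and each covariate column are formed;
    the x and y ranks are residualized on an intercept plus the ranked
    covariates by least squares; rho is the Pearson correlation of the
    residuals.  With no covariates this equals the ordinary Spearman rho.
    p is two-sided from t = rho*sqrt(df/(1-rho^2)), df = n - 2 - n_cov.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match x/y length")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)) or np.any(~np.isfinite(cov)):
        raise ValueError("missing values are not allowed in used rows")
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, covariates={k})")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant x or y")

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    design = np.column_stack([np.ones(n)] + [sps.rankdata(cov[:, j]) for j in range(k)])
    beta_x, *_ = np.linalg.lstsq(design, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    denom = np.sqrt(np.sum(ex**2) * np.sum(ey**2))
    if denom == 0:
        raise ValueError("residual ranks are constant; correlation undefined")
    rho = float(np.sum(ex * ey) / denom)
    df = n - 2 - k
    rho_c = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return rho, p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level alpha/m (exact value).

    Round to 4 decimals for reporting (e.g. 0.05/38 -> 0.0013).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def cohort_ttests(
    table: pd.DataFrame,
    value_cols: Sequence[str],
    group_col: str = "group",
    groups: tuple[str, str] = ("patient", "control"),
    welch: bool = False,
) -> pd.DataFrame:
    """Two-sample t-tests of each value column between two cohort groups."""
    rows = []
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    for col in value_cols:
        x = g1[col].dropna().to_numpy()
        y = g2[col].dropna().to_numpy()
        res = two_sample_t(x, y, welch=welch)
        rows.append(
            {
                "variable": col,
                "group_1": groups[0],
                "group_2": groups[1],
                "n_1": x.size,
                "n_2": y.size,
                "mean_1": x.mean(),
                "mean_2": y.mean(),
                "t": res.t,
                "df": res.df,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def cohort_partial_spearman(
    table: pd.DataFrame,
    x_cols: Sequence[str],
    y_cols: Sequence[str],
    covariate_cols: Sequence[str] = ("age", "sex", "education"),
) -> pd.DataFrame:
    """Partial Spearman correlations of every (x, y) column pair with the
    given covariates, using complete rows only."""
    rows = []
    for xc in x_cols:
        for yc in y_cols:
            used = table[[xc, yc, *covariate_cols]].dropna()
            rho, p = spearman_partial(
                used[xc].to_numpy(),
                used[yc].to_numpy(),
                used[list(covariate_cols)].to_numpy(),
            )
            rows.append({"x": xc, "y": yc, "n": len(used), "rho": rho, "p": p})
    return pd.DataFrame(rows)
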