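"""Regional group-difference statistics, FDR correction, behavior correlations.

Per-region T maps come from ordinary least squares of regional MS on a group
indicator plus nuisance covariates (age, sex, education); p-values are
Benjamini-Hochberg adjusted across regions in a single family. Group is coded
case=1, control=0, so negative T means lower MS in cases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from mstrans.morphometry import GROUP_CASE, GROUP_CONTROL

DEFAULT_COVARIATES = ("age", "sex", "education")


@dataclass
class BehaviorCorrelation:
    """Partial correlation between two subject-level variables."""

    r: float
    p: float
    n_effective: int
    covariates: tuple[str, ...]


def _encode(series: pd.Series) -> np.ndarray:
    """Numeric passthrough; categories become 0..k-1 indicator columns-1."""
    if series.dtype.kind in "OUSb" or isinstance(
        series.dtype, pd.CategoricalDtype
    ):
        codes, _ = pd.factorize(series)
        return codes.astype(float)
    return series.to_numpy(dtype=float)


def build_design(
    meta: pd.DataFrame, covariates: tuple[str, ...] = DEFAULT_COVARIATES
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [intercept, group(case=1), covariates...]."""
    groups = meta["group"].astype(str)
    bad = set(groups) - {GROUP_CASE, GROUP_CONTROL}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    g = (groups == GROUP_CASE).to_numpy(dtype=float)
    cols = [np.ones(len(meta)), g]
    names = ["intercept", "group"]
    for cov in covariates:
        cols.append(_encode(meta[cov]))
        names.append(cov)
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify a collinear column by leave-one-out rank
        for j in range(design.shape[1]):
            sub = np.delete(design, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                raise ValueError(f"rank-deficient design: column {names[j]!r}")
        raise ValueError("rank-deficient design")
    return design, names


def tmap(
    regional: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Per-region OLS group contrast with covariate adjustment.

    Parameters
    ----------
    regional
        Subjects x regions regional-MS table (index: subject_id).
    meta
        Per-subject metadata aligned to ``regional`` by subject_id.
    covariates
        Nuisance covariate column names; may be empty.

    Returns
    -------
    DataFrame indexed by region with columns ``T, p, q, direction``.
    """
    meta = meta.set_index(meta["subject_id"].astype(str)).loc[
        regional.index.astype(str)
    ]
    ncase = (meta["group"].astype(str) == GROUP_CASE).sum()
    nctrl = (meta["group"].astype(str) == GROUP_CONTROL).sum()
    if min(ncase, nctrl) < 2:
        raise ValueError("need >=2 subjects per group")
    design, _ = build_design(meta, covariates)
    y = regional.to_numpy(dtype=float)
    n, p = design.shape
    dof = n - p
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta[1] / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    q = fdr_bh(pvals)
    return pd.DataFrame(
        {
            "T": t,
            "p": pvals,
            "q": q,
            "direction": np.sign(t),
        },
        index=pd.Index(regional.columns, name="region_id"),
    )


def fdr_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def mean_ms_subset(regional: pd.DataFrame, regions: list) -> pd.Series:
    """Per-subject unweighted mean of regional MS over ``regions``."""
    if len(regions) == 0:
        raise ValueError("empty region list")
    missing = [r for r in regions if r not in regional.columns]
    if missing:
        raise ValueError(f"unknown region ids: {missing}")
    return regional[list(regions)].mean(axis=1)


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    covariate_names: tuple[str, ...] = (),
) -> BehaviorCorrelation:
    """Pearson correlation of OLS residuals of x and y on the covariates.

    Missing entries (NaN in x, y or any covariate) are dropped; the t test
    uses n - 2 - k degrees of freedom for k covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        z = np.empty((x.size, 0))
    else:
        z = np.asarray(covariates, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(z).any(axis=1))
    x, y, z = x[keep], y[keep], z[keep]
    n, k = x.size, z.shape[1]
    if n <= k + 2:
        raise ValueError(f"n_effective={n} too small for k={k} covariates")
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), dof))
    return BehaviorCorrelation(
        r=r, p=p, n_effective=n, covariates=tuple(covariate_names)
    )


def pooled_t_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Pooled-variance two-sample t and two-sided p from group summaries."""
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = float(2 * stats.t.sf(abs(t), n1 + n2 - 2))
    return float(t), p


def chi2_from_counts(counts1, counts2) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a 2 x k table."""
    table = np.asarray([counts1, counts2], dtype=float)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def group_compare(
    meta: pd.DataFrame,
    continuous: tuple[str, ...] = ("age", "education"),
    categorical: tuple[str, ...] = ("sex",),
) -> pd.DataFrame:
    """Demographics table: pooled two-sample t / Pearson chi-squared per row."""
    groups = meta["group"].astype(str)
    case = meta[groups == GROUP_CASE]
    ctrl = meta[groups == GROUP_CONTROL]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in continuous:
        a = case[col].dropna().to_numpy(dtype=float)
        b = ctrl[col].dropna().to_numpy(dtype=float)
        t, p = pooled_t_from_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        rows.append(
            {
                "variable": col,
                "test": "t",
                "case_summary": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                "control_summary": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                "statistic": t,
                "p": p,
            }
        )
    for col in categorical:
        levels = sorted(meta[col].astype(str).unique())
        c1 = [int((case[col].astype(str) == lv).sum()) for lv in levels]
        c2 = [int((ctrl[col].astype(str) == lv).sum()) for lv in levels]
        chi2, p = chi2_from_counts(c1, c2)
        rows.append(
            {
                "variable": col,
                "test": "chi2",
                "case_summary": "/".join(map(str, c1)),
                "control_summary": "/".join(map(str, c2)),
                "statistic": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
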