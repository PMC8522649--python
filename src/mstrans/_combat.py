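"""Parametric empirical-Bayes location/scale batch adjustment (ComBat).

Operates on a features x samples matrix. Each row is standardized against a
covariate-adjusted grand model, per-batch location (gamma) and scale (delta)
are estimated, shrunk toward their empirical priors (normal prior on gamma,
inverse-gamma moment-matched prior on delta), removed, and the grand
location/scale restored. Biological covariates supplied in ``design`` are
refit into the output so their signal survives harmonization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["combat"]


def _aprior(delta_hat: np.ndarray) -> float:
    m, v = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * v + m**2) / v


def _bprior(delta_hat: np.ndarray) -> float:
    m, v = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * v + m**3) / v


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(sdat, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterate gamma*/delta* to their EB posterior point estimates."""
    n = (~np.isnan(sdat)).sum(axis=1).astype(float)
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat(
    data: np.ndarray,
    batch: np.ndarray,
    design: np.ndarray | None = None,
    eb: bool = True,
) -> np.ndarray:
    """Harmonize ``data`` (features x samples) across ``batch`` labels.

    Parameters
    ----------
    data
        Features x samples matrix (no missing values).
    batch
        Length-``n_samples`` array of batch labels.
    design
        Optional samples x k matrix of biological covariates to preserve
        (no intercept column; it is added internally via batch indicators).
    eb
        Shrink batch parameters by empirical Bayes (parametric priors).

    Returns
    -------
    np.ndarray
        Harmonized matrix, same shape as ``data``.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be 2-D (features x samples)")
    n_feat, n_samp = data.shape
    batch = np.asarray(batch)
    if batch.shape[0] != n_samp:
        raise ValueError("batch length must equal number of samples")

    levels, batch_idx = np.unique(batch, return_inverse=True)
    n_batch = len(levels)
    if n_batch == 1:
        return data.copy()
    counts = np.bincount(batch_idx)
    if counts.min() < 2:
        small = levels[counts < 2]
        raise ValueError(f"batches with <2 samples: {list(small)}")

    batch_design = np.zeros((n_samp, n_batch))
    batch_design[np.arange(n_samp), batch_idx] = 1.0
    if design is not None:
        design = np.asarray(design, dtype=float)
        if design.ndim == 1:
            design = design[:, None]
        full = np.hstack([batch_design, design])
    else:
        full = batch_design

    # zero within-batch variance makes delta degenerate
    for b in range(n_batch):
        sub = data[:, batch_idx == b]
        bad = np.where(sub.var(axis=1) == 0)[0]
        if bad.size:
            raise ValueError(
                f"zero-variance feature rows within batch {levels[b]!r}: "
                f"{bad[:10].tolist()}"
            )

    B_hat, *_ = np.linalg.lstsq(full, data.T, rcond=None)
    grand_mean = (counts / n_samp) @ B_hat[:n_batch]
    var_pooled = ((data - (full @ B_hat).T) ** 2).mean(axis=1)
    if np.any(var_pooled == 0):
        raise ValueError("zero pooled residual variance in some feature rows")

    stand_mean = np.outer(grand_mean, np.ones(n_samp))
    if design is not None:
        stand_mean += (design @ B_hat[n_batch:]).T
    sdat = (data - stand_mean) / np.sqrt(var_pooled)[:, None]

    gamma_hat = np.vstack(
        [sdat[:, batch_idx == b].mean(axis=1) for b in range(n_batch)]
    )
    delta_hat = np.vstack(
        [sdat[:, batch_idx == b].var(axis=1, ddof=1) for b in range(n_batch)]
    )

    if eb:
        gamma_bar = gamma_hat.mean(axis=1)
        t2 = gamma_hat.var(axis=1, ddof=1)
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for b in range(n_batch):
            a, bb = _aprior(delta_hat[b]), _bprior(delta_hat[b])
            g, d = _it_sol(
                sdat[:, batch_idx == b],
                gamma_hat[b],
                delta_hat[b],
                gamma_bar[b],
                t2[b],
                a,
                bb,
            )
            gamma_star[b], delta_star[b] = g, d
    else:
        gamma_star, delta_star = gamma_hat, delta_hat

    adj = sdat.copy()
    for b in range(n_batch):
        sel = batch_idx == b
        adj[:, sel] = (adj[:, sel] - gamma_star[b][:, None]) / np.sqrt(
            delta_star[b]
        )[:, None]
    return adj * np.sqrt(var_pooled)[:, None] + stand_mean
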