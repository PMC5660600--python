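"""Numerical primitives used throughout the package.

Pairwise-complete Pearson correlation (row-vs-row and all-pairs), the
Gaussian-KDE mode used for centering, and a Benjamini-Hochberg wrapper.
"""
from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

_EPS = 1e-12


def paired_pearson(
    X: np.ndarray, Y: np.ndarray, min_obs: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise pairwise-complete Pearson correlation.

    ``X`` and ``Y`` are (k, n) arrays; row i of the result is the Pearson
    correlation between ``X[i]`` and ``Y[i]`` over samples where both are
    finite.  Rows with fewer than ``min_obs`` complete pairs, or with zero
    variance on either side, yield NaN.

    Returns
    -------
    (r, n_obs) : correlations (k,) and complete-pair counts (k,)
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("X and Y must have the same shape")
    mask = np.isfinite(X) & np.isfinite(Y)
    n = mask.sum(axis=1)
    safe_n = np.maximum(n, 1)
    Xm = np.where(mask, X, 0.0)
    Ym = np.where(mask, Y, 0.0)
    mx = Xm.sum(axis=1) / safe_n
    my = Ym.sum(axis=1) / safe_n
    Xc = np.where(mask, X - mx[:, None], 0.0)
    Yc = np.where(mask, Y - my[:, None], 0.0)
    cov = (Xc * Yc).sum(axis=1)
    vx = (Xc * Xc).sum(axis=1)
    vy = (Yc * Yc).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(vx * vy)
    bad = (n < min_obs) | (vx <= _EPS) | (vy <= _EPS)
    r = np.where(bad, np.nan, r)
    return r, n.astype(int)


def pairwise_pearson(
    X: np.ndarray, min_obs: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """All unordered row pairs, pairwise-complete Pearson, condensed form.

    Returns the upper-triangle (``scipy.spatial.distance.squareform`` order)
    of the correlation matrix together with complete-pair counts.  Uses
    masked matrix products so the cost is a handful of (genes x genes)
    matmuls rather than a Python loop over C(genes, 2) pairs.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-d array with at least two rows")
    # row-centering is a no-op for Pearson but keeps the one-pass sums small
    with np.errstate(invalid="ignore"):
        X = X - np.nanmean(X, axis=1, keepdims=True)
    mask = np.isfinite(X)
    A = np.where(mask, X, 0.0)
    M = mask.astype(float)
    n = M @ M.T
    S1 = A @ M.T          # S1[i, j] = sum of x_i over the joint mask
    S2 = (A * A) @ M.T
    P = A @ A.T
    cov = n * P - S1 * S1.T
    var_i = n * S2 - S1**2       # variance term of row i against mask j
    denom2 = var_i * var_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cov / np.sqrt(denom2)
    bad = (n < min_obs) | (var_i <= _EPS) | (var_i.T <= _EPS)
    r[bad] = np.nan
    iu = np.triu_indices(X.shape[0], k=1)
    return r[iu], n[iu].astype(int)


def condensed_index(i: np.ndarray, j: np.ndarray, n: int) -> np.ndarray:
    """Index into the condensed upper triangle for pairs (i, j), i < j."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    if np.any(i >= j):
        raise ValueError("requires i < j")
    return i * (2 * n - i - 3) // 2 + j - 1


def kde_mode(x: np.ndarray, grid_size: int = 512) -> float:
    """Mode of a Gaussian kernel density estimate (Silverman bandwidth).

    Evaluated on a dense grid spanning the data plus three bandwidths on
    either side; a (near-)constant input returns the constant itself.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("no finite values")
    if x.size == 1 or np.ptp(x) < 1e-12:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    h = kde.factor * x.std(ddof=1)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
    return float(grid[np.argmax(kde(grid))])


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaN entries stay NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def slope_f_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, int]:
    """Simple OLS of y on x with intercept; F-test of the slope.

    Returns (slope, F, p, n) over jointly finite entries.  The F statistic
    compares the one-predictor model against the intercept-only model and,
    with a single predictor, equals the squared slope t statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    xc = x[ok] - x[ok].mean()
    yc = y[ok] - y[ok].mean()
    sxx = float(xc @ xc)
    if sxx <= _EPS:
        raise ValueError("constant predictor")
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    rss = float(resid @ resid)
    tss = float(yc @ yc)
    df = n - 2
    if rss <= _EPS * max(tss, 1.0):
        return beta, np.inf, 0.0, n
    f = (tss - rss) / (rss / df)
    p = float(stats.f.sf(f, 1, df))
    return beta, float(f), p, n
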