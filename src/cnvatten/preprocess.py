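"""Normalisation and cohort preprocessing.

Low-expression filtering on counts, proteome coverage, linear removal of
clinical/technical confounders, presence filtering of sparse proteins and
KDE-mode centering.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._stats import kde_mode
from .containers import OmicsMatrix, validate_covariates

log = logging.getLogger(__name__)


def cpm_filter_log(counts: pd.DataFrame) -> OmicsMatrix:
    """Filter lowly expressed genes and return log2 counts-per-million.

    CPM_ij = counts_ij / library_size_j * 1e6.  Genes whose mean CPM across
    samples is <= 1 are removed; survivors are returned as log2(CPM + 0.5).
    """
    arr = counts.to_numpy(dtype=float)
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("counts must be finite and nonnegative")
    libsize = arr.sum(axis=0)
    zero = np.flatnonzero(libsize <= 0)
    if zero.size:
        raise ValueError(f"zero library size for sample {counts.columns[zero[0]]!r}")
    cpm = arr / libsize[None, :] * 1e6
    keep = cpm.mean(axis=1) > 1.0
    if not keep.any():
        raise ValueError("all genes fall below the mean-CPM threshold")
    logcpm = np.log2(cpm[keep] + 0.5)
    return OmicsMatrix(
        pd.DataFrame(logcpm, index=counts.index[keep], columns=counts.columns),
        "mrna",
    )


def coverage_jaccard(expressed: set, measured: set) -> float:
    """Jaccard index |A & B| / |A | B| between expressed and measured genes."""
    union = set(expressed) | set(measured)
    if not union:
        raise ValueError("both gene sets are empty")
    return len(set(expressed) & set(measured)) / len(union)


def _design_matrix(cov: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + continuous columns + one-hot (drop-first) categoricals."""
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for col in cov.columns:
        series = cov[col]
        if pd.api.types.is_numeric_dtype(series):
            cols.append(series.to_numpy(dtype=float))
            names.append(col)
        else:
            levels = sorted(series.dropna().unique())
            if len(levels) < 2:
                log.warning("covariate %r has a single level; dropped", col)
                continue
            for level in levels[1:]:
                cols.append((series == level).to_numpy(dtype=float))
                names.append(f"{col}[{level}]")
    return np.column_stack(cols), names


def regress_out_covariates(m: OmicsMatrix, cov: pd.DataFrame) -> OmicsMatrix:
    """Remove linear covariate effects gene by gene.

    For each gene, OLS of its values on the covariate design (intercept,
    continuous age, one-hot categoricals); the corrected value is the
    residual plus the fitted intercept, so gene-level means are retained.
    Missing entries stay missing and are excluded from each fit; genes with
    fewer complete observations than design columns + 2 are left
    uncorrected (logged).
    """
    validate_covariates(cov)
    missing_samples = [s for s in m.sample_ids if s not in cov.index]
    if missing_samples:
        raise ValueError(f"samples missing from covariates: {missing_samples[:5]}")
    cov = cov.loc[m.sample_ids]
    X, _ = _design_matrix(cov)
    k = X.shape[1]
    Y = m.values.to_numpy(dtype=float)
    out = Y.copy()

    finite = np.isfinite(Y)
    full = finite.all(axis=1)
    if full.any():
        # shared least squares for genes with complete data
        pinv = np.linalg.pinv(X)
        B = pinv @ Y[full].T                     # (k, n_full)
        fitted = X @ B
        out[full] = (Y[full].T - fitted + B[0][None, :]).T
    n_skipped = 0
    for i in np.flatnonzero(~full):
        obs = finite[i]
        if obs.sum() < k + 2:
            n_skipped += 1
            continue
        Xi = X[obs]
        yi = Y[i, obs]
        beta, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
        out[i, obs] = yi - Xi @ beta + beta[0]
    if n_skipped:
        log.warning("%d genes left uncorrected (too few complete observations)", n_skipped)
    return OmicsMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), m.level
    )


def presence_filter(m: OmicsMatrix, min_fraction: float = 0.5) -> OmicsMatrix:
    """Keep genes measured in at least ``min_fraction`` of the samples."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must lie in (0, 1]")
    frac = m.values.notna().mean(axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        raise ValueError("presence filter removed every gene")
    return OmicsMatrix(m.values.loc[keep], m.level)


def kde_center(m: OmicsMatrix, min_obs: int = 5) -> OmicsMatrix:
    """Center each gene by the mode of a Gaussian KDE of its values.

    Unlike mean-centering this puts the bulk of a skewed or contaminated
    distribution at zero.  Requires >= ``min_obs`` finite values per gene.
    """
    Y = m.values.to_numpy(dtype=float)
    out = Y.copy()
    for i in range(Y.shape[0]):
        x = Y[i][np.isfinite(Y[i])]
        if x.size < min_obs:
            raise ValueError(
                f"gene {m.values.index[i]!r} has fewer than {min_obs} values"
            )
        out[i] = Y[i] - kde_mode(x)
    return OmicsMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns), m.level
    )
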