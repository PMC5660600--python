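"""Attenuation-potential expression signature and drug-response association.

The per-sample attenuation potential is correlated with each gene's
expression to yield a signature; new samples (e.g. cell lines) are scored
by correlating their expression profile with the signature; the
signature's discriminative power is benchmarked with repeated 70/30
logistic classification; scored cell lines are regressed against drug
response (AUC) one compound at a time.
"""
from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler

from ._stats import bh_fdr, paired_pearson, slope_f_test
from .containers import OmicsMatrix

log = logging.getLogger(__name__)


def build_signature(mrna: OmicsMatrix, potential: pd.Series) -> pd.Series:
    """Per-gene Pearson r between expression and sample attenuation potential."""
    shared = [s for s in mrna.sample_ids if s in potential.index]
    if len(shared) < 20:
        raise ValueError(f"need >= 20 samples with both values, got {len(shared)}")
    E = mrna.values[shared].to_numpy(dtype=float)
    pot = potential.loc[shared].to_numpy(dtype=float)
    r, _ = paired_pearson(E, np.broadcast_to(pot, E.shape), min_obs=3)
    return pd.Series(r, index=mrna.values.index, name="r")


def score_samples(signature: pd.Series, expression: OmicsMatrix) -> pd.Series:
    """Predicted attenuation potential: per-sample Pearson r with the signature.

    Computed across genes shared between the signature and the expression
    matrix; requires >= 50 shared genes.  Pearson invariance makes the
    score robust to per-sample affine scaling of expression.
    """
    sig = signature.dropna()
    shared = [g for g in expression.gene_ids if g in sig.index]
    if len(shared) < 50:
        raise ValueError(f"only {len(shared)} genes shared with the signature (< 50)")
    E = expression.values.loc[shared].to_numpy(dtype=float).T  # samples x genes
    s = sig.loc[shared].to_numpy(dtype=float)
    r, _ = paired_pearson(E, np.broadcast_to(s, E.shape), min_obs=3)
    return pd.Series(r, index=expression.values.columns, name="predicted_potential")


def benchmark_signature(
    expression: OmicsMatrix,
    labels: pd.Series,
    n_splits: int = 1000,
    test_fraction: float = 0.3,
    seed: int = 0,
    fdr_threshold: float = 0.05,
    Cs: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
) -> tuple[float, float, np.ndarray]:
    """Cross-validated logistic benchmark of strong vs weak attenuation.

    For each of ``n_splits`` stratified 70/30 splits: ANOVA F feature
    selection on the training samples with BH FDR (< ``fdr_threshold``
    kept), then an L2 logistic model with its regularisation strength
    chosen by 5-fold stratified cross-validation, evaluated by AROC on the
    held-out samples.  Splits where no feature survives selection fall
    back to an uninformative model (AROC 0.5, counted in the log).

    Returns (mean AROC, sd, per-split values).
    """
    y = pd.Series(labels).loc[expression.sample_ids]
    classes = y.unique()
    if len(classes) != 2:
        raise ValueError("labels must have exactly two classes")
    counts = y.value_counts()
    if counts.min() < 10:
        raise ValueError("both classes need >= 10 samples")
    X = expression.values.to_numpy(dtype=float).T  # samples x genes
    yb = (y == sorted(classes)[1]).to_numpy(dtype=int)

    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, test_size=test_fraction, random_state=seed
    )
    aucs = np.empty(n_splits)
    n_empty = 0
    for k, (tr, te) in enumerate(splitter.split(X, yb)):
        fvals, pvals = f_classif(X[tr], yb[tr])
        keep = bh_fdr(pvals) < fdr_threshold
        if not keep.any():
            n_empty += 1
            aucs[k] = 0.5
            continue
        scaler = StandardScaler().fit(X[tr][:, keep])
        Xtr = scaler.transform(X[tr][:, keep])
        Xte = scaler.transform(X[te][:, keep])
        with warnings.catch_warnings():
            # sklearn 1.9 emits FutureWarnings about upcoming API defaults
            warnings.simplefilter("ignore", FutureWarning)
            model = LogisticRegressionCV(  # ridge (L2) penalty, the default
                Cs=list(Cs),
                cv=StratifiedKFold(5),
                max_iter=2000,
                random_state=seed,
            ).fit(Xtr, yb[tr])
        aucs[k] = roc_auc_score(yb[te], model.predict_proba(Xte)[:, 1])
    if n_empty:
        log.info("%d/%d splits had no surviving features", n_empty, n_splits)
    return float(aucs.mean()), float(aucs.std(ddof=1)), aucs


def drug_associations(
    predicted_potential: pd.Series,
    drug_auc: pd.DataFrame,
    min_n: int = 20,
) -> pd.DataFrame:
    """Single linear regressions of drug response on predicted potential.

    ``drug_auc`` is drugs x cell lines (area under the dose-response
    curve; higher = more resistant).  Per drug: OLS of AUC on the
    predicted attenuation potential over cell lines with both values,
    two-sided p from the slope F-test, BH FDR across drugs.  A positive
    slope reads as attenuation implying resistance.
    """
    shared = [c for c in drug_auc.columns if c in predicted_potential.index]
    pot = predicted_potential.loc[shared].to_numpy(dtype=float)
    rows = []
    n_skipped = 0
    for drug in drug_auc.index:
        auc = drug_auc.loc[drug, shared].to_numpy(dtype=float)
        ok = np.isfinite(auc) & np.isfinite(pot)
        if ok.sum() < min_n:
            n_skipped += 1
            continue
        try:
            beta, f, p, n = slope_f_test(pot[ok], auc[ok])
        except ValueError:
            n_skipped += 1
            continue
        r = float(np.corrcoef(pot[ok], auc[ok])[0, 1])
        rows.append({"drug": drug, "slope": beta, "r": r, "p": p, "n": n})
    if n_skipped:
        log.info("%d drugs skipped (fewer than %d cell lines)", n_skipped, min_n)
    if not rows:
        raise ValueError("no drug with enough cell lines")
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values(["p", "drug"], kind="mergesort").reset_index(drop=True)
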