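"""Per-gene and per-sample dosage attenuation.

The attenuation score of an entity is r(CNV, mRNA) - r(CNV, protein): a
positive score means the dosage signal reaching the transcript is lost at
the protein level, i.e. post-transcriptional buffering.  A two-component
Gaussian mixture on the scores separates attenuated entities (the
component with the larger mean) from the background.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from ._stats import paired_pearson

log = logging.getLogger(__name__)

#: stringent attenuation calls additionally require |score| above this
STRINGENT_SCORE = 0.3


@dataclass
class GmmFitReport:
    """Fit summary of the two-component mixture on attenuation scores."""

    means: np.ndarray
    variances: np.ndarray
    weights: np.ndarray
    seed: int
    converged: bool
    n_components: int = 2


def feature_correlations(
    cnv, mrna, protein, min_obs: int = 15
) -> pd.DataFrame:
    """Per-gene CNV-mRNA and CNV-protein Pearson r plus the attenuation score.

    Genes are intersected across the three levels and correlations computed
    over pairwise-complete samples.  Genes with fewer than ``min_obs``
    complete pairs for either correlation (or zero CNV variance) get NaN
    and are excluded from downstream scoring.
    """
    genes = [g for g in cnv.gene_ids if g in set(mrna.gene_ids) & set(protein.gene_ids)]
    samples = [s for s in cnv.sample_ids if s in set(mrna.sample_ids) & set(protein.sample_ids)]
    if not genes or len(samples) < 3:
        raise ValueError("matrices share too few genes or samples")
    C = cnv.values.loc[genes, samples].to_numpy(dtype=float)
    T = mrna.values.loc[genes, samples].to_numpy(dtype=float)
    P = protein.values.loc[genes, samples].to_numpy(dtype=float)
    r_t, n_t = paired_pearson(C, T, min_obs=min_obs)
    r_p, n_p = paired_pearson(C, P, min_obs=min_obs)
    n_dropped = int(np.isnan(r_t).sum() + np.isnan(r_p).sum())
    if n_dropped:
        log.info("%d correlations missing (low n or zero variance)", n_dropped)
    table = pd.DataFrame(
        {
            "r_cnv_mrna": r_t,
            "r_cnv_protein": r_p,
            "n_obs_mrna": n_t,
            "n_obs_protein": n_p,
            "score": r_t - r_p,
        },
        index=pd.Index(genes, name="entity"),
    )
    return table


def classify_attenuation(
    scores: pd.Series, seed: int = 0
) -> tuple[pd.DataFrame, GmmFitReport]:
    """Two-component Gaussian mixture classification of attenuation scores.

    The component with the larger mean is labelled ``attenuated``; the
    stringent flag additionally requires |score| > 0.3.  Near-constant
    score vectors fall back to a single background cluster.

    Returns a DataFrame (gmm_class, gmm_posterior, stringent_flag) indexed
    like ``scores`` (NaN scores get background / posterior NaN) and the fit
    report.
    """
    scores = pd.Series(scores)
    finite = scores.dropna()
    if len(finite) < 20:
        raise ValueError(f"need >= 20 finite scores, got {len(finite)}")
    out = pd.DataFrame(
        {
            "gmm_class": "background",
            "gmm_posterior": np.nan,
            "stringent_flag": False,
        },
        index=scores.index,
    )
    if finite.std(ddof=0) < 1e-6:
        log.warning("attenuation scores are near-constant; single-cluster fallback")
        report = GmmFitReport(
            means=np.array([finite.mean()]),
            variances=np.array([finite.var(ddof=0)]),
            weights=np.array([1.0]),
            seed=seed,
            converged=True,
            n_components=1,
        )
        out.loc[finite.index, "gmm_posterior"] = 0.0
        return out, report

    x = finite.to_numpy(dtype=float).reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2,
        n_init=10,
        init_params="kmeans",
        tol=1e-6,
        max_iter=500,
        random_state=seed,
    ).fit(x)
    att = int(np.argmax(gm.means_.ravel()))
    posterior = gm.predict_proba(x)[:, att]
    labels = np.where(posterior > 0.5, "attenuated", "background")  # ties -> background
    out.loc[finite.index, "gmm_class"] = labels
    out.loc[finite.index, "gmm_posterior"] = posterior
    out.loc[finite.index, "stringent_flag"] = (labels == "attenuated") & (
        np.abs(finite.to_numpy()) > STRINGENT_SCORE
    )
    report = GmmFitReport(
        means=gm.means_.ravel(),
        variances=gm.covariances_.ravel(),
        weights=gm.weights_.ravel(),
        seed=seed,
        converged=bool(gm.converged_),
    )
    return out, report


def attenuation_table(
    cnv, mrna, protein, min_obs: int = 15, seed: int = 0
) -> tuple[pd.DataFrame, GmmFitReport]:
    """Per-gene correlations plus GMM classification, as one table."""
    table = feature_correlations(cnv, mrna, protein, min_obs=min_obs)
    labels, report = classify_attenuation(table["score"], seed=seed)
    return table.join(labels), report


def sample_attenuation_potential(
    cnv, mrna, protein, min_obs: int = 15, seed: int = 0
) -> tuple[pd.DataFrame, GmmFitReport]:
    """Per-sample attenuation potential: the same statistic across genes.

    For each sample, Pearson r across genes between CNV and mRNA, and CNV
    and protein; the score and GMM classification follow the per-gene
    procedure.  Samples with high attenuation potential buffer dosage
    effects proteome-wide.
    """
    genes = [g for g in cnv.gene_ids if g in set(mrna.gene_ids) & set(protein.gene_ids)]
    samples = [s for s in cnv.sample_ids if s in set(mrna.sample_ids) & set(protein.sample_ids)]
    if len(genes) < 3 or not samples:
        raise ValueError("matrices share too few genes or samples")
    C = cnv.values.loc[genes, samples].to_numpy(dtype=float).T
    T = mrna.values.loc[genes, samples].to_numpy(dtype=float).T
    P = protein.values.loc[genes, samples].to_numpy(dtype=float).T
    r_t, n_t = paired_pearson(C, T, min_obs=min_obs)
    r_p, n_p = paired_pearson(C, P, min_obs=min_obs)
    table = pd.DataFrame(
        {
            "r_cnv_mrna": r_t,
            "r_cnv_protein": r_p,
            "n_obs_mrna": n_t,
            "n_obs_protein": n_p,
            "score": r_t - r_p,
        },
        index=pd.Index(samples, name="entity"),
    )
    labels, report = classify_attenuation(table["score"], seed=seed)
    return table.join(labels), report


def write_attenuation_tsv(table: pd.DataFrame, path) -> None:
    cols = [
        "r_cnv_mrna",
        "r_cnv_protein",
        "n_obs_mrna",
        "n_obs_protein",
        "score",
        "gmm_class",
        "gmm_posterior",
        "stringent_flag",
    ]
    table[[c for c in cols if c in table.columns]].to_csv(
        path, sep="\t", index_label="entity", na_rep="NA"
    )
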