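"""All-pairs abundance correlation and interaction-set ROC evaluation.

Protein complex subunits are strongly co-regulated at the protein level;
pairwise correlation profiles therefore rank known interaction pairs
(complex co-members, high-confidence functional edges, kinase-substrate
edges, co-pathway enzymes) above random pairs, and do so better with
proteomics than with transcriptomics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._stats import condensed_index, pairwise_pearson
from .containers import OmicsMatrix

log = logging.getLogger(__name__)


@dataclass
class PairCorrelationTable:
    """Condensed all-pairs Pearson correlations at one molecular level.

    ``r`` and ``n_obs`` are the upper triangle in row-major (squareform)
    order; index arithmetic via :meth:`pair_index`.
    """

    gene_ids: list[str]
    r: np.ndarray
    n_obs: np.ndarray
    level: str

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.r)

    def pair_index(self, pairs: list[frozenset]) -> np.ndarray:
        """Condensed indices of unordered gene-id pairs."""
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        ii, jj = [], []
        for pair in pairs:
            a, b = tuple(pair)
            i, j = pos[a], pos[b]
            if i > j:
                i, j = j, i
            ii.append(i)
            jj.append(j)
        return condensed_index(np.array(ii), np.array(jj), self.n_genes)

    def to_dataframe(self, max_pairs: int = 2_000_000) -> pd.DataFrame:
        if self.n_pairs > max_pairs:
            raise ValueError(f"{self.n_pairs} pairs exceed max_pairs={max_pairs}")
        iu, ju = np.triu_indices(self.n_genes, k=1)
        genes = np.asarray(self.gene_ids)
        return pd.DataFrame(
            {
                "gene_a": genes[iu],
                "gene_b": genes[ju],
                "r": self.r,
                "n_obs": self.n_obs,
            }
        )


def pairwise_correlations(m: OmicsMatrix, min_obs: int = 15) -> PairCorrelationTable:
    """Pairwise-complete Pearson r for every unordered gene pair."""
    if m.shape[0] < 2:
        raise ValueError("need at least two genes")
    r, n = pairwise_pearson(m.values.to_numpy(dtype=float), min_obs=min_obs)
    return PairCorrelationTable(gene_ids=m.gene_ids, r=r, n_obs=n, level=m.level)


@dataclass
class InteractionSets:
    """Positive interaction-pair collections restricted to a gene universe."""

    complexes: set[frozenset] = field(default_factory=set)
    functional: set[frozenset] = field(default_factory=set)
    signaling: set[frozenset] = field(default_factory=set)
    metabolic: set[frozenset] = field(default_factory=set)

    def as_dict(self) -> dict[str, set[frozenset]]:
        return {
            "complexes": self.complexes,
            "functional": self.functional,
            "signaling": self.signaling,
            "metabolic": self.metabolic,
        }


def _comember_pairs(groups: dict[str, set[str]], universe: set[str]) -> set[frozenset]:
    pairs: set[frozenset] = set()
    for members in groups.values():
        present = sorted(set(members) & universe)
        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                pairs.add(frozenset((a, b)))
    return pairs


def _edge_pairs(edges: pd.DataFrame, universe: set[str]) -> tuple[set[frozenset], int]:
    pairs: set[frozenset] = set()
    n_self = 0
    for a, b in zip(edges["gene_a"], edges["gene_b"]):
        if a == b:
            n_self += 1
            continue
        if a in universe and b in universe:
            pairs.add(frozenset((a, b)))
    return pairs, n_self


def build_interaction_sets(
    complexes: dict[str, set[str]] | None = None,
    functional_edges: pd.DataFrame | None = None,
    signaling_edges: pd.DataFrame | None = None,
    pathways: dict[str, set[str]] | None = None,
    universe: set[str] | None = None,
    functional_min_score: float = 900.0,
) -> InteractionSets:
    """Assemble positive pair sets from the four interaction sources.

    Complex pairs are all unordered co-members (deduplicated across
    complexes); functional pairs keep edges with score >= the confidence
    threshold (STRING-style, default 900); metabolic pairs are co-members
    of any pathway gene set.  All pairs are restricted to ``universe`` and
    self-edges are dropped (counted in the log).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    universe = set(universe)
    out = InteractionSets()
    if complexes:
        out.complexes = _comember_pairs(complexes, universe)
    n_self = 0
    if functional_edges is not None and len(functional_edges):
        edges = functional_edges
        if "score" in edges.columns:
            edges = edges[edges["score"] >= functional_min_score]
        out.functional, s = _edge_pairs(edges, universe)
        n_self += s
    if signaling_edges is not None and len(signaling_edges):
        out.signaling, s = _edge_pairs(signaling_edges, universe)
        n_self += s
    if pathways:
        out.metabolic = _comember_pairs(pathways, universe)
    if n_self:
        log.info("dropped %d self-edges", n_self)
    return out


def interaction_aroc(
    pairs: PairCorrelationTable,
    positives: set[frozenset],
    n_negative_draws: int = 5,
    seed: int = 0,
) -> tuple[float, float, np.ndarray]:
    """AROC of pairwise correlation as a classifier of interaction pairs.

    The positive class is heavily outnumbered, so for each of
    ``n_negative_draws`` draws a random negative set of equal size is
    sampled (without replacement) from non-positive pairs with finite r.
    Returns (mean AROC, sd, per-draw values).
    """
    known = set(pairs.gene_ids)
    positives = [p for p in positives if set(p) <= known]
    if not positives:
        raise ValueError("no positive pair maps into the correlation table")
    pos_idx = pairs.pair_index(sorted(positives, key=sorted))
    finite = np.isfinite(pairs.r)
    pos_idx = pos_idx[finite[pos_idx]]
    if pos_idx.size < 10:
        raise ValueError(f"need >= 10 positives with finite r, got {pos_idx.size}")
    neg_mask = finite.copy()
    neg_mask[pos_idx] = False
    candidates = np.flatnonzero(neg_mask)
    if candidates.size < pos_idx.size:
        raise ValueError("not enough non-positive pairs to sample negatives")
    rng = np.random.default_rng(seed)
    pos_scores = pairs.r[pos_idx]
    aucs = np.empty(n_negative_draws)
    for d in range(n_negative_draws):
        neg_idx = rng.choice(candidates, size=pos_idx.size, replace=False)
        y = np.concatenate((np.ones(pos_idx.size), np.zeros(pos_idx.size)))
        s = np.concatenate((pos_scores, pairs.r[neg_idx]))
        aucs[d] = roc_auc_score(y, s)
    return float(aucs.mean()), float(aucs.std(ddof=1)), aucs
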