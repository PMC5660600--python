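"""Synthetic multi-omics cohorts with known attenuation ground truth.

The generator emulates the statistical structure the analysis assumes:
discrete gene-dosage states propagate linearly to mRNA; protein tracks its
own transcript for pass-through genes but is buffered toward a shared
latent complex abundance for attenuated complex subunits; directed
rate-limiting edges add a partner's dosage signal to a protein; additive
clinical/technical confounders; and missing-at-random protein entries.

Generative model (per gene i, sample j):

    CNV_ij ~ categorical over states {-2,...,2}
    T_ij   = mu_i + a_i * CNV_ij + covariate effects + N(0, sigma_T^2)
    P_ij   = nu_i + mu_i + gamma_ij * (T_ij - mu_i)
             + (1 - gamma_ij) * C_kj + technology effect + N(0, sigma_P^2)

where C_kj ~ N(0, sigma_C^2) is the latent abundance of complex k, shared
by its subunits and independent of every CNV (so buffering strictly lowers
the CNV-protein correlation without creating spurious dosage signal).
A rate-limiting edge (x, y, delta) adds delta * (CNV_xj - mean_j CNV_xj)
to P_yj.  gamma_i = 1 means pass-through; gamma_i < 1 means attenuated.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    OmicsMatrix,
    write_complex_membership,
    write_covariates_tsv,
)

CNV_STATES = np.array([-2, -1, 0, 1, 2])


@dataclass(frozen=True)
class ComplexSpec:
    """A protein complex: member gene indices and per-subunit buffering.

    ``gamma`` entries in [0, 1]: 1 = no buffering (pass-through subunit),
    0 = protein fully decoupled from its own transcript and tied to the
    latent complex abundance.
    """

    members: tuple[int, ...]
    gamma: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.gamma):
            raise ValueError("members and gamma must have equal length")
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate member in complex")
        if any(g < 0 or g > 1 for g in self.gamma):
            raise ValueError("gamma must lie in [0, 1]")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study conditions the pipeline is meant for: a
    282-sample pan-cancer cohort, ~2,000 genes, 30 complexes of 4-10
    subunits with one pass-through (rate-limiting-candidate) subunit each.
    """

    n_samples: int = 282
    n_genes: int = 2000
    cnv_state_probs: tuple[float, ...] = (0.05, 0.2, 0.5, 0.2, 0.05)
    dosage_slope_range: tuple[float, float] = (0.5, 1.5)
    mrna_noise_sd: float = 0.5
    protein_noise_sd: float = 0.5
    complex_noise_sd: float = 1.0
    complexes: list[ComplexSpec] | None = None
    n_complexes: int = 30
    complex_size_range: tuple[int, int] = (4, 10)
    attenuated_gamma: float = 0.2
    regulatory_edges: list[tuple[int, int, float]] = field(default_factory=list)
    covariate_spec: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.1,
            "gender": 0.2,
            "tumour_type": 0.3,
            "technology": 0.5,
        }
    )
    missing_rate: float = 0.1
    # per-sample heterogeneity of buffering strength: a fraction of samples
    # buffer attenuated genes down to `high_potential_gamma`
    high_potential_fraction: float = 0.0
    high_potential_gamma: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        probs = np.asarray(self.cnv_state_probs, dtype=float)
        if probs.size != 5 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("cnv_state_probs must be 5 nonnegative values summing to 1")
        if self.n_samples < 2 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.attenuated_gamma <= 1.0:
            raise ValueError("attenuated_gamma must lie in [0, 1]")
        if not 0.0 <= self.high_potential_fraction <= 1.0:
            raise ValueError("high_potential_fraction must lie in [0, 1]")
        for sd_name in ("mrna_noise_sd", "protein_noise_sd", "complex_noise_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        if self.complexes is not None:
            for k, spec in enumerate(self.complexes):
                for g in spec.members:
                    if not 0 <= g < self.n_genes:
                        raise ValueError(
                            f"complexes[{k}] member {g} outside gene range"
                        )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort, including generative parameters."""

    gamma: np.ndarray                      # per-gene base buffering factor
    attenuated_genes: list[str]            # genes with gamma < 1
    edges: list[tuple[str, str, float]]    # directed rate-limiting effects
    complex_assignments: dict[str, str]    # gene id -> complex id
    high_potential_samples: list[str]
    dosage_slope: np.ndarray | None = None  # per-gene mRNA ~ CNV slope a_i
    baseline: np.ndarray | None = None      # per-gene mRNA baseline mu_i

    def to_json(self, path: str | Path, gene_ids: list[str]) -> None:
        payload = {
            "gamma": {g: float(v) for g, v in zip(gene_ids, self.gamma)},
            "attenuated_genes": sorted(self.attenuated_genes),
            "edges": [[x, y, float(d)] for x, y, d in self.edges],
            "complex_assignments": dict(sorted(self.complex_assignments.items())),
            "high_potential_samples": sorted(self.high_potential_samples),
        }
        if self.dosage_slope is not None:
            payload["dosage_slope"] = {
                g: float(v) for g, v in zip(gene_ids, self.dosage_slope)
            }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class SyntheticDataset:
    cnv: OmicsMatrix
    mrna: OmicsMatrix
    protein: OmicsMatrix
    covariates: pd.DataFrame
    complexes: dict[str, set[str]]
    truth: SyntheticTruth
    config: SimulationConfig


def _default_complexes(config: SimulationConfig, rng: np.random.Generator) -> list[ComplexSpec]:
    """Disjoint complexes over the first genes; first subunit pass-through."""
    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    if sizes.sum() > config.n_genes:
        raise ValueError("complexes do not fit in n_genes; reduce n_complexes")
    specs, start = [], 0
    for s in sizes:
        members = tuple(range(start, start + int(s)))
        gamma = (1.0,) + (config.attenuated_gamma,) * (int(s) - 1)
        specs.append(ComplexSpec(members, gamma))
        start += int(s)
    return specs


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one synthetic cohort; identical configs + seeds give identical data."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_samples

    complexes = config.complexes
    if complexes is None:
        complexes = _default_complexes(config, rng)

    # index -> complex, base gamma
    gamma = np.ones(G)
    complex_of = np.full(G, -1, dtype=int)
    for k, spec in enumerate(complexes):
        for g, gm in zip(spec.members, spec.gamma):
            if complex_of[g] != -1:
                raise ValueError(f"gene {g} assigned to two complexes")
            complex_of[g] = k
            gamma[g] = gm
    for x, y, _ in config.regulatory_edges:
        if not (0 <= x < G and 0 <= y < G):
            raise ValueError(f"regulatory edge ({x}, {y}) outside gene range")
        if x == y:
            raise ValueError("regulatory edge endpoints must be distinct")
        if complex_of[x] == -1 or complex_of[x] != complex_of[y]:
            raise ValueError(
                f"regulatory edge ({x}, {y}) must join members of one complex"
            )

    cnv = rng.choice(CNV_STATES, size=(G, S), p=np.asarray(config.cnv_state_probs))

    mu = rng.normal(8.0, 1.0, size=G)
    slope = rng.uniform(*config.dosage_slope_range, size=G)

    # covariates
    age = rng.normal(60.0, 10.0, size=S)
    gender = rng.choice(["female", "male"], size=S)
    tumour = rng.choice(["BRCA", "HGSC", "COREAD"], size=S, p=[0.4, 0.3, 0.3])
    tech = rng.choice(["isobaric", "labelfree"], size=S, p=[0.6, 0.4])
    eff = config.covariate_spec
    cov_mrna = np.zeros((G, S))
    if eff.get("age", 0.0) > 0:
        z_age = (age - age.mean()) / max(age.std(), 1e-9)
        cov_mrna += rng.normal(0.0, eff["age"], size=G)[:, None] * z_age[None, :]
    if eff.get("gender", 0.0) > 0:
        ind = (gender == "male").astype(float)
        cov_mrna += rng.normal(0.0, eff["gender"], size=G)[:, None] * ind[None, :]
    if eff.get("tumour_type", 0.0) > 0:
        for level in ("HGSC", "COREAD"):
            ind = (tumour == level).astype(float)
            cov_mrna += rng.normal(0.0, eff["tumour_type"], size=G)[:, None] * ind[None, :]

    T = (
        mu[:, None]
        + slope[:, None] * cnv
        + cov_mrna
        + rng.normal(0.0, config.mrna_noise_sd, size=(G, S))
    )

    # latent complex abundances and per-gene/per-sample buffering factors
    C = rng.normal(0.0, config.complex_noise_sd, size=(len(complexes), S))
    if len(complexes):
        Cmat = np.where(complex_of[:, None] >= 0, C[np.maximum(complex_of, 0)], 0.0)
    else:
        Cmat = np.zeros((G, S))
    Gamma = np.tile(gamma[:, None], (1, S))
    hp_flag = rng.random(S) < config.high_potential_fraction
    if hp_flag.any():
        boosted = np.minimum(gamma, config.high_potential_gamma)
        Gamma[:, hp_flag] = np.where(
            (gamma < 1.0)[:, None], boosted[:, None], 1.0
        )

    nu = rng.normal(0.0, 0.5, size=G)
    P = (
        nu[:, None]
        + mu[:, None]
        + Gamma * (T - mu[:, None])
        + (1.0 - Gamma) * Cmat
        + rng.normal(0.0, config.protein_noise_sd, size=(G, S))
    )
    if eff.get("technology", 0.0) > 0:
        ind = (tech == "labelfree").astype(float)
        P += rng.normal(0.0, eff["technology"], size=G)[:, None] * ind[None, :]

    for x, y, delta in config.regulatory_edges:
        P[y] += delta * (cnv[x] - cnv[x].mean())

    if config.missing_rate > 0:
        P = np.where(rng.random((G, S)) < config.missing_rate, np.nan, P)

    gene_ids = [f"G{i:04d}" for i in range(G)]
    sample_ids = [f"S{j:04d}" for j in range(S)]
    as_df = lambda M: pd.DataFrame(M, index=gene_ids, columns=sample_ids)

    covariates = pd.DataFrame(
        {
            "age": np.round(age, 4),
            "gender": gender,
            "tumour_type": tumour,
            "technology": tech,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    complex_sets = {
        f"C{k:03d}": {gene_ids[g] for g in spec.members}
        for k, spec in enumerate(complexes)
    }
    truth = SyntheticTruth(
        gamma=gamma,
        attenuated_genes=[gene_ids[i] for i in np.flatnonzero(gamma < 1.0)],
        edges=[(gene_ids[x], gene_ids[y], d) for x, y, d in config.regulatory_edges],
        complex_assignments={
            gene_ids[g]: f"C{complex_of[g]:03d}"
            for g in np.flatnonzero(complex_of >= 0)
        },
        high_potential_samples=[sample_ids[j] for j in np.flatnonzero(hp_flag)],
        dosage_slope=slope,
        baseline=mu,
    )
    return SyntheticDataset(
        cnv=OmicsMatrix(as_df(cnv.astype(float)), "cnv"),
        mrna=OmicsMatrix(as_df(T), "mrna"),
        protein=OmicsMatrix(as_df(P), "protein"),
        covariates=covariates,
        complexes=complex_sets,
        truth=truth,
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> None:
    """Write cnv/mrna/protein/covariates TSVs, complexes and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.cnv.to_tsv(out / "cnv.tsv")
    dataset.mrna.to_tsv(out / "mrna.tsv")
    dataset.protein.to_tsv(out / "protein.tsv")
    write_covariates_tsv(dataset.covariates, out / "covariates.tsv")
    write_complex_membership(dataset.complexes, out / "complexes.tsv")
    dataset.truth.to_json(out / "truth.json", dataset.cnv.gene_ids)
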