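"""End-to-end driver wiring all analysis stages with deterministic seeds.

Given either a synthetic-cohort request or paths to the input tables, runs
preprocess -> attenuation -> enrichment -> co-regulation -> regulators ->
signature, writes every result table as TSV into the output directory and
returns a manifest (seeds, parameters, stage-by-stage counts).  A rerun
with the identical config reproduces the outputs byte-for-byte.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .attenuation import (
    attenuation_table,
    sample_attenuation_potential,
    write_attenuation_tsv,
)
from .containers import (
    OmicsMatrix,
    read_complex_membership,
    read_covariates_tsv,
)
from .coregulation import (
    build_interaction_sets,
    interaction_aroc,
    pairwise_correlations,
)
from .enrichment import gsea, normalize_scores_for_ranking
from .preprocess import kde_center, presence_filter, regress_out_covariates
from .regulators import (
    annotate_transcript_support,
    enumerate_directed_pairs,
    test_regulatory_pairs,
)
from .signature import benchmark_signature, build_signature
from .simulate import SimulationConfig, simulate_dataset, write_dataset

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Structured configuration of a full run."""

    out_dir: str
    simulate: SimulationConfig | None = None
    inputs: dict[str, str] | None = None  # cnv, mrna, protein, covariates, complexes
    min_obs: int = 15
    presence_min_fraction: float = 0.5
    gmm_seed: int = 0
    gsea_n_perm: int = 200
    roc_negative_draws: int = 5
    fdr_threshold: float = 0.05
    benchmark_splits: int = 50
    seed: int = 0

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must request either simulation or input paths")
        if not 0 < self.presence_min_fraction <= 1:
            raise ValueError("presence_min_fraction must lie in (0, 1]")
        if not 0 < self.fdr_threshold <= 1:
            raise ValueError("fdr_threshold must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(simulate=SimulationConfig(**sim) if sim is not None else None, **raw)
        cfg.validate()
        return cfg


def _load_inputs(paths: dict[str, str]):
    required = ("cnv", "mrna", "protein", "covariates", "complexes")
    for key in required:
        if key not in paths:
            raise PipelineError(f"load: missing input path for {key!r}")
        if not Path(paths[key]).exists():
            raise PipelineError(f"load: file not found: {paths[key]}")
    cnv = OmicsMatrix.from_tsv(paths["cnv"], "cnv")
    mrna = OmicsMatrix.from_tsv(paths["mrna"], "mrna")
    protein = OmicsMatrix.from_tsv(paths["protein"], "protein")
    covariates = read_covariates_tsv(paths["covariates"])
    complexes = read_complex_membership(paths["complexes"])
    return cnv, mrna, protein, covariates, complexes


def run_full_analysis(config: PipelineConfig) -> dict:
    """Execute every stage and write results + manifest under ``out_dir``."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "cnvatten_version": __version__,
        "seed": config.seed,
        "gmm_seed": config.gmm_seed,
        "counts": {},
        "results": {},
    }

    # --- inputs -----------------------------------------------------------
    try:
        if config.simulate is not None:
            dataset = simulate_dataset(config.simulate)
            write_dataset(dataset, out / "data")
            cnv, mrna, protein = dataset.cnv, dataset.mrna, dataset.protein
            covariates, complexes = dataset.covariates, dataset.complexes
            manifest["simulation_seed"] = config.simulate.seed
        else:
            cnv, mrna, protein, covariates, complexes = _load_inputs(config.inputs)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(f"load: {exc}") from exc
    manifest["counts"]["genes_input"] = cnv.shape[0]
    manifest["counts"]["samples"] = cnv.shape[1]

    # --- preprocess -------------------------------------------------------
    try:
        mrna = regress_out_covariates(mrna, covariates)
        protein = regress_out_covariates(protein, covariates)
        protein = presence_filter(protein, config.presence_min_fraction)
        mrna = kde_center(mrna)
        protein = kde_center(protein)
    except Exception as exc:
        raise PipelineError(f"preprocess: {exc}") from exc
    manifest["counts"]["proteins_after_presence_filter"] = protein.shape[0]

    # --- per-gene attenuation --------------------------------------------
    try:
        atten, report = attenuation_table(
            cnv, mrna, protein, min_obs=config.min_obs, seed=config.gmm_seed
        )
        write_attenuation_tsv(atten, out / "attenuation_genes.tsv")
    except Exception as exc:
        raise PipelineError(f"attenuation: {exc}") from exc
    scored = atten["score"].notna()
    n_att = int((atten["gmm_class"] == "attenuated").sum())
    manifest["counts"]["genes_scored"] = int(scored.sum())
    manifest["counts"]["genes_attenuated"] = n_att
    manifest["counts"]["genes_attenuated_stringent"] = int(atten["stringent_flag"].sum())
    manifest["results"]["attenuated_fraction"] = round(n_att / max(scored.sum(), 1), 6)
    manifest["results"]["gmm_converged"] = bool(report.converged)

    # --- enrichment against the complex catalog ---------------------------
    try:
        normalized = normalize_scores_for_ranking(atten.loc[scored, "score"])
        enr = gsea(
            normalized,
            complexes,
            n_perm=config.gsea_n_perm,
            seed=config.seed,
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"enrichment: {exc}") from exc
    manifest["counts"]["gene_sets_tested"] = len(enr)
    manifest["counts"]["gene_sets_fdr5"] = int((enr["fdr"] < 0.05).sum())

    # --- co-regulation ----------------------------------------------------
    try:
        common = [g for g in protein.gene_ids if g in set(mrna.gene_ids)]
        prot_pairs = pairwise_correlations(protein.subset_genes(common), config.min_obs)
        mrna_pairs = pairwise_correlations(mrna.subset_genes(common), config.min_obs)
        sets = build_interaction_sets(complexes=complexes, universe=set(common))
        aroc_p, sd_p, _ = interaction_aroc(
            prot_pairs, sets.complexes, config.roc_negative_draws, seed=config.seed
        )
        aroc_t, sd_t, _ = interaction_aroc(
            mrna_pairs, sets.complexes, config.roc_negative_draws, seed=config.seed
        )
        pd.DataFrame(
            {
                "level": ["protein", "mrna"],
                "complex_aroc_mean": [aroc_p, aroc_t],
                "complex_aroc_sd": [sd_p, sd_t],
            }
        ).to_csv(out / "coregulation_aroc.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"coregulation: {exc}") from exc
    manifest["counts"]["pairwise_coefficients_per_level"] = prot_pairs.n_pairs
    manifest["results"]["complex_aroc_protein"] = round(aroc_p, 6)
    manifest["results"]["complex_aroc_mrna"] = round(aroc_t, 6)

    # --- regulators -------------------------------------------------------
    try:
        prot_set, mrna_set, cnv_set = (
            set(protein.gene_ids),
            set(mrna.gene_ids),
            set(cnv.gene_ids),
        )
        pairs_cnv = enumerate_directed_pairs(complexes, prot_set, mrna_set, cnv_set)
        pairs_tx = enumerate_directed_pairs(complexes, prot_set, mrna_set, mrna_set)
        assoc_cnv = test_regulatory_pairs(
            protein, mrna, cnv, pairs_cnv, "cnv", config.fdr_threshold, config.min_obs
        )
        assoc_tx = test_regulatory_pairs(
            protein, mrna, None, pairs_tx, "transcript", config.fdr_threshold, config.min_obs
        )
        assoc_cnv = annotate_transcript_support(assoc_cnv, assoc_tx, config.fdr_threshold)
        assoc_cnv.to_csv(out / "regulators_cnv.tsv", sep="\t", index=False)
        assoc_tx.to_csv(out / "regulators_transcript.tsv", sep="\t", index=False)
    except Exception as exc:
        raise PipelineError(f"regulators: {exc}") from exc
    manifest["counts"]["directed_pairs_cnv"] = len(pairs_cnv)
    manifest["counts"]["directed_pairs_transcript"] = len(pairs_tx)
    manifest["counts"]["regulators_cnv_fdr5"] = int(assoc_cnv["significant"].sum())
    manifest["counts"]["regulators_transcript_fdr5"] = int(assoc_tx["significant"].sum())

    # --- sample potential and signature ----------------------------------
    try:
        sample_att, _ = sample_attenuation_potential(
            cnv, mrna, protein, min_obs=config.min_obs, seed=config.gmm_seed
        )
        write_attenuation_tsv(sample_att, out / "attenuation_samples.tsv")
        signature = build_signature(mrna, sample_att["score"].dropna())
        signature.to_frame().to_csv(
            out / "signature.tsv", sep="\t", index_label="gene_id", na_rep="NA"
        )
        labels = sample_att["gmm_class"]
        counts = labels.value_counts()
        if len(counts) == 2 and counts.min() >= 10:
            mean_auc, sd_auc, _ = benchmark_signature(
                mrna.subset_samples(labels.index),
                labels,
                n_splits=config.benchmark_splits,
                seed=config.seed,
                fdr_threshold=config.fdr_threshold,
            )
            manifest["results"]["signature_benchmark_aroc"] = round(mean_auc, 6)
            manifest["results"]["signature_benchmark_sd"] = round(sd_auc, 6)
        else:
            manifest["results"]["signature_benchmark_aroc"] = None
            log.info("benchmark skipped: class sizes %s", counts.to_dict())
    except Exception as exc:
        raise PipelineError(f"signature: {exc}") from exc
    manifest["counts"]["samples_high_potential"] = int(
        (sample_att["gmm_class"] == "attenuated").sum()
    )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
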