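"""Generate a synthetic multi-omics tumour cohort with known ground truth.

The generator produces GISTIC-like copy-number states, mRNA that tracks
dosage linearly, and protein that is buffered toward a latent complex
abundance for attenuated complex subunits, plus clinical/technical
covariates and missing protein entries.
"""
from cnvatten import SimulationConfig, simulate_dataset, write_dataset

config = SimulationConfig(seed=1)  # 282 samples, 2,000 genes, 30 complexes
dataset = simulate_dataset(config)

print(f"cohort: {dataset.cnv.shape[0]} genes x {dataset.cnv.shape[1]} samples")
print(f"complexes: {len(dataset.complexes)}")
print(f"truly attenuated genes (gamma < 1): {len(dataset.truth.attenuated_genes)}")
missing = dataset.protein.values.isna().to_numpy().mean()
print(f"protein missingness: {missing:.1%} (requested {config.missing_rate:.0%})")

write_dataset(dataset, "scratch/example_cohort")
print("written to scratch/example_cohort/ (cnv/mrna/protein/covariates TSVs + truth.json)")
# The attenuated genes are the planted positives every later stage tries
# to recover; truth.json records them with the generative parameters.
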