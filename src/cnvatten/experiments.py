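"""Self-contained validation experiments on synthetic cohorts.

Each function simulates the data it needs through :mod:`cnvatten.simulate`,
runs the corresponding analysis stage and returns summary numbers.  They
back both the validation test-suite and the reproduction script, keeping
the two on one code path.
"""
from __future__ import annotations

import numpy as np
from scipy import stats

from .attenuation import attenuation_table, sample_attenuation_potential
from .coregulation import build_interaction_sets, interaction_aroc, pairwise_correlations
from .regulators import enumerate_directed_pairs, residualize, test_regulatory_pairs
from .simulate import ComplexSpec, SimulationConfig, simulate_dataset


def attenuation_recovery(seed: int = 0) -> dict:
    """GMM recovery of the truly buffered genes on the default cohort."""
    ds = simulate_dataset(SimulationConfig(seed=seed))
    table, _ = attenuation_table(ds.cnv, ds.mrna, ds.protein, seed=seed)
    scored = table[table["score"].notna()]
    truth = set(ds.truth.attenuated_genes) & set(scored.index)
    called = set(scored.index[scored["gmm_class"] == "attenuated"])
    sensitivity = len(called & truth) / len(truth)
    specificity = 1.0 - len(called - truth) / (len(scored) - len(truth))
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "n_genes_scored": len(scored),
        "n_true_attenuated": len(truth),
        "n_called": len(called),
        "attenuated_fraction": len(called) / len(scored),
    }


def coregulation_ordering(seed: int = 0, min_obs: int = 15) -> dict:
    """Complex-pair AROC and mean correlations at both molecular levels."""
    ds = simulate_dataset(SimulationConfig(seed=seed))
    prot = pairwise_correlations(ds.protein, min_obs=min_obs)
    mrna = pairwise_correlations(ds.mrna, min_obs=min_obs)
    sets = build_interaction_sets(
        complexes=ds.complexes, universe=set(ds.protein.gene_ids)
    )
    aroc_p, sd_p, _ = interaction_aroc(prot, sets.complexes, seed=seed)
    aroc_t, sd_t, _ = interaction_aroc(mrna, sets.complexes, seed=seed)
    pos_idx = prot.pair_index(sorted(sets.complexes, key=sorted))
    finite = np.isfinite(prot.r)
    pos_mask = np.zeros(prot.n_pairs, dtype=bool)
    pos_mask[pos_idx] = True
    rng = np.random.default_rng(seed)
    background = rng.choice(np.flatnonzero(finite & ~pos_mask), 5000, replace=False)
    return {
        "aroc_protein": aroc_p,
        "aroc_protein_sd": sd_p,
        "aroc_mrna": aroc_t,
        "aroc_mrna_sd": sd_t,
        "mean_complex_pair_r_protein": float(np.nanmean(prot.r[pos_idx])),
        "mean_random_pair_r_protein": float(np.nanmean(prot.r[background])),
        "n_complex_pairs": int(len(pos_idx)),
    }


def _edge_config(
    seed: int, edges: list[tuple[int, int, float]], n_complexes: int = 1
) -> SimulationConfig:
    specs = [
        ComplexSpec(tuple(range(6 * k, 6 * k + 6)), (1.0,) + (0.2,) * 5)
        for k in range(n_complexes)
    ]
    return SimulationConfig(
        n_samples=282,
        n_genes=max(6 * n_complexes, 30),
        complexes=specs,
        regulatory_edges=edges,
        missing_rate=0.1,
        seed=seed,
    )


def _run_pairs(ds, fdr_threshold: float = 0.05):
    pairs = enumerate_directed_pairs(
        ds.complexes,
        set(ds.protein.gene_ids),
        set(ds.mrna.gene_ids),
        set(ds.cnv.gene_ids),
    )
    return test_regulatory_pairs(
        ds.protein, ds.mrna, ds.cnv, pairs, "cnv", fdr_threshold=fdr_threshold
    )


def regulator_null_calibration(seed: int = 0, n_seeds: int = 10) -> dict:
    """p-value uniformity and false discoveries with no implanted edges."""
    pvals: list[float] = []
    discoveries = []
    for k in range(n_seeds):
        ds = simulate_dataset(_edge_config(seed + 1000 + k, [], n_complexes=6))
        assoc = _run_pairs(ds)
        pvals.extend(assoc["p"].tolist())
        discoveries.append(int(assoc["significant"].sum()))
    ks = stats.kstest(pvals, "uniform")
    return {
        "ks_pvalue": float(ks.pvalue),
        "mean_discoveries": float(np.mean(discoveries)),
        "total_discoveries": int(np.sum(discoveries)),
        "n_tests": len(pvals),
    }


def regulator_edge_power(seed: int = 0, n_seeds: int = 100) -> dict:
    """Recovery rate of a single implanted edge of size 0.5 sd(residual)."""
    recovered = 0
    correct_sign = 0
    for k in range(n_seeds):
        s = seed + 2000 + k
        base = simulate_dataset(_edge_config(s, []))
        resid = residualize(
            base.protein.values.loc["G0001"].to_numpy(),
            base.mrna.values.loc["G0001"].to_numpy(),
        ).residuals
        delta = 0.5 * float(np.nanstd(resid))
        ds = simulate_dataset(_edge_config(s, [(0, 1, delta)]))
        assoc = _run_pairs(ds).set_index(["px", "py"])
        hit = assoc.loc[("G0000", "G0001")]
        if bool(hit["significant"]):
            recovered += 1
            if hit["sign"] == "positive":
                correct_sign += 1
    return {
        "n_seeds": n_seeds,
        "recovered": recovered,
        "correct_sign": correct_sign,
        "recovery_rate": recovered / n_seeds,
    }


def regulator_fdr_control(seed: int = 0, n_seeds: int = 50) -> dict:
    """Empirical false-discovery proportion with 5% true edges (delta 0.6)."""
    edges = [
        (0, 1, 0.6), (0, 2, 0.6), (6, 7, 0.6), (6, 8, 0.6), (12, 13, 0.6),
        (12, 14, 0.6), (18, 19, 0.6), (24, 25, 0.6), (30, 31, 0.6),
    ]  # 9 of 180 directed pairs
    true_pairs = {(f"G{x:04d}", f"G{y:04d}") for x, y, _ in edges}
    fdps = []
    power = []
    for k in range(n_seeds):
        ds = simulate_dataset(_edge_config(seed + 3000 + k, edges, n_complexes=6))
        assoc = _run_pairs(ds)
        called = {
            (r.px, r.py) for r in assoc.itertuples() if r.significant
        }
        n_called = len(called)
        fp = len(called - true_pairs)
        fdps.append(fp / max(n_called, 1))
        power.append(len(called & true_pairs) / len(true_pairs))
    return {
        "mean_fdp": float(np.mean(fdps)),
        "mean_power": float(np.mean(power)),
        "n_seeds": n_seeds,
        "nominal_fdr": 0.05,
    }


def sample_potential_recovery(seed: int = 0) -> dict:
    """Recovery of samples simulated with boosted proteome-wide buffering."""
    cfg = SimulationConfig(
        n_samples=200,
        n_genes=600,
        n_complexes=50,
        complex_size_range=(8, 8),
        attenuated_gamma=0.9,
        high_potential_fraction=0.2,
        high_potential_gamma=0.1,
        missing_rate=0.05,
        seed=seed + 13,
    )
    ds = simulate_dataset(cfg)
    table, _ = sample_attenuation_potential(ds.cnv, ds.mrna, ds.protein, seed=seed)
    planted = set(ds.truth.high_potential_samples)
    called = set(table.index[table["gmm_class"] == "attenuated"])
    return {
        "recovery": len(called & planted) / len(planted),
        "false_rate": len(called - planted) / (len(table) - len(planted)),
        "n_planted": len(planted),
    }


def signature_benchmark_calibration(seed: int = 0, n_splits: int = 100) -> dict:
    """Logistic benchmark on shuffled labels and on a planted 20-gene signal."""
    import pandas as pd

    from .containers import OmicsMatrix
    from .signature import benchmark_signature

    rng = np.random.default_rng(seed)
    n_genes, n_samples = 300, 200
    samples = [f"S{j:04d}" for j in range(n_samples)]
    genes = [f"G{i:04d}" for i in range(n_genes)]
    labels = pd.Series(["strong"] * 100 + ["weak"] * 100, index=samples)

    null_expr = rng.normal(size=(n_genes, n_samples))
    shuffled = pd.Series(rng.permutation(labels.to_numpy()), index=samples)
    null_mean, null_sd, null_aucs = benchmark_signature(
        OmicsMatrix(pd.DataFrame(null_expr, index=genes, columns=samples), "mrna"),
        shuffled,
        n_splits=n_splits,
        seed=seed,
    )

    planted_expr = rng.normal(size=(n_genes, n_samples))
    planted_expr[:20, :100] += 1.0  # 20-gene block shifted by one sd in class "strong"
    planted_mean, planted_sd, _ = benchmark_signature(
        OmicsMatrix(pd.DataFrame(planted_expr, index=genes, columns=samples), "mrna"),
        labels,
        n_splits=n_splits,
        seed=seed,
    )
    return {
        "null_mean_aroc": null_mean,
        "null_sd": null_sd,
        "null_se_of_mean": null_sd / np.sqrt(n_splits),
        "planted_mean_aroc": planted_mean,
        "planted_sd": planted_sd,
        "n_splits": n_splits,
    }
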