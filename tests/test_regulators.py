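import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cnvatten import (
    ComplexSpec,
    SimulationConfig,
    compare_to_knockdowns,
    enumerate_directed_pairs,
    residualize,
    simulate_dataset,
)
from cnvatten import regulators as reg

# avoid pytest collecting the library function by its test_* name
fit_regulatory_pairs = reg.test_regulatory_pairs
from cnvatten._stats import bh_fdr, slope_f_test

from helpers import bh_oracle, f_test_oracle, ols_oracle, spearman_oracle


class TestResidualize:
    def test_exact_linear_relation_leaves_zero_residuals(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        prof = residualize(2.0 * t, t)
        np.testing.assert_allclose(prof.residuals, 0.0, atol=1e-10)
        assert prof.slope == pytest.approx(2.0, abs=1e-12)

    def test_constant_transcript_centers_protein(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=12)
        prof = residualize(p, np.full(12, 3.0))
        np.testing.assert_allclose(prof.residuals, p - p.mean(), atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=12)
        p = 0.7 * t + rng.normal(size=12)
        prof = residualize(p, t)
        X = np.column_stack([np.ones(12), t])
        _, expected = ols_oracle(X, p)
        np.testing.assert_allclose(prof.residuals, expected, atol=1e-10)

    def test_missing_samples_carry_missing_residuals(self):
        t = np.arange(15.0)
        p = 2 * t
        p[3] = np.nan
        prof = residualize(p, t)
        assert np.isnan(prof.residuals[3])
        assert prof.n_obs == 14

    def test_residuals_orthogonal_to_transcript(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=40)
        p = 0.5 * t + rng.normal(size=40)
        prof = residualize(p, t)
        assert abs(np.dot(prof.residuals, t - t.mean())) < 1e-6


class TestEnumerateDirectedPairs:
    def test_three_gene_complex_yields_six_pairs(self):
        pairs = enumerate_directed_pairs(
            {"c": {"a", "b", "c"}}, {"a", "b", "c"}, {"a", "b", "c"}, {"a", "b", "c"}
        )
        assert len(pairs) == 6

    def test_predictor_coverage_controls_outgoing_pairs(self):
        complexes = {"c": {"a", "b"}}
        measured = {"a", "b"}
        no_cnv_for_a = enumerate_directed_pairs(complexes, measured, measured, {"b"})
        assert no_cnv_for_a == [("b", "a")]
        with_transcript = enumerate_directed_pairs(complexes, measured, measured, {"a", "b"})
        assert with_transcript == [("a", "b"), ("b", "a")]

    def test_toy_catalog_matches_bruteforce(self):
        complexes = {"c1": {"a", "b", "c"}, "c2": {"c", "d"}}
        measured = {"a", "b", "c", "d"}
        pairs = enumerate_directed_pairs(complexes, measured, measured, measured)
        brute = set()
        for members in complexes.values():
            for x in members:
                for y in members:
                    if x != y:
                        brute.add((x, y))
        assert set(pairs) == brute


class TestFStatistics:
    def test_f_equals_squared_t_and_p_matches(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        beta, f, p, n = slope_f_test(x, y)
        slope_o, f_o, p_o = f_test_oracle(x, y)
        assert beta == pytest.approx(slope_o, abs=1e-10)
        assert f == pytest.approx(f_o, rel=1e-10)
        assert p == pytest.approx(p_o, rel=1e-8)

    @given(st.lists(st.floats(0.0001, 0.9999, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bh_matches_bruteforce_stepup(self, pvals):
        p = np.asarray(pvals)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_bh_monotone_in_p(self, rng):
        p = np.sort(rng.uniform(size=50))
        adj = bh_fdr(p)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()


def _edge_config(delta, seed, gamma=0.2, edge=(0, 1)):
    members = tuple(range(6))
    spec = ComplexSpec(members, (1.0,) + (gamma,) * 5)
    return SimulationConfig(
        n_samples=282,
        n_genes=30,
        complexes=[spec],
        regulatory_edges=[(edge[0], edge[1], delta)] if delta else [],
        missing_rate=0.1,
        seed=seed,
    )


def _residual_sd(seed):
    ds = simulate_dataset(_edge_config(0.0, seed))
    prof = residualize(
        ds.protein.values.loc["G0001"].to_numpy(),
        ds.mrna.values.loc["G0001"].to_numpy(),
    )
    return np.nanstd(prof.residuals)


class TestRegulatoryPairs:
    def test_implanted_edge_recovered_with_positive_sign(self):
        delta = 0.5 * _residual_sd(101)
        ds = simulate_dataset(_edge_config(delta, 101))
        pairs = enumerate_directed_pairs(
            ds.complexes,
            set(ds.protein.gene_ids),
            set(ds.mrna.gene_ids),
            set(ds.cnv.gene_ids),
        )
        assoc = fit_regulatory_pairs(ds.protein, ds.mrna, ds.cnv, pairs, "cnv")
        hit = assoc[(assoc.px == "G0000") & (assoc.py == "G0001")].iloc[0]
        assert hit.significant
        assert hit.sign == "positive"

    def test_mutual_exclusivity_edge_recovered_with_negative_sign(self):
        delta = -0.5 * _residual_sd(102)
        ds = simulate_dataset(_edge_config(delta, 102))
        pairs = enumerate_directed_pairs(
            ds.complexes,
            set(ds.protein.gene_ids),
            set(ds.mrna.gene_ids),
            set(ds.cnv.gene_ids),
        )
        assoc = fit_regulatory_pairs(ds.protein, ds.mrna, ds.cnv, pairs, "cnv")
        hit = assoc[(assoc.px == "G0000") & (assoc.py == "G0001")].iloc[0]
        assert hit.significant
        assert hit.sign == "negative"

    def test_implanting_forward_edge_keeps_reverse_near_nominal(self):
        """Directionality: x->y effects must not surface as y->x calls."""
        reverse_p = []
        for seed in range(210, 240):
            delta = 0.5 * _residual_sd(seed)
            ds = simulate_dataset(_edge_config(delta, seed))
            pairs = [("G0001", "G0000")]
            assoc = fit_regulatory_pairs(ds.protein, ds.mrna, ds.cnv, pairs, "cnv")
            reverse_p.append(assoc.iloc[0]["p"])
        frac_nominal = np.mean(np.asarray(reverse_p) < 0.05)
        assert frac_nominal <= 0.2  # ~5% expected; binomial slack over 30 seeds

    def test_transcript_support_annotation(self):
        from cnvatten.regulators import annotate_transcript_support

        delta = 0.6 * _residual_sd(103)
        ds = simulate_dataset(_edge_config(delta, 103))
        pairs = enumerate_directed_pairs(
            ds.complexes,
            set(ds.protein.gene_ids),
            set(ds.mrna.gene_ids),
            set(ds.cnv.gene_ids),
        )
        cnv_assoc = fit_regulatory_pairs(ds.protein, ds.mrna, ds.cnv, pairs, "cnv")
        tx_assoc = fit_regulatory_pairs(ds.protein, ds.mrna, None, pairs, "transcript")
        out = annotate_transcript_support(cnv_assoc, tx_assoc)
        hit = out[(out.px == "G0000") & (out.py == "G0001")].iloc[0]
        # dosage reaches the partner's residual through the transcript too
        assert bool(hit.transcript_support)

    def test_zero_variance_predictor_skipped(self, rng):
        from conftest import as_omics

        prot = as_omics(rng.normal(size=(2, 30)), "protein")
        mrna = as_omics(rng.normal(size=(2, 30)), "mrna")
        cnv = as_omics(np.zeros((2, 30)), "cnv")
        with pytest.raises(ValueError, match="no testable pair"):
            fit_regulatory_pairs(prot, mrna, cnv, [("G0000", "G0001")], "cnv")


class TestKnockdownComparison:
    def _assoc(self, betas):
        return pd.DataFrame(
            {
                "px": [f"x{i}" for i in range(len(betas))],
                "py": [f"y{i}" for i in range(len(betas))],
                "beta": betas,
            }
        )

    def test_identical_rankings_give_rho_one(self):
        assoc = self._assoc([0.1, 0.5, 0.3, 0.9, 0.2, 0.7])
        kd = assoc.rename(columns={"beta": "change"})[["px", "py"]].assign(
            change=[0.1, 0.5, 0.3, 0.9, 0.2, 0.7]
        )
        rho, p = compare_to_knockdowns(assoc, kd)
        assert rho == pytest.approx(1.0)

    def test_reversed_rankings_give_rho_minus_one(self):
        assoc = self._assoc([0.1, 0.2, 0.3, 0.4, 0.5])
        kd = assoc[["px", "py"]].assign(change=[0.5, 0.4, 0.3, 0.2, 0.1])
        rho, p = compare_to_knockdowns(assoc, kd)
        assert rho == pytest.approx(-1.0)

    def test_eight_row_toy_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(8)
        betas = rng.normal(size=8)
        changes = rng.normal(size=8)
        assoc = self._assoc(betas)
        kd = assoc[["px", "py"]].assign(change=changes)
        rho, _ = compare_to_knockdowns(assoc, kd)
        assert rho == pytest.approx(spearman_oracle(betas, changes), abs=1e-12)

    def test_insufficient_overlap_rejected(self):
        assoc = self._assoc([0.1, 0.2])
        kd = assoc[["px", "py"]].assign(change=[1.0, 2.0])
        with pytest.raises(ValueError, match="5"):
            compare_to_knockdowns(assoc, kd)
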