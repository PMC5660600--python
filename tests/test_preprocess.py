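import numpy as np
import pandas as pd
import pytest

from cnvatten import (
    OmicsMatrix,
    coverage_jaccard,
    cpm_filter_log,
    kde_center,
    presence_filter,
    regress_out_covariates,
)

from conftest import as_omics
from helpers import kde_mode_oracle


class TestCpmFilter:
    def test_all_zero_gene_excluded(self):
        counts = pd.DataFrame(
            {"s1": [0, 100, 2000], "s2": [0, 150, 2500]},
            index=["zero", "mid", "high"],
        )
        out = cpm_filter_log(counts)
        assert "zero" not in out.gene_ids

    def test_hand_computed_cpm_threshold(self):
        """Gene with counts (1, 1) at library sizes 1e6 / 2e6: mean CPM 0.75."""
        counts = pd.DataFrame(
            {"s1": [1, 10_000, 989_999], "s2": [1, 20_000, 1_979_999]},
            index=["low", "mid", "filler"],
        )
        assert counts["s1"].sum() == 1_000_000 and counts["s2"].sum() == 2_000_000
        out = cpm_filter_log(counts)
        assert "low" not in out.gene_ids
        assert "mid" in out.gene_ids
        # survivors carry log2(CPM + 0.5)
        expected = np.log2(10_000 / 1_000_000 * 1e6 + 0.5)
        assert out.values.loc["mid", "s1"] == pytest.approx(expected, abs=1e-12)

    def test_high_counts_all_kept(self, rng):
        counts = pd.DataFrame(
            rng.integers(100, 1000, size=(20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(4)],
        )
        assert cpm_filter_log(counts).shape[0] == 20

    def test_zero_library_size_names_sample(self):
        counts = pd.DataFrame({"good": [5, 5], "empty": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            cpm_filter_log(counts)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
        ],
    )
    def test_examples(self, a, b, expected):
        assert coverage_jaccard(a, b) == pytest.approx(expected)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            coverage_jaccard(set(), set())


class TestRegressOutCovariates:
    def _cov(self, n, batch):
        return pd.DataFrame(
            {"age": np.linspace(40, 70, n), "batch": batch},
            index=[f"S{j:04d}" for j in range(n)],
        )

    def test_orthogonal_covariate_leaves_gene_unchanged(self):
        n = 40
        batch = np.array(["A", "B"] * (n // 2))
        indicator = (batch == "B").astype(float)
        age = np.linspace(40, 70, n)
        # build a gene orthogonal to the centered design columns
        design = np.column_stack([age - age.mean(), indicator - indicator.mean()])
        rng = np.random.default_rng(0)
        y = rng.normal(size=n)
        y -= design @ np.linalg.lstsq(design, y, rcond=None)[0]
        m = as_omics(y[None, :], "mrna")
        out = regress_out_covariates(m, self._cov(n, batch))
        np.testing.assert_allclose(out.values.to_numpy()[0], y, atol=1e-8)

    def test_exact_batch_effect_removed(self):
        n = 30
        batch = np.array(["A"] * 15 + ["B"] * 15)
        y = 1.0 + 2.0 * (batch == "B")
        m = as_omics(y[None, :], "protein")
        out = regress_out_covariates(m, self._cov(n, batch))
        corrected = out.values.to_numpy()[0]
        assert np.ptp(corrected) < 1e-8  # constant after removing the batch term

    def test_missing_entries_stay_missing(self):
        n = 30
        batch = np.array(["A", "B"] * 15)
        rng = np.random.default_rng(1)
        y = rng.normal(size=(5, n))
        y[2, 7] = np.nan
        out = regress_out_covariates(as_omics(y, "protein"), self._cov(n, batch))
        assert np.isnan(out.values.to_numpy()[2, 7])
        assert np.isfinite(out.values.to_numpy()).sum() == 5 * n - 1

    def test_single_level_covariate_dropped(self):
        n = 20
        cov = pd.DataFrame(
            {"batch": ["A"] * n, "age": np.linspace(30, 60, n)},
            index=[f"S{j:04d}" for j in range(n)],
        )
        y = np.random.default_rng(2).normal(size=(3, n))
        out = regress_out_covariates(as_omics(y, "mrna"), cov)
        assert out.shape == (3, n)

    def test_residuals_orthogonal_to_design(self, small_dataset):
        """On complete data each corrected gene is orthogonal to the design."""
        out = regress_out_covariates(small_dataset.mrna, small_dataset.covariates)
        from cnvatten.preprocess import _design_matrix

        X, _ = _design_matrix(small_dataset.covariates.loc[out.sample_ids])
        resid = out.values.to_numpy() - out.values.to_numpy().mean(axis=1, keepdims=True)
        Xc = X[:, 1:] - X[:, 1:].mean(axis=0, keepdims=True)
        Xc = Xc / np.abs(Xc).max(axis=0)
        inner = resid @ Xc / resid.shape[1]
        assert np.abs(inner).max() < 1e-6

    def test_covariate_signal_removed_from_principal_components(self, small_dataset):
        """Top PCs decorrelate from every covariate after correction."""
        from sklearn.decomposition import PCA

        corrected = regress_out_covariates(small_dataset.mrna, small_dataset.covariates)
        pcs = PCA(n_components=10, random_state=0).fit_transform(
            corrected.values.to_numpy().T
        )
        cov = small_dataset.covariates
        numeric = {
            "age": cov["age"].to_numpy(),
            "gender": (cov["gender"] == "male").to_numpy(float),
            "technology": (cov["technology"] == "labelfree").to_numpy(float),
            "tumour_HGSC": (cov["tumour_type"] == "HGSC").to_numpy(float),
            "tumour_COREAD": (cov["tumour_type"] == "COREAD").to_numpy(float),
        }
        for name, vec in numeric.items():
            for k in range(10):
                r = np.corrcoef(pcs[:, k], vec)[0, 1]
                assert abs(r) < 0.1, f"PC{k + 1} still tracks {name}: r={r:.3f}"


class TestPresenceFilter:
    def test_strict_threshold(self):
        n = 100
        y = np.ones((2, n))
        y[0, :51] = np.nan  # measured in 49% of samples
        out = presence_filter(as_omics(y, "protein"), 0.5)
        assert out.shape[0] == 1

    def test_no_missing_unchanged(self, rng):
        m = as_omics(rng.normal(size=(10, 8)), "protein")
        pd.testing.assert_frame_equal(presence_filter(m).values, m.values)

    def test_matches_bruteforce_recount(self, small_dataset):
        out = presence_filter(small_dataset.protein, 0.9)
        P = small_dataset.protein.values
        expected = [
            g
            for g in P.index
            if sum(np.isfinite(v) for v in P.loc[g]) / P.shape[1] >= 0.9
        ]
        assert out.gene_ids == expected

    def test_empty_result_rejected(self):
        y = np.full((2, 10), np.nan)
        y[:, 0] = 1.0
        with pytest.raises(ValueError):
            presence_filter(as_omics(y, "protein"), 0.5)


class TestKdeCenter:
    def test_symmetric_sample_centered_near_zero(self, rng):
        y = rng.normal(5.0, 1.0, size=(1, 400))
        out = kde_center(as_omics(y, "mrna"))
        assert abs(out.values.to_numpy().mean()) < 0.15

    def test_bimodal_centers_on_dominant_mode(self, rng):
        x = np.concatenate([rng.normal(5.0, 0.1, 140), rng.normal(0.0, 0.1, 60)])
        out = kde_center(as_omics(x[None, :], "protein"))
        centered = out.values.to_numpy()[0]
        # dominant mode maps to ~0; the mean does not
        assert abs(np.median(centered[:140])) < 0.1
        assert abs(centered.mean()) > 0.5
        oracle_mode = kde_mode_oracle(x)
        assert abs((x - centered).mean() - oracle_mode) < 0.05

    def test_idempotent_at_mode(self, rng):
        m = as_omics(rng.normal(size=(5, 200)), "mrna")
        once = kde_center(m)
        twice = kde_center(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-6
        )

    def test_constant_gene_centered_to_zero(self):
        y = np.full((1, 20), 3.5)
        out = kde_center(as_omics(y, "mrna"))
        np.testing.assert_allclose(out.values.to_numpy(), 0.0)


class TestRoundTrip:
    def test_tsv_round_trip_bit_exact(self, tmp_path, rng):
        y = rng.normal(size=(6, 5))
        y[1, 2] = np.nan
        m = as_omics(y, "protein")
        m.to_tsv(tmp_path / "m.tsv")
        back = OmicsMatrix.from_tsv(tmp_path / "m.tsv", "protein")
        pd.testing.assert_frame_equal(back.values, m.values)

    def test_sample_order_preserved(self, small_dataset, tmp_path):
        small_dataset.mrna.to_tsv(tmp_path / "t.tsv")
        back = OmicsMatrix.from_tsv(tmp_path / "t.tsv", "mrna")
        assert back.sample_ids == small_dataset.mrna.sample_ids
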