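import numpy as np
import pandas as pd
import pytest

from filamix import (FitError, MixtureFit, MixtureModel, SimulationParams,
                     condition_means, fit_mixture, rank_outliers,
                     reduce_dataset, simulate_dataset, weighted_residuals)


class TestReduceDataset:
    def test_low_signal_gene_removed(self, toy_matrix):
        m = toy_matrix
        m.values.loc["g1"] = 100.0  # mean 100 < 128
        out, report = reduce_dataset(m, "P", mean_floor=128,
                                     cv_threshold=np.inf)
        assert "g1" not in out.gene_ids
        assert report.genes_removed_low_signal == 1
        assert report.genes_out == report.genes_in - 1

    def test_filters_off_is_identity(self, toy_matrix):
        out, report = reduce_dataset(toy_matrix, "P", mean_floor=0.0,
                                     cv_threshold=np.inf)
        assert list(out.gene_ids) == list(toy_matrix.gene_ids)
        assert report.genes_removed_low_signal == 0
        assert report.genes_removed_variability == 0

    def test_variable_gene_removed_after_low_signal(self, toy_matrix):
        m = toy_matrix
        # g2: huge spread within the V replicates -> CV > 0.5
        m.values.loc["g2", ["P_V_1", "P_V_2", "P_V_3"]] = [100.0, 2000.0,
                                                           150.0]
        out, report = reduce_dataset(m, "P", mean_floor=0.0,
                                     cv_threshold=0.5)
        assert "g2" not in out.gene_ids
        assert report.genes_removed_variability >= 1

    def test_absent_condition_errors(self, toy_matrix):
        with pytest.raises(Exception, match="M"):
            reduce_dataset(toy_matrix, "M")

    def test_counts_reconcile(self, small_sim):
        m, _ = small_sim
        out, report = reduce_dataset(m, "P")
        assert report.genes_out == (report.genes_in
                                    - report.genes_removed_low_signal
                                    - report.genes_removed_variability)
        assert out.n_genes == report.genes_out


class TestFitMixture:
    def test_noiseless_recovery_hand_example(self):
        """V=(100,200,400), Ht=(50,300,10), F=aV+bHt with a=.92,b=.08."""
        v = np.array([100.0, 200.0, 400.0])
        ht = np.array([50.0, 300.0, 10.0])
        f = 0.92 * v + 0.08 * ht
        np.testing.assert_allclose(f, [96.0, 208.0, 368.8])
        fit = fit_mixture(v, ht, f, method="ols")
        assert fit.a == pytest.approx(0.92, abs=1e-10)
        assert fit.b == pytest.approx(0.08, abs=1e-10)
        assert fit.sse == pytest.approx(0.0, abs=1e-12)

    def test_grid_agrees_with_ols_on_noiseless_data(self):
        rng = np.random.default_rng(4)
        v = rng.uniform(100, 5000, 200)
        ht = rng.uniform(100, 5000, 200)
        f = 0.913 * v + 0.077 * ht
        ols = fit_mixture(v, ht, f, method="ols")
        grid = fit_mixture(v, ht, f, method="grid")
        assert abs(grid.a - ols.a) <= 0.001
        assert abs(grid.b - ols.b) <= 0.001

    def test_grid_lattice_brute_force_oracle(self):
        """Coarse grid reproduced by explicit double loop over the lattice."""
        rng = np.random.default_rng(5)
        v = rng.uniform(100, 1000, 30)
        ht = rng.uniform(100, 1000, 30)
        f = 0.9 * v + 0.1 * ht + rng.normal(0, 20, 30)
        f = np.abs(f)
        grid = fit_mixture(v, ht, f, method="grid",
                           a_grid=(0.8, 1.0, 0.01), b_grid=(0.0, 0.2, 0.01))
        norm2 = v * v + ht * ht + f * f
        best = (np.inf, None, None)
        for a in np.arange(0.8, 1.0 + 0.005, 0.01):
            for b in np.arange(0.0, 0.2 + 0.005, 0.01):
                sse = (((f - a * v - b * ht) ** 2) / norm2).sum()
                if sse < best[0]:
                    best = (sse, a, b)
        assert grid.a == pytest.approx(best[1], abs=1e-12)
        assert grid.b == pytest.approx(best[2], abs=1e-12)
        assert grid.sse == pytest.approx(best[0], rel=1e-9)

    def test_negative_b_not_clipped(self):
        """Coefficients are unconstrained (real data can give b < 0)."""
        rng = np.random.default_rng(6)
        v = rng.uniform(100, 1000, 100)
        ht = rng.uniform(100, 1000, 100)
        f = 1.05 * v - 0.05 * ht
        fit = fit_mixture(v, ht, f, method="ols")
        assert fit.b == pytest.approx(-0.05, abs=1e-9)
        grid = fit_mixture(v, ht, f, method="grid")
        assert grid.b == pytest.approx(-0.05, abs=0.001)

    def test_collinear_input_errors(self):
        v = np.array([1.0, 2.0, 3.0])
        with pytest.raises(FitError, match="collinear"):
            fit_mixture(v, 2 * v, v, method="ols")

    def test_empty_and_tiny_inputs_error(self):
        with pytest.raises(FitError):
            fit_mixture([], [], [])
        with pytest.raises(FitError):
            fit_mixture([1.0, 2.0], [2.0, 1.0], [1.0, 1.0])

    def test_bootstrap_ci_contains_estimate(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(100, 5000, 300)
        ht = rng.uniform(100, 5000, 300)
        f = np.abs(0.92 * v + 0.08 * ht + rng.normal(0, 30, 300))
        fit = fit_mixture(v, ht, f, method="ols", n_boot=200, seed=1)
        lo, hi = fit.bootstrap_ci_a
        assert lo <= fit.a <= hi
        lo, hi = fit.bootstrap_ci_b
        assert lo <= fit.b <= hi

    def test_bootstrap_seeded_determinism(self):
        rng = np.random.default_rng(8)
        v = rng.uniform(100, 5000, 100)
        ht = rng.uniform(100, 5000, 100)
        f = 0.9 * v + 0.1 * ht
        f1 = fit_mixture(v, ht, f, n_boot=50, seed=9)
        f2 = fit_mixture(v, ht, f, n_boot=50, seed=9)
        assert f1.bootstrap_ci_a == f2.bootstrap_ci_a
        assert f1.bootstrap_ci_b == f2.bootstrap_ci_b

    def test_sklearn_estimator_interface(self):
        est = MixtureModel(method="ols")
        assert est.get_params()["method"] == "ols"
        X = np.array([[100.0, 50.0], [200.0, 300.0], [400.0, 10.0]])
        y = X @ [0.92, 0.08]
        est.fit(X, y)
        np.testing.assert_allclose(est.coef_, [0.92, 0.08], atol=1e-10)
        np.testing.assert_allclose(est.predict(X), y, rtol=1e-12)


class TestWeightedResiduals:
    def test_exact_mixture_gives_zero(self):
        fit = MixtureFit(a=0.92, b=0.08, method="ols", sse=0.0)
        rec = weighted_residuals(fit, [100.0], [100.0], [100.0])
        assert rec["r"].iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_example(self):
        """V=Ht=100, F=200: f_calc=100, norm=sqrt(60000), r ~ +0.4082."""
        fit = MixtureFit(a=0.92, b=0.08, method="ols", sse=0.0)
        rec = weighted_residuals(fit, [100.0], [100.0], [200.0],
                                 gene_ids=["g1"])
        assert rec.loc["g1", "f_calc"] == pytest.approx(100.0)
        assert rec.loc["g1", "vector_norm"] == pytest.approx(
            np.sqrt(60000.0))
        assert rec.loc["g1", "r"] == pytest.approx(100.0 / np.sqrt(60000.0))
        assert rec.loc["g1", "r"] == pytest.approx(0.4082, abs=1e-4)

    def test_sign_convention(self):
        fit = MixtureFit(a=0.92, b=0.08, method="ols", sse=0.0)
        rec = weighted_residuals(fit, [100.0, 100.0], [100.0, 100.0],
                                 [50.0, 200.0], gene_ids=["lo", "hi"])
        assert rec.loc["lo", "r"] < 0
        assert rec.loc["hi", "r"] > 0

    def test_reconstruction_identity(self, small_sim):
        """r * norm + f_calc recovers f_mean for every gene."""
        m, _ = small_sim
        v, ht, f = condition_means(m, "P")
        fit = fit_mixture(v, ht, f)
        rec = weighted_residuals(fit, v, ht, f, gene_ids=m.gene_ids)
        np.testing.assert_allclose(
            rec["r"] * rec["vector_norm"] + rec["f_calc"], rec["f_mean"],
            rtol=1e-12)

    def test_all_zero_gene_excluded_with_warning(self):
        fit = MixtureFit(a=0.92, b=0.08, method="ols", sse=0.0)
        with pytest.warns(UserWarning, match="V=Ht=F=0"):
            rec = weighted_residuals(fit, [0.0, 100.0], [0.0, 100.0],
                                     [0.0, 100.0], gene_ids=["z", "g"])
        assert list(rec.index) == ["g"]


class TestRankOutliers:
    @pytest.fixture
    def records(self):
        fit = MixtureFit(a=0.92, b=0.08, method="ols", sse=0.0)
        v = [100.0, 100.0, 100.0, 100.0]
        ht = [100.0, 100.0, 100.0, 100.0]
        f = [100.0, 300.0, 20.0, 300.0]  # zero, high, low, high (tie)
        return weighted_residuals(fit, v, ht, f,
                                  gene_ids=["gz", "gb", "gl", "ga"])

    def test_k_zero_empty(self, records):
        assert len(rank_outliers(records, 0)) == 0

    def test_f_high_direction(self, records):
        top = rank_outliers(records, 2, "f_high")
        assert set(top.index) == {"ga", "gb"}

    def test_tie_broken_lexicographically(self, records):
        top = rank_outliers(records, 2, "f_high")
        assert list(top.index) == ["ga", "gb"]
        assert list(top["rank"]) == [1, 2]

    def test_f_low_direction(self, records):
        assert rank_outliers(records, 1, "f_low").index[0] == "gl"

    def test_negative_k_errors(self, records):
        with pytest.raises(ValueError):
            rank_outliers(records, -1)

    def test_degraded_genes_top_ranked(self):
        """Planted degraded genes dominate the f_high ranking."""
        p = SimulationParams(n_genes=1000, noise_cv=0.1,
                             degraded_gene_count=10,
                             degradation_factor=0.1, seed=3)
        m, truth = simulate_dataset(p)
        v, ht, f = condition_means(m, "P")
        fit = fit_mixture(v, ht, f)
        rec = weighted_residuals(fit, v, ht, f, gene_ids=m.gene_ids)
        top = rank_outliers(rec, 15, "f_high")
        assert truth.degraded_genes <= set(top.index)


def test_bootstrap_interval_coverage():
    """95% percentile bootstrap intervals cover the true b in roughly 95%
    of simulated datasets (90-99% band, scaled-down replication)."""
    cover = 0
    n_data = 60
    for s in range(n_data):
        p = SimulationParams(n_genes=800, noise_cv=0.1,
                             degraded_gene_count=0, seed=1000 + s)
        m, _ = simulate_dataset(p)
        v, ht, f = condition_means(m, "P")
        fit = fit_mixture(v, ht, f, n_boot=200, seed=s)
        lo, hi = fit.bootstrap_ci_b
        cover += lo <= 0.08 <= hi
    assert 0.90 * n_data <= cover <= 0.99 * n_data


def test_degradation_monotonicity():
    """Stronger degradation (smaller delta) never worsens a degraded
    gene's mean f_high rank (averaged over seeds)."""
    mean_rank = {}
    for delta in (0.5, 0.2, 0.05):
        ranks = []
        for seed in range(4):
            p = SimulationParams(n_genes=800, noise_cv=0.1,
                                 degraded_gene_count=5,
                                 degradation_factor=delta, seed=seed)
            m, truth = simulate_dataset(p)
            v, ht, f = condition_means(m, "P")
            fit = fit_mixture(v, ht, f)
            rec = weighted_residuals(fit, v, ht, f, gene_ids=m.gene_ids)
            ordered = rank_outliers(rec, len(rec), "f_high")
            ranks.extend(ordered.loc[sorted(truth.degraded_genes),
                                     "rank"].tolist())
        mean_rank[delta] = np.mean(ranks)
    assert mean_rank[0.05] <= mean_rank[0.2] <= mean_rank[0.5]
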