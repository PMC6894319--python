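import numpy as np
import pandas as pd
import pytest

from hectpipe.genepanel import (
    PanelMatrix,
    differential_expression,
    isoform_ratio,
    normalize_panel,
    pca_scores,
    plsr_nipals,
)
from hectpipe.mechanics import DataError
from hectpipe.synthetic import PanelSimParams, generate_panel_counts


def small_panel(rng=None, n=3):
    rng = rng or np.random.default_rng(0)
    genes = ["B2M", "GAPDH", "TNNT2", "MYH7", "MYH6", "ACTA1"]
    classes = pd.Series(
        ["housekeeping", "housekeeping", "endogenous", "endogenous", "endogenous", "endogenous"],
        index=genes,
    )
    samples = [f"c{i}" for i in range(n)] + [f"t{i}" for i in range(n)]
    counts = pd.DataFrame(
        rng.uniform(100, 5000, size=(len(genes), 2 * n)), index=genes, columns=samples
    )
    groups = pd.Series(["control"] * n + ["treated"] * n, index=samples)
    return PanelMatrix(counts=counts, gene_classes=classes, groups=groups)


class TestNormalization:
    def test_stage1_invariant_to_per_sample_scaling(self):
        pm = small_panel()
        scaled = small_panel()
        scaled.counts["c1"] *= 3.0
        a = normalize_panel(pm).values
        b = normalize_panel(scaled).values
        # multiplying one sample's counts cancels through the housekeeping
        # factor (global rescale aside, which shifts all samples equally)
        ratio = (b / a).to_numpy()
        np.testing.assert_allclose(ratio, ratio[0, 0])

    def test_reference_gene_is_unity_after_stage2(self):
        pm = small_panel()
        full = normalize_panel(pm)
        # TNNT2 is consumed as the reference; re-derive its normalized value
        counts = pm.counts.astype(float)
        hk = np.exp(np.log(counts.loc[["B2M", "GAPDH"]]).mean(axis=0))
        stage1 = counts.div(hk, axis=1)
        np.testing.assert_allclose(
            (stage1.loc["MYH7"] / stage1.loc["TNNT2"]), full.values.loc["MYH7"]
        )
        assert full.provenance["reference_gene"] == "TNNT2"

    def test_global_scaling_invariance(self):
        pm = small_panel()
        scaled = small_panel()
        scaled.counts *= 17.0
        np.testing.assert_allclose(
            normalize_panel(pm).values, normalize_panel(scaled).values, rtol=1e-12
        )

    def test_zero_housekeeping_count_named(self):
        pm = small_panel()
        pm.counts.loc["GAPDH", "c0"] = 0.0
        with pytest.raises(DataError, match="GAPDH.*c0"):
            normalize_panel(pm)

    def test_fold_change_recovery_from_generator(self):
        # Monte-Carlo mean of the pipeline fold estimate tracks the
        # generating fold change
        ests = []
        for seed in range(30):
            pm = generate_panel_counts(PanelSimParams(n_per_group=30, seed=seed))
            deg = differential_expression(normalize_panel(pm))
            ests.append(deg.loc["ACTA1", "fold_change"])
        assert np.mean(ests) == pytest.approx(2.35, rel=0.05)


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        pm = small_panel()
        pm.counts.loc[:, ["t0", "t1", "t2"]] = pm.counts.loc[:, ["c0", "c1", "c2"]].to_numpy()
        deg = differential_expression(normalize_panel(pm))
        np.testing.assert_allclose(deg["fold_change"], 1.0)
        assert np.all((deg["p_value"] > 0.99) | np.isnan(deg["p_value"]))

    def test_within_group_permutation_invariance(self):
        pm = small_panel()
        deg1 = differential_expression(normalize_panel(pm))
        permuted = small_panel()
        permuted.counts = permuted.counts[["c2", "c0", "c1", "t1", "t2", "t0"]]
        permuted.groups = permuted.groups[["c2", "c0", "c1", "t1", "t2", "t0"]]
        deg2 = differential_expression(normalize_panel(permuted))
        np.testing.assert_allclose(deg1["p_value"], deg2["p_value"], rtol=1e-10)
        np.testing.assert_allclose(deg1["fold_change"], deg2["fold_change"], rtol=1e-10)

    def test_q_values_monotone_in_p(self):
        pm = generate_panel_counts(PanelSimParams(n_per_group=5, seed=1))
        deg = differential_expression(normalize_panel(pm)).dropna(subset=["p_value"])
        deg = deg.sort_values("p_value")
        assert (np.diff(deg["q_value"]) >= -1e-12).all()
        assert (deg["q_value"] >= deg["p_value"] - 1e-12).all()


class TestIsoformRatio:
    def _panel_with(self, a_vals, b_vals):
        genes = ["B2M", "GAPDH", "TNNT2", "A", "B"]
        classes = pd.Series(
            ["housekeeping", "housekeeping", "endogenous", "endogenous", "endogenous"],
            index=genes,
        )
        n = len(a_vals)
        samples = [f"s{i}" for i in range(n)]
        counts = pd.DataFrame(
            [[1000.0] * n, [1000.0] * n, [1000.0] * n, list(a_vals), list(b_vals)],
            index=genes,
            columns=samples,
        )
        groups = pd.Series(["g"] * n, index=samples)
        return normalize_panel(PanelMatrix(counts=counts, gene_classes=classes, groups=groups))

    def test_constant_ratio(self):
        res = isoform_ratio(self._panel_with([4, 4, 4], [2, 2, 2]), "A", "B")
        assert res.loc["g", "mean_of_ratios"] == pytest.approx(2.0)

    def test_equal_genes_give_unity(self):
        res = isoform_ratio(self._panel_with([3, 5, 7], [3, 5, 7]), "A", "B")
        assert res.loc["g", "mean_of_ratios"] == pytest.approx(1.0)

    def test_conventions_differ_for_heterogeneous_samples(self):
        # A={4,1}, B={2,1}: mean of per-sample ratios 1.5, ratio of means 5/3
        res = isoform_ratio(self._panel_with([4, 1], [2, 1]), "A", "B")
        assert res.loc["g", "mean_of_ratios"] == pytest.approx(1.5)
        assert res.loc["g", "ratio_of_means"] == pytest.approx(5.0 / 3.0)

    def test_zero_denominator_named(self):
        norm = self._panel_with([4, 1], [2, 1])
        norm.values.loc["B", "s1"] = 0.0
        with pytest.raises(DataError, match="s1"):
            isoform_ratio(norm, "A", "B")


class TestPCA:
    def test_one_dimensional_data_single_component(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        res = pca_scores(x)
        assert res["explained_variance"][0] == pytest.approx(1.0)

    def test_scores_loadings_reconstruct_centered_data(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 4)))
        res = pca_scores(x)
        recon = res["scores"] @ res["loadings"].T
        np.testing.assert_allclose(recon, x - x.mean(), atol=1e-10)

    def test_matches_covariance_eigendecomposition(self, rng):
        x = pd.DataFrame(rng.normal(size=(4, 6)))
        res = pca_scores(x)
        cov = np.cov(x.to_numpy(), rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1][: res["rank"]]
        np.testing.assert_allclose(
            res["explained_variance"], evals / evals.sum(), atol=1e-10
        )

    def test_constant_matrix_degenerate(self):
        with pytest.raises(DataError):
            pca_scores(pd.DataFrame(np.ones((4, 3))))


def svd_pls2(x, y, k):
    """Independent SVD-based PLS2 oracle on pre-scaled blocks."""
    x, y = x.copy(), y.copy()
    ws, ts = [], []
    for _ in range(k):
        u, _, _ = np.linalg.svd(x.T @ y, full_matrices=False)
        w = u[:, 0]
        t = x @ w
        p = x.T @ t / (t @ t)
        q = y.T @ t / (t @ t)
        x = x - np.outer(t, p)
        y = y - np.outer(t, q)
        ws.append(w)
        ts.append(t)
    return np.column_stack(ws), np.column_stack(ts)


class TestNIPALS:
    def test_exact_linear_map_perfect_prediction(self, rng):
        x = pd.DataFrame({"g": rng.normal(size=8)})
        y = pd.DataFrame({"m": 2.0 * x["g"]})
        model = plsr_nipals(x, y, n_components=1)
        assert model.train_r2 == pytest.approx(1.0)
        assert model.loo_r2 == pytest.approx(1.0)

    def test_first_weight_proportional_to_xty_for_single_target(self, rng):
        x = pd.DataFrame(rng.normal(size=(10, 5)))
        y = pd.DataFrame({"m": rng.normal(size=10)})
        model = plsr_nipals(x, y, n_components=1, cross_validate=False)
        xs = ((x - x.mean()) / x.std(ddof=1)).to_numpy()
        ys = ((y - y.mean()) / y.std(ddof=1)).to_numpy().ravel()
        closed = xs.T @ ys
        closed /= np.linalg.norm(closed)
        cosine = abs(closed @ model.x_weights[:, 0])
        assert cosine == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal(self, rng):
        x = pd.DataFrame(rng.normal(size=(9, 6)))
        y = pd.DataFrame(rng.normal(size=(9, 3)))
        model = plsr_nipals(x, y, n_components=3, cross_validate=False)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_matches_svd_pls_oracle(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 8)))
        y = pd.DataFrame(rng.normal(size=(6, 2)))
        model = plsr_nipals(x, y, n_components=2, cross_validate=False)
        xs = ((x - x.mean()) / x.std(ddof=1)).to_numpy()
        ys = ((y - y.mean()) / y.std(ddof=1)).to_numpy()
        w_ref, t_ref = svd_pls2(xs, ys, 2)
        for k in range(2):
            sign = np.sign(w_ref[:, k] @ model.x_weights[:, k])
            np.testing.assert_allclose(sign * w_ref[:, k], model.x_weights[:, k], atol=1e-6)
            np.testing.assert_allclose(sign * t_ref[:, k], model.x_scores[:, k], atol=1e-6)

    def test_explained_variance_within_bounds(self, rng):
        x = pd.DataFrame(rng.normal(size=(8, 5)))
        y = pd.DataFrame(rng.normal(size=(8, 2)))
        model = plsr_nipals(x, y, n_components=2, cross_validate=False)
        for arr in (model.explained_x_pct, model.explained_y_pct):
            assert np.all(arr >= 0) and np.all(arr <= 100) and arr.sum() <= 100 + 1e-9

    def test_correlation_loadings_in_unit_disc(self, rng):
        x = pd.DataFrame(rng.normal(size=(8, 5)))
        y = pd.DataFrame(rng.normal(size=(8, 2)))
        model = plsr_nipals(x, y, n_components=2, cross_validate=False)
        assert np.all(np.abs(model.correlation_loadings_x) <= 1 + 1e-12)
        assert np.all(np.abs(model.correlation_loadings_y) <= 1 + 1e-12)

    def test_zero_variance_column_named(self, rng):
        x = pd.DataFrame(rng.normal(size=(6, 3)), columns=["a", "b", "c"])
        x["b"] = 4.0
        y = pd.DataFrame({"m": rng.normal(size=6)})
        with pytest.raises(DataError, match="b"):
            plsr_nipals(x, y, n_components=1)
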