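"""PCA, contributions, HCPC and cluster characterization."""

import io

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmefib.clustering import (
    characterize_clusters,
    cluster_til_comparison,
    fit_pca,
    hcpc,
    linkage_to_newick,
    variable_contributions,
)


class TestPca:
    def test_collinear_data_loads_on_single_pc(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": 2 * x})
        model = fit_pca(df)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 6)))
        model = fit_pca(df)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_through_loadings(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)), columns=list("abcde"))
        model = fit_pca(df)
        z = (df - model.center) / model.scale
        back = model.coordinates.to_numpy() @ model.loadings.to_numpy().T
        assert np.allclose(back, z.to_numpy(), atol=1e-9)

    def test_sign_convention_largest_loading_positive(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        model = fit_pca(df)
        for col in model.loadings.columns:
            v = model.loadings[col].to_numpy()
            assert v[np.argmax(np.abs(v))] > 0

    def test_constant_column_dropped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=20), "b": np.ones(20)})
        model = fit_pca(df)
        assert model.dropped_constant == ("b",)

    def test_all_constant_refused(self):
        with pytest.raises(ValueError):
            fit_pca(pd.DataFrame({"a": np.ones(10), "b": np.ones(10)}))


class TestContributions:
    def test_sum_to_hundred(self, rng):
        model = fit_pca(pd.DataFrame(rng.normal(size=(40, 13))))
        c = variable_contributions(model, 1)
        assert c.contribution_pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_identity_loading_full_contribution(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"big": rng.normal(0, 10, 200), "tiny": rng.normal(0, 10, 200)})
        df["big"] *= 1  # independent columns: each PC is dominated by one metric
        model = fit_pca(df, standardize=False)
        c = variable_contributions(model, 1)
        assert c.contribution_pct.iloc[0] > 50

    def test_uniform_expectation_for_13_metrics(self, rng):
        model = fit_pca(pd.DataFrame(rng.normal(size=(40, 13))))
        c = variable_contributions(model, 1)
        # dashed-line level: 100/13 ~ 7.69%
        assert c.above_uniform.equals(c.contribution_pct > 100 / 13)


class TestHcpc:
    def test_two_separated_blobs_ari_one(self, rng):
        a = rng.normal(0, 0.3, size=(20, 4))
        b = rng.normal(6, 0.3, size=(20, 4))
        df = pd.DataFrame(np.vstack([a, b]))
        truth = np.r_[np.zeros(20), np.ones(20)]
        model = fit_pca(df)
        fcm = hcpc(model, k=2, retain=4, metrics=df)
        assert adjusted_rand_score(truth, fcm.labels.to_numpy()) == 1.0

    def test_k_one_single_cluster_empty_characterization(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 3)))
        fcm = hcpc(fit_pca(df), k=1, retain=3, metrics=df)
        assert set(fcm.labels) == {1}
        assert fcm.characterization.empty

    def test_k_exceeding_samples_refused(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            hcpc(fit_pca(df), k=10, retain=3)

    def test_retain_by_cumulative_variance(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 6)))
        fcm = hcpc(fit_pca(df), k=2, retain=0.99, metrics=df)
        assert fcm.cumulative_variance >= 0.99 or fcm.retained == 6

    def test_row_permutation_equivariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(24, 5)))
        df.iloc[:12] += 8  # two groups
        perm = rng.permutation(24)
        f1 = hcpc(fit_pca(df), k=2, retain=5, metrics=df)
        f2 = hcpc(fit_pca(df.iloc[perm]), k=2, retain=5, metrics=df.iloc[perm])
        # canonical size-ordered labels make the assignment comparable
        l1 = f1.labels.to_numpy()[perm]
        l2 = f2.labels.to_numpy()
        assert adjusted_rand_score(l1, l2) == 1.0


class TestCharacterization:
    def test_constant_metric_eta_zero_p_one(self):
        df = pd.DataFrame({"m": np.ones(12)})
        labels = pd.Series([1] * 6 + [2] * 6)
        ch = characterize_clusters(df, labels)
        assert (ch.eta_sq == 0).all()
        assert (ch.f_p == 1.0).all()

    def test_metric_equal_to_label_eta_one(self):
        labels = pd.Series([1] * 6 + [2] * 6)
        ch = characterize_clusters(pd.DataFrame({"m": labels.astype(float)}), labels)
        assert ch.eta_sq.iloc[0] == pytest.approx(1.0)

    def test_eta_sq_equals_squared_correlation_oracle(self, rng):
        v = rng.normal(size=30)
        labels = pd.Series(rng.integers(1, 4, size=30))
        ch = characterize_clusters(pd.DataFrame({"m": v}), labels)
        # oracle: eta^2 = r^2 between metric and cluster-mean-encoded predictor
        enc = labels.map({c: v[labels == c].mean() for c in labels.unique()})
        r = np.corrcoef(v, enc)[0, 1]
        assert ch.eta_sq.iloc[0] == pytest.approx(r**2, abs=1e-9)

    def test_rows_sorted_by_eta_descending(self, rng):
        labels = pd.Series([1] * 10 + [2] * 10)
        df = pd.DataFrame(
            {"strong": np.r_[np.zeros(10), np.ones(10)], "weak": rng.normal(size=20)}
        )
        ch = characterize_clusters(df, labels)
        assert list(ch.eta_sq) == sorted(ch.eta_sq, reverse=True)


class TestTilComparison:
    def test_single_cluster_empty_table(self, rng):
        t = cluster_til_comparison(
            pd.Series(rng.poisson(20, 10)), pd.Series(np.ones(10, dtype=int))
        )
        assert t.empty

    def test_pairwise_rows_and_medians(self, rng):
        til = pd.Series(np.r_[rng.poisson(40, 15), rng.poisson(10, 15)])
        labels = pd.Series(np.r_[np.ones(15, int), np.full(15, 2)])
        t = cluster_til_comparison(til, labels)
        assert len(t) == 1
        assert t.median_a.iloc[0] > t.median_b.iloc[0]
        assert t.p.iloc[0] < 0.01


def test_newick_export_is_parseable(rng):
    df = pd.DataFrame(rng.normal(size=(8, 3)), index=[f"s{i}" for i in range(8)])
    fcm = hcpc(fit_pca(df), k=2, retain=3, metrics=df)
    nwk = linkage_to_newick(fcm.linkage, fcm.labels.index)
    skbio = pytest.importorskip("skbio")
    tree = skbio.TreeNode.read(io.StringIO(nwk))
    assert {t.name for t in tree.tips()} == set(fcm.labels.index)
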