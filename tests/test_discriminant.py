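"""DAPC fitting, contribution vectors and Mahalanobis distance tables."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wingquant.discriminant import (
    FeatureMatrix,
    contribution_vectors,
    dapc_fit,
    mahalanobis_matrix,
    md_summary,
    top_contributors,
)


def gaussian_groups(rng, means, n_each, cov=None, p=None):
    p = p if p is not None else len(means[0])
    cov = cov if cov is not None else np.eye(p)
    X, labels = [], []
    for g, mu in enumerate(means):
        X.append(rng.multivariate_normal(np.asarray(mu, dtype=float), cov, size=n_each))
        labels += [f"g{g}"] * n_each
    return FeatureMatrix(X=np.vstack(X), labels=labels)


class TestFit:
    def test_seven_groups_give_six_axes(self, rng=None):
        rng = np.random.default_rng(0)
        means = [np.r_[5.0 * np.eye(7)[g][:6], 0] for g in range(7)]
        fm = gaussian_groups(rng, means, n_each=8, p=7)
        res = dapc_fit(fm, n_pcs=7)
        assert res.n_axes == 6
        assert res.ld_scores.shape == (56, 6)
        assert res.centroids.shape == (7, 6)

    def test_two_cloud_separation_concentrates_on_axis(self):
        rng = np.random.default_rng(1)
        means = [np.zeros(6), np.r_[8.0, np.zeros(5)]]
        fm = gaussian_groups(rng, means, n_each=40)
        res = dapc_fit(fm, n_pcs=6)
        contrib = contribution_vectors(res)
        assert int(np.argmax(contrib[:, 0])) == 0
        assert contrib[0, 0] > 0.5

    def test_no_signal_means_no_separation(self):
        rng = np.random.default_rng(2)
        fm = gaussian_groups(rng, [np.zeros(5), np.zeros(5)], n_each=200)
        res = dapc_fit(fm, n_pcs=5)
        between = res.centroids.var(axis=0).sum()
        labels = np.asarray(fm.labels)
        within = np.mean(
            [res.ld_scores[labels == g].var(axis=0).sum() for g in res.groups]
        )
        assert between < within

    def test_small_cohort_reduces_retained_pcs(self):
        rng = np.random.default_rng(3)
        fm = gaussian_groups(rng, [np.zeros(30), np.ones(30)], n_each=6)
        res = dapc_fit(fm, n_pcs=50)
        assert res.n_pcs <= 11  # min(n-1, p, 50) = 11

    def test_rotation_invariance_of_scores(self):
        """An orthogonal rotation of the input leaves discriminant scores
        unchanged up to per-axis sign."""
        rng = np.random.default_rng(4)
        means = [np.zeros(5), 4 * np.eye(5)[0], 4 * np.eye(5)[1]]
        fm = gaussian_groups(rng, means, n_each=30)
        q, _ = np.linalg.qr(rng.normal(size=(5, 5)))
        fm_rot = FeatureMatrix(X=fm.X @ q.T, labels=fm.labels)
        s1 = dapc_fit(fm, n_pcs=5).ld_scores
        s2 = dapc_fit(fm_rot, n_pcs=5).ld_scores
        for j in range(s1.shape[1]):
            assert np.allclose(s1[:, j], s2[:, j], atol=1e-6) or np.allclose(
                s1[:, j], -s2[:, j], atol=1e-6
            )

    def test_needs_two_groups(self):
        fm = FeatureMatrix(X=np.random.default_rng(5).random((10, 3)), labels=["a"] * 10)
        with pytest.raises(ValueError):
            dapc_fit(fm)


class TestContributions:
    def test_columns_are_proportions(self):
        rng = np.random.default_rng(6)
        means = [np.zeros(8), 3 * np.ones(8), -3 * np.ones(8)]
        res = dapc_fit(gaussian_groups(rng, means, n_each=20), n_pcs=8)
        contrib = contribution_vectors(res)
        assert np.all(contrib >= 0)
        assert np.allclose(contrib.sum(axis=0), 1.0, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        means = [np.zeros(8), 3 * np.eye(8)[2], 3 * np.eye(8)[5]]
        res = dapc_fit(gaussian_groups(rng, means, n_each=20), n_pcs=8)
        raw = np.abs(res.pc_loadings @ res.ld_loadings)
        expected = raw / raw.sum(axis=0, keepdims=True)
        assert np.allclose(contribution_vectors(res), expected, atol=1e-12)

    def test_top_contributors_ranked(self):
        rng = np.random.default_rng(8)
        means = [np.zeros(6), 5 * np.eye(6)[3]]
        fm = gaussian_groups(rng, means, n_each=30)
        fm.catalogue = pd.DataFrame({"coef": [f"c{i}" for i in range(6)]})
        res = dapc_fit(fm, n_pcs=6)
        top = top_contributors(res, k=3)
        axis1 = top[top["axis"] == 1]
        assert list(axis1["rank"]) == [1, 2, 3]
        assert axis1.iloc[0]["coef"] == "c3"
        assert axis1["contribution"].is_monotonic_decreasing


class TestMahalanobis:
    def test_duplicated_group_distance_zero(self):
        rng = np.random.default_rng(9)
        X = rng.multivariate_normal(np.zeros(4), np.eye(4), size=40)
        fm = FeatureMatrix(X=np.vstack([X, X]), labels=["a"] * 40 + ["b"] * 40)
        res = dapc_fit(fm, n_pcs=4)
        md = mahalanobis_matrix(res)
        assert md.loc["a", "b"] == pytest.approx(0.0, abs=1e-8)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(10)
        means = [np.zeros(5), 2 * np.eye(5)[0], 4 * np.eye(5)[1], 2 * np.ones(5)]
        res = dapc_fit(gaussian_groups(rng, means, n_each=15), n_pcs=5)
        md = mahalanobis_matrix(res).to_numpy()
        assert np.allclose(md, md.T)
        assert np.all(np.diag(md) == 0)

    def test_matches_quadratic_form_oracle(self):
        rng = np.random.default_rng(11)
        means = [np.zeros(4), np.r_[3.0, 1.0, 0, 0]]
        res = dapc_fit(gaussian_groups(rng, means, n_each=50), n_pcs=4)
        md = mahalanobis_matrix(res)
        # independent textbook computation from the discriminant scores
        scores, labels = res.ld_scores, np.asarray(res.labels)
        g0, g1 = scores[labels == "g0"], scores[labels == "g1"]
        pooled = (
            (g0 - g0.mean(0)).T @ (g0 - g0.mean(0))
            + (g1 - g1.mean(0)).T @ (g1 - g1.mean(0))
        ) / (len(scores) - 2)
        d = g0.mean(0) - g1.mean(0)
        expected = np.sqrt(d @ np.linalg.inv(pooled) @ d)
        assert md.loc["g0", "g1"] == pytest.approx(expected, abs=1e-8)

    def test_affine_invariance(self):
        """MD between centroids is unchanged by an invertible linear map of
        the discriminant space when the covariance transforms with it."""
        rng = np.random.default_rng(12)
        means = [np.zeros(4), np.r_[3.0, 0, 0, 0], np.r_[0, 3.0, 0, 0]]
        res = dapc_fit(gaussian_groups(rng, means, n_each=25), n_pcs=4)
        md1 = mahalanobis_matrix(res).to_numpy()
        A = rng.normal(size=(res.n_axes, res.n_axes)) + 3 * np.eye(res.n_axes)
        res.centroids = res.centroids @ A.T
        res.within_cov = A @ res.within_cov @ A.T
        md2 = mahalanobis_matrix(res).to_numpy()
        assert np.allclose(md1, md2, atol=1e-8)


class TestSummary:
    def _tables(self, groups):
        rng = np.random.default_rng(13)
        out = {}
        for name in ("LM", "CHRM"):
            m = np.zeros((len(groups), len(groups)))
            iu = np.triu_indices(len(groups), 1)
            vals = rng.uniform(1, 6, len(iu[0]))
            m[iu] = vals
            m += m.T
            out[name] = pd.DataFrame(m, index=groups, columns=groups)
        return out

    def test_pair_count_for_seven_groups(self):
        tables = self._tables([f"g{i}" for i in range(7)])
        df = md_summary(tables)
        assert len(df) == 21 + 1  # 21 pairs + MEAN row
        assert df.iloc[-1]["pair"] == "MEAN"

    def test_single_table_mean_equals_values(self):
        tables = self._tables(["a", "b", "c"])
        df = md_summary({"LM": tables["LM"]})
        pairs = df[df["pair"] != "MEAN"]
        assert np.allclose(pairs["mean"], pairs["LM"])

    def test_threshold_annotation(self):
        groups = ["a", "b"]
        t = pd.DataFrame([[0, 2.0], [2.0, 0]], index=groups, columns=groups)
        df = md_summary({"LM": t}, threshold=3.0)
        assert df.iloc[0]["below_threshold"] == "LM"

    def test_mismatched_groups_rejected(self):
        a = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["a", "b"])
        b = pd.DataFrame(np.zeros((2, 2)), index=["a", "c"], columns=["a", "c"])
        with pytest.raises(ValueError):
            md_summary({"x": a, "y": b})
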