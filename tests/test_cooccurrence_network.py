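import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from twinmag.cooccurrence_network import (
    adjacency,
    build_network,
    cluster_taxa,
    pagerank,
    spearman_matrix,
    tom,
)


def random_adjacency(rng, n):
    A = rng.uniform(0, 1, size=(n, n))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    return pd.DataFrame(A, index=[f"f{i}" for i in range(n)], columns=[f"f{i}" for i in range(n)])


def brute_force_tom(A: np.ndarray) -> np.ndarray:
    """Direct triple-loop evaluation of the unsigned TOM formula."""
    n = len(A)
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestSpearman:
    def test_self_and_monotone_transform_correlate_one(self, rng):
        x = rng.uniform(1, 10, size=12)
        df = pd.DataFrame({"x": x, "y": np.exp(x), "z": rng.uniform(1, 10, 12)})
        rho = spearman_matrix(df, prevalence_min=0.0)
        assert rho.loc["x", "x"] == 1.0
        assert rho.loc["x", "y"] == pytest.approx(1.0)

    def test_matches_rank_then_pearson_oracle(self, rng):
        df = pd.DataFrame(rng.uniform(0, 5, size=(5, 2)), columns=["a", "b"])
        rho = spearman_matrix(df, prevalence_min=0.0)
        ra = stats.rankdata(df["a"])
        rb = stats.rankdata(df["b"])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert rho.loc["a", "b"] == pytest.approx(expected)

    def test_prevalence_filter_drops_rare_features(self, rng):
        df = pd.DataFrame(rng.uniform(1, 5, size=(20, 3)), columns=["a", "b", "rare"])
        df.loc[df.index[2:], "rare"] = 0.0  # present in 10% of 20 samples? 2/20=10% -> keep
        rho = spearman_matrix(df, prevalence_min=0.10)
        assert "rare" in rho.columns
        df.loc[df.index[1:], "rare"] = 0.0  # 5% -> drop
        rho = spearman_matrix(df, prevalence_min=0.10)
        assert "rare" not in rho.columns

    def test_too_few_survivors_rejected(self, rng):
        df = pd.DataFrame({"a": rng.uniform(1, 2, 5), "b": [0.0] * 5})
        with pytest.raises(ValueError, match="prevalence"):
            spearman_matrix(df, prevalence_min=0.10)


class TestAdjacency:
    def test_beta_one_is_absolute_rho(self, rng):
        rho = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]], index=list("ab"), columns=list("ab"))
        a = adjacency(rho, beta=1.0)
        assert a.loc["a", "b"] == 0.5
        assert a.loc["a", "a"] == 0.0

    def test_beta_two_squares_elementwise(self, rng):
        n = 4
        M = rng.uniform(-1, 1, size=(n, n))
        rho = pd.DataFrame((M + M.T) / 2)
        a1 = adjacency(rho, beta=1.0).to_numpy()
        a2 = adjacency(rho, beta=2.0).to_numpy()
        assert np.allclose(a2, a1**2)

    def test_zero_rho_zero_adjacency(self):
        rho = pd.DataFrame(np.zeros((3, 3)))
        assert (adjacency(rho).to_numpy() == 0).all()

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            adjacency(pd.DataFrame(np.eye(2)), beta=0.0)


class TestTOM:
    def test_complete_unit_graph_all_ones(self):
        n = 5
        A = pd.DataFrame(1.0 - np.eye(n))
        T = tom(A)
        assert np.allclose(T.to_numpy(), 1.0)

    def test_isolated_edge_direct_substitution(self):
        # a_01 = 1, nothing else: TOM = (0 + 1) / (min(1,1) + 1 - 1) = 1
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        T = tom(pd.DataFrame(A))
        assert T.iloc[0, 1] == pytest.approx(1.0)
        assert T.iloc[2, 3] == 0.0

    def test_matches_triple_loop_oracle(self, rng):
        for n in (5, 7, 10):
            A = random_adjacency(rng, n)
            T = tom(A).to_numpy()
            assert np.abs(T - brute_force_tom(A.to_numpy())).max() < 1e-12

    def test_bounds_and_symmetry(self, rng):
        A = random_adjacency(rng, 8)
        T = tom(A).to_numpy()
        assert (T >= 0).all() and (T <= 1 + 1e-12).all()
        assert np.allclose(T, T.T)

    def test_entries_outside_unit_interval_rejected(self):
        A = pd.DataFrame([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(ValueError):
            tom(A)


class TestClusterTaxa:
    def test_planted_blocks_recovered(self, rng):
        n = 12
        T = np.full((n, n), 0.05)
        T[:6, :6] = 0.9
        T[6:, 6:] = 0.9
        T += rng.uniform(0, 0.01, size=(n, n))
        T = (T + T.T) / 2
        np.fill_diagonal(T, 1.0)
        names = [f"f{i}" for i in range(n)]
        _, labels = cluster_taxa(pd.DataFrame(T, index=names, columns=names), n_clusters=2)
        assert labels.iloc[:6].nunique() == 1
        assert labels.iloc[6:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_identical_features_merge_first(self):
        T = np.array([[1.0, 1.0, 0.1], [1.0, 1.0, 0.1], [0.1, 0.1, 1.0]])
        Z, _ = cluster_taxa(pd.DataFrame(T), n_clusters=2)
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)  # first merge at height 0
        assert set(Z[0, :2].astype(int)) == {0, 1}

    def test_two_features_single_merge(self):
        T = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]])
        Z, labels = cluster_taxa(T, n_clusters=2)
        assert Z.shape[0] == 1
        assert labels.nunique() == 2

    def test_single_feature_rejected(self):
        with pytest.raises(ValueError):
            cluster_taxa(pd.DataFrame([[1.0]]))


class TestPageRank:
    def test_uniform_complete_graph(self):
        n = 6
        W = pd.DataFrame(1.0 - np.eye(n))
        p = pagerank(W)
        assert np.abs(p.to_numpy() - 1.0 / n).max() < 1e-9

    def test_star_hub_dominates(self):
        n = 6
        W = np.zeros((n, n))
        W[0, 1:] = W[1:, 0] = 1.0
        p = pagerank(pd.DataFrame(W))
        assert p.iloc[0] > p.iloc[1:].max()

    def test_matches_closed_form_oracle(self, rng):
        """p = (1-d)/n (I - d P^T)^{-1} 1 solved directly."""
        n = 6
        W = random_adjacency(rng, n).to_numpy()
        d = 0.85
        P = W / W.sum(axis=1, keepdims=True)
        expected = np.linalg.solve(np.eye(n) - d * P.T, np.full(n, (1 - d) / n))
        expected /= expected.sum()
        p = pagerank(pd.DataFrame(W), damping=d).to_numpy()
        assert np.abs(p - expected).max() < 1e-8

    @given(scale=st.floats(min_value=0.01, max_value=100))
    def test_scale_invariance_and_normalization(self, scale):
        rng = np.random.default_rng(3)
        W = random_adjacency(rng, 5)
        p1 = pagerank(W).to_numpy()
        p2 = pagerank(W * scale).to_numpy()
        assert abs(p1.sum() - 1.0) < 1e-9
        assert np.allclose(p1, p2, atol=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            pagerank(pd.DataFrame(np.zeros((3, 3))))


def test_build_network_end_to_end(rng):
    z = pd.DataFrame(
        rng.standard_normal((15, 6)), columns=[f"f{i}" for i in range(6)]
    )
    raw = pd.DataFrame(
        rng.uniform(1, 5, size=(15, 6)), columns=z.columns, index=z.index
    )
    net = build_network(z, prevalence_source=raw)
    assert abs(net["pagerank"].sum() - 1.0) < 1e-9
    T = net["tom"].to_numpy()
    assert np.allclose(T, T.T)
    assert net["clusters"].index.equals(net["tom"].index)
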