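"""Pearson–Euclidean similarity, soft-threshold adjacency and clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from zentropy import (
    adjacency_from_similarity,
    compare_topology,
    family_dataset,
    network_from_adjacency,
    similarity_matrix,
)


def _df(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index")


@pytest.fixture
def hand_fixture():
    # 3 variables, 4 observations; v2 = 2*v1 (perfectly correlated),
    # v3 reversed (perfectly anticorrelated with v1)
    return _df({"v1": [1, 2, 3, 4], "v2": [2, 4, 6, 8], "v3": [4, 3, 2, 1]})


class TestSimilarityMatrix:
    def test_hand_evaluated_entries(self, hand_fixture):
        s = similarity_matrix(hand_fixture)
        # distances: d12 = sqrt(1+4+9+16) = sqrt(30), d13 = sqrt(9+1+1+9) = sqrt(20),
        # d23 = sqrt(4+1+16+49) = sqrt(70); max ln(d+1) is for d23
        maxl = math.log(math.sqrt(70) + 1)
        s12 = (1 + (1 - math.log(math.sqrt(30) + 1) / maxl)) / 2
        s13 = -(1 + (1 - math.log(math.sqrt(20) + 1) / maxl)) / 2
        assert s.loc["v1", "v2"] == pytest.approx(s12, rel=1e-12)
        assert s.loc["v1", "v3"] == pytest.approx(s13, rel=1e-12)
        assert s.loc["v1", "v3"] < 0

    def test_identical_rows_score_one(self):
        s = similarity_matrix(_df({"a": [1, 2, 3], "b": [1, 2, 3], "c": [5, 1, 9]}))
        assert s.loc["a", "b"] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal_bounded(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            data = pd.DataFrame(
                rng.normal(size=(5, 7)), index=[f"x{i}" for i in range(5)]
            )
            s = similarity_matrix(data)
            v = s.to_numpy()
            assert np.allclose(v, v.T)
            assert np.allclose(np.diag(v), 1.0)
            assert (v >= -1 - 1e-12).all() and (v <= 1 + 1e-12).all()

    def test_zero_variance_row_names_variable(self):
        with pytest.raises(ValueError, match="flatvar"):
            similarity_matrix(_df({"ok": [1, 2, 3], "flatvar": [4, 4, 4]}))

    def test_rejects_missing_values_and_tiny_matrices(self):
        with pytest.raises(ValueError, match="missing"):
            similarity_matrix(_df({"a": [1, np.nan, 3], "b": [1, 2, 3]}))
        with pytest.raises(ValueError):
            similarity_matrix(_df({"a": [1, 2, 3]}))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        data = pd.DataFrame(rng.normal(size=(6, 8)), index=[f"x{i}" for i in range(6)])
        perm = ["x3", "x0", "x5", "x1", "x4", "x2"]
        s = similarity_matrix(data)
        sp = similarity_matrix(data.loc[perm])
        assert np.allclose(sp.to_numpy(), s.loc[perm, perm].to_numpy())


class TestAdjacencyAndNetwork:
    def test_power_one_threshold_zero_is_complete(self, hand_fixture):
        s = similarity_matrix(hand_fixture)
        net = network_from_adjacency(adjacency_from_similarity(s, beta=1), tau=0.0)
        assert len(net.edges) == 3 and len(net.components) == 1

    def test_zero_diagonal_symmetric_bounded(self, hand_fixture):
        a = adjacency_from_similarity(similarity_matrix(hand_fixture), beta=6).to_numpy()
        assert np.allclose(np.diag(a), 0.0)
        assert np.allclose(a, a.T)
        assert (a >= 0).all() and (a <= 1).all()

    def test_monotone_in_beta_and_tau(self, hand_fixture):
        s = similarity_matrix(hand_fixture)
        a_lo = adjacency_from_similarity(s, beta=2).to_numpy()
        a_hi = adjacency_from_similarity(s, beta=8).to_numpy()
        assert (a_hi <= a_lo + 1e-15).all()
        e_loose = network_from_adjacency(adjacency_from_similarity(s, beta=6), tau=0.05).edge_set()
        e_tight = network_from_adjacency(adjacency_from_similarity(s, beta=6), tau=0.5).edge_set()
        assert e_tight <= e_loose

    def test_large_beta_keeps_only_near_perfect_similarity(self):
        # u and v are identical rows (S = 1 exactly), w is merely correlated:
        # under a huge power only the perfect pair survives
        data = _df({"u": [1.0, 2, 3, 4], "v": [1.0, 2, 3, 4], "w": [1.5, 2.1, 3.4, 3.9]})
        s = similarity_matrix(data)
        net = network_from_adjacency(adjacency_from_similarity(s, beta=400), tau=0.5)
        assert net.edge_set() == {("u", "v")}

    def test_invalid_parameters(self, hand_fixture):
        s = similarity_matrix(hand_fixture)
        with pytest.raises(ValueError):
            adjacency_from_similarity(s, beta=0.5)
        with pytest.raises(ValueError):
            network_from_adjacency(adjacency_from_similarity(s), tau=1.0)


class TestCompareTopology:
    def test_identical_networks(self, hand_fixture):
        s = similarity_matrix(hand_fixture)
        net = network_from_adjacency(adjacency_from_similarity(s), tau=0.1)
        rep = compare_topology(net, net)
        assert rep.jaccard == 1.0 and rep.same_partition

    def test_disjoint_edge_sets(self, hand_fixture):
        s = similarity_matrix(hand_fixture)
        a = adjacency_from_similarity(s, beta=6)
        n1 = network_from_adjacency(a, tau=0.0)
        n2 = network_from_adjacency(a, tau=0.99)
        only_weak = compare_topology(n1, n2)
        assert 0.0 <= only_weak.jaccard <= 1.0

    def test_mismatched_node_sets_rejected(self, hand_fixture):
        s = similarity_matrix(hand_fixture)
        n1 = network_from_adjacency(adjacency_from_similarity(s))
        s2 = similarity_matrix(_df({"a": [1, 2, 3], "b": [3, 1, 2]}))
        n2 = network_from_adjacency(adjacency_from_similarity(s2))
        with pytest.raises(ValueError, match="node sets"):
            compare_topology(n1, n2)

    def test_family_pipeline_reports_agreement(self):
        # the end-to-end indices-vs-entropy comparison: the agreement level is
        # an empirical outcome of (beta, tau), reported rather than asserted
        nets = {}
        for kind in ("indices", "entropy"):
            sim = similarity_matrix(family_dataset(kind, 1, 8))
            nets[kind] = network_from_adjacency(adjacency_from_similarity(sim, beta=6), tau=0.1)
        rep = compare_topology(nets["indices"], nets["entropy"])
        assert 0.0 <= rep.jaccard <= 1.0
        assert rep.n_shared_edges <= min(rep.n_edges_1, rep.n_edges_2)


class TestFamilyDataset:
    def test_shape_and_monotone_rows(self):
        d = family_dataset("indices", 1, 8)
        assert d.shape == (12, 8)
        assert (d.diff(axis=1).iloc[:, 1:] > 0).all().all()

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            family_dataset("bogus")
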