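"""Connectome construction, Fisher transform, vectorization, and IO."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cpmconn import (
    Atlas,
    ConnectivityMatrix,
    EdgeVector,
    TimeSeriesMatrix,
    compute_connectome,
    devectorize,
    fisher_z,
    inverse_fisher_z,
    n_edges,
    vectorize,
)
from cpmconn.core import n_nodes_from_edges
from cpmconn.io import (
    load_dosenbach_atlas,
    read_atlas,
    read_connectome,
    read_edge_table,
    read_phenotype,
    write_connectome,
    write_edge_table,
    write_phenotype,
)


class TestFisherZ:
    @pytest.mark.parametrize("r, z", [(0.0, 0.0), (0.5, 0.5493061443340548)])
    def test_known_values(self, r, z):
        assert fisher_z(r) == pytest.approx(z, abs=1e-12)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=50, deadline=None)
    def test_odd_function_and_inverse(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)
        assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-9)

    def test_perfect_anticorrelation_is_clipped(self):
        # node_j = -node_i exactly -> r = -1 clipped to -(1 - 1e-7)
        assert fisher_z(-1.0) == pytest.approx(np.arctanh(-(1 - 1e-7)))

    def test_out_of_domain_raises(self):
        with pytest.raises(ValueError):
            fisher_z(1.001)


class TestComputeConnectome:
    def test_matches_per_pair_pearson_loop(self, rng):
        from scipy import stats
        x = rng.normal(size=(30, 8))
        cm = compute_connectome(TimeSeriesMatrix(subject_id="s", values=x))
        for i in range(8):
            for j in range(i + 1, 8):
                r = stats.pearsonr(x[:, i], x[:, j]).statistic
                assert cm.z[i, j] == pytest.approx(np.arctanh(r), abs=1e-12)

    def test_independent_columns_give_small_z(self, rng):
        T = 500
        x = rng.normal(size=(T, 20))
        cm = compute_connectome(TimeSeriesMatrix(subject_id="s", values=x))
        iu = np.triu_indices(20, 1)
        bound = 4 / np.sqrt(T - 3)  # ~4 SD of the Fisher-z null
        assert np.mean(np.abs(cm.z[iu]) < bound) > 0.99
        assert np.max(np.abs(cm.z[iu])) < 1.5 * bound

    def test_anticorrelated_pair_clipped(self):
        t = np.linspace(0, 1, 50)
        x = np.column_stack([t, -t, np.sin(7 * t)])
        cm = compute_connectome(TimeSeriesMatrix(subject_id="s", values=x))
        assert cm.z[0, 1] == pytest.approx(np.arctanh(-(1 - 1e-7)))

    def test_zero_variance_column_raises_with_node_id(self):
        x = np.random.default_rng(0).normal(size=(20, 3))
        x[:, 1] = 7.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            compute_connectome(TimeSeriesMatrix(subject_id="s", values=x))


class TestVectorization:
    def test_edge_count_160(self):
        assert n_edges(160) == 12720

    def test_three_node_ordering(self):
        a, b, c = 0.1, -0.2, 0.3
        z = np.array([[0, a, b], [a, 0, c], [b, c, 0]])
        v = vectorize(ConnectivityMatrix(subject_id="s", z=z))
        assert np.array_equal(v.values, [a, b, c])

    @given(st.integers(2, 60))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_bijection(self, n):
        rng = np.random.default_rng(n)
        z = rng.normal(size=(n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        cm = ConnectivityMatrix(subject_id="s", z=z)
        assert np.array_equal(devectorize(vectorize(cm)).z, cm.z)
        assert n_nodes_from_edges(n_edges(n)) == n

    def test_wrong_length_raises(self):
        with pytest.raises(ValueError):
            EdgeVector(subject_id="s", values=np.zeros(7), n_nodes=4)


class TestAtlas:
    def test_bundled_160_node_atlas(self):
        atlas = load_dosenbach_atlas()
        assert atlas.n_nodes == 160
        assert len(atlas.networks) == 6

    def test_toy_atlas_round_trip(self, tmp_path):
        t = pd.DataFrame({
            "node_id": [1, 2, 3, 4], "label": list("abcd"),
            "network": ["A", "A", "B", "B"],
            "x": [0.0, 1, 2, 3], "y": [0.0] * 4, "z": [0.0] * 4,
        })
        t.to_csv(tmp_path / "atlas.csv", index=False)
        atlas = read_atlas(tmp_path / "atlas.csv")
        assert atlas.n_nodes == 4
        assert atlas.networks == ["A", "B"]

    def test_duplicate_node_id_raises(self):
        t = pd.DataFrame({
            "node_id": [1, 1], "label": ["a", "b"], "network": ["A", "A"],
            "x": [0.0, 1], "y": [0.0, 0], "z": [0.0, 0],
        })
        with pytest.raises(ValueError, match="duplicate"):
            Atlas(table=t)


class TestIO:
    def test_connectome_round_trip_bit_identical(self, tmp_path, rng):
        z = rng.normal(size=(12, 12))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        cm = ConnectivityMatrix(subject_id="s1", z=z)
        write_connectome(cm, tmp_path / "s1.txt")
        back = read_connectome(tmp_path / "s1.txt")
        assert np.array_equal(back.z, cm.z)
        assert back.subject_id == "s1"

    def test_non_square_matrix_raises(self, tmp_path):
        np.savetxt(tmp_path / "bad.txt", np.zeros((2, 3)))
        with pytest.raises(ValueError, match="square"):
            read_connectome(tmp_path / "bad.txt")

    def test_edge_table_round_trip(self, tmp_path, rng):
        edges = rng.normal(size=(3, 10))
        write_edge_table(["a", "b", "c"], edges, tmp_path / "e.csv")
        ids, back = read_edge_table(tmp_path / "e.csv")
        assert ids == ["a", "b", "c"]
        assert np.array_equal(back, edges)

    def test_phenotype_round_trip(self, tmp_path, tiny_pheno):
        write_phenotype(tiny_pheno, tmp_path / "p.csv")
        back = read_phenotype(tmp_path / "p.csv")
        assert len(back) == 6
        assert back["score_total"].isna().sum() == 1

    def test_edge_list_of_two_edge_mask(self, tmp_path):
        from cpmconn.io import read_edge_list, write_edge_list
        m = np.zeros((4, 4), dtype=int)
        m[0, 2] = m[2, 0] = 1
        m[1, 3] = m[3, 1] = -1
        write_edge_list(m, tmp_path / "el.csv")
        t = pd.read_csv(tmp_path / "el.csv")
        assert len(t) == 2
        assert np.array_equal(read_edge_list(tmp_path / "el.csv", 4), m)
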