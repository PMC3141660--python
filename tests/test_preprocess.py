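import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from quartetdist import parse_newick, shared_leaf_map
from quartetdist.preprocess import (
    ArithmeticCapacityError,
    NodePairTables,
    _exact_matmul,
    build_intersection_table,
    build_node_pair_tables,
    choose_product_side,
    compute_product_aggregates,
)
from quartetdist.synthgen import generate

from conftest import BUTTERFLY_AB_CD, BUTTERFLY_AC_BD, internal_node_with_leaf_neighbors

small_matrices = arrays(
    np.int64,
    st.tuples(st.integers(2, 6), st.integers(2, 6)),
    elements=st.integers(0, 5),
)


def _table(text1, text2):
    t1, t2 = parse_newick(text1), parse_newick(text2)
    return t1, t2, build_intersection_table(t1, t2, shared_leaf_map(t1, t2))


class TestIntersectionTable:
    def test_identical_butterflies(self):
        t1, t2, tab = _table(BUTTERFLY_AB_CD, BUTTERFLY_AB_CD)
        v = internal_node_with_leaf_neighbors(t1, {"c", "d"})
        vp = internal_node_with_leaf_neighbors(t2, {"c", "d"})
        # component behind the edge into the cd-node is {a,b} in both trees
        i = next(k for k, u in enumerate(t1.adj[v]) if u not in t1.labels)
        j = next(k for k, u in enumerate(t2.adj[vp]) if u not in t2.labels)
        assert tab.component_pair_count(v, i, vp, j) == 2

    def test_crossing_butterflies(self):
        t1, t2, tab = _table(BUTTERFLY_AB_CD, BUTTERFLY_AC_BD)
        v = internal_node_with_leaf_neighbors(t1, {"c", "d"})
        vp = internal_node_with_leaf_neighbors(t2, {"b", "d"})
        i = next(k for k, u in enumerate(t1.adj[v]) if u not in t1.labels)
        j = next(k for k, u in enumerate(t2.adj[vp]) if u not in t2.labels)
        # {a,b} vs {a,c}
        assert tab.component_pair_count(v, i, vp, j) == 1

    def test_containment_in_full_leaf_set(self):
        t1, t2, tab = _table(BUTTERFLY_AB_CD, "(a,b,c,d);")
        hub = t2.internal_nodes[0]
        for v in t1.internal_nodes:
            for i in range(t1.degree(v)):
                _, _, size = tab.component_descriptor(1, v, i)
                # G = any single leaf's complement-free subtree: use each
                # component of the star hub, then sum = |F| over all of them
                total = sum(
                    tab.component_pair_count(v, i, hub, j)
                    for j in range(t2.degree(hub))
                )
                assert total == size

    def test_complement_identity_random_audit(self, rng):
        t1 = generate("general", 18, seed=3)
        t2 = generate("general", 18, seed=4)
        tab = build_intersection_table(t1, t2, shared_leaf_map(t1, t2))
        edges1 = list(t1.directed_inner_edges())
        edges2 = list(t2.directed_inner_edges())
        for _ in range(50):
            e1 = edges1[rng.integers(len(edges1))]
            e2 = edges2[rng.integers(len(edges2))]
            front = tab.front_count(e1, e2)
            k2, eps2, g_size = tab.component_descriptor(2, e2.target, e2.behind_index)
            k1, eps1, _ = tab.component_descriptor(1, e1.target, e1.behind_index)
            behind_front = tab._pair_count(k1, eps1, k2, 1 - eps2)
            # |F ∩ G| + |F̄ ∩ G| = |G| with G the front of e2
            assert front + behind_front == tab.n - g_size

    def test_bounds(self, rng):
        t1 = generate("binary", 15, seed=1)
        t2 = generate("sqrt_hub", 15, seed=2)
        tab = build_intersection_table(t1, t2, shared_leaf_map(t1, t2))
        for v in t1.internal_nodes:
            for vp in t2.internal_nodes:
                I = tab.node_pair_matrix(v, vp)
                assert (I >= 0).all()
                assert I.sum() == 15


class TestNodePairTables:
    def test_identical_butterfly_matrix(self):
        t1, t2, tab = _table(BUTTERFLY_AB_CD, BUTTERFLY_AB_CD)
        v = internal_node_with_leaf_neighbors(t1, {"c", "d"})
        vp = internal_node_with_leaf_neighbors(t2, {"c", "d"})
        npt = build_node_pair_tables(v, vp, tab)
        assert npt.I.tolist() == [[2, 0, 0], [0, 1, 0], [0, 0, 1]]
        assert npt.R.tolist() == [2, 1, 1]
        assert npt.C.tolist() == [2, 1, 1]
        assert npt.M == 4

    def test_crossing_butterfly_matrix(self):
        t1, t2, tab = _table(BUTTERFLY_AB_CD, BUTTERFLY_AC_BD)
        v = internal_node_with_leaf_neighbors(t1, {"c", "d"})
        vp = internal_node_with_leaf_neighbors(t2, {"b", "d"})
        npt = build_node_pair_tables(v, vp, tab)
        assert npt.I.tolist() == [[1, 1, 0], [1, 0, 0], [0, 0, 1]]
        assert npt.M == 4

    def test_total_is_leaf_count_everywhere(self):
        t1 = generate("general", 20, seed=11)
        t2 = generate("sqrt_hub", 20, seed=12)
        tab = build_intersection_table(t1, t2, shared_leaf_map(t1, t2))
        for v in t1.internal_nodes:
            for vp in t2.internal_nodes:
                npt = build_node_pair_tables(v, vp, tab)
                assert npt.M == 20
                assert npt.R.sum() == npt.C.sum() == npt.M

    @given(I=small_matrices)
    def test_aggregates_match_definitions(self, I):
        npt = NodePairTables.from_matrix(I)
        assert (npt.I2 == I * I).all()
        assert npt.SQ == int((I * I).sum())
        assert npt.SR2 == int((I.sum(1) ** 2).sum())
        assert (npt.RI_col == I.sum(1) @ I).all()
        assert (npt.CI_row == I @ I.sum(0)).all()


class TestProducts:
    @pytest.mark.parametrize(
        "dims,expected",
        [((3, 100), "left"), ((100, 3), "right"), ((5, 5), "left")],
    )
    def test_choose_product_side(self, dims, expected):
        assert choose_product_side(*dims) == expected

    def test_hand_multiplied_examples(self):
        npt = NodePairTables.from_matrix([[1, 1, 0], [1, 0, 0], [0, 0, 1]])
        compute_product_aggregates(npt, side="left")
        assert npt.gram[0, 0] == 2 and npt.gram[0, 1] == 1 and npt.gram[2, 2] == 1
        assert (npt.sq_gram == npt.gram).all()  # entries are 0/1 so I' == I
        diag = NodePairTables.from_matrix([[2, 0, 0], [0, 1, 0], [0, 0, 1]])
        compute_product_aggregates(diag, side="left")
        assert (diag.gram == np.diag([4, 1, 1])).all()

    @given(I=small_matrices)
    def test_products_equal_explicit_contraction(self, I):
        left = compute_product_aggregates(NodePairTables.from_matrix(I), "left")
        right = compute_product_aggregates(NodePairTables.from_matrix(I), "right")
        assert (left.gram == I @ I.T).all()
        assert (left.sq_gram == (I * I) @ I.T).all()
        assert (right.gram == I.T @ I).all()
        assert (right.sq_gram == I.T @ (I * I)).all()
        # both association orders yield the same triple product
        assert (left.triple == I @ I.T @ I).all()
        assert (right.triple == left.triple).all()

    def test_exact_matmul_beyond_double_precision(self):
        big = np.array([[2**31]], dtype=np.int64)
        assert _exact_matmul(big, big)[0, 0] == 2**62
        huge = np.array([[2**32]], dtype=np.int64)
        with pytest.raises(ArithmeticCapacityError):
            _exact_matmul(huge, huge)
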