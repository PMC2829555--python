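"""Identity/similarity computation, distance conversion and neighbor
joining, with forward-constructed additive trees as the oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from mipkit.io import ProteinRecord
from mipkit.phylo import (
    identity_matrix,
    nj_tree,
    pairwise_identity,
    to_distance,
    tree_distance_matrix,
    tree_to_newick,
)
from mipkit.simulate import BUILTIN_SPECS, generate_family


# ---------------------------------------------------------------------------
# Oracle helpers: random additive trees built by sequential leaf insertion
# ---------------------------------------------------------------------------

def random_tree_edges(n: int, rng) -> tuple[list[tuple[int, int]], dict]:
    """An unrooted binary tree on leaves 0..n-1 as (edge list, lengths)."""
    edges = [(0, n), (1, n), (2, n)]  # internal nodes numbered from n
    next_node = n + 1
    for leaf in range(3, n):
        i = rng.integers(0, len(edges))
        u, v = edges.pop(int(i))
        w = next_node
        next_node += 1
        edges += [(u, w), (v, w), (leaf, w)]
    lengths = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
    return edges, lengths


def path_distance_matrix(n: int, edges, lengths) -> np.ndarray:
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_edge(*e, weight=lengths[e])
    d = np.zeros((n, n))
    for i in range(n):
        dist = nx.single_source_dijkstra_path_length(g, i)
        for j in range(n):
            d[i, j] = dist[j]
    return (d + d.T) / 2.0  # exact symmetry despite summation order


def all_five_taxon_topologies():
    """The 15 unrooted binary topologies on 5 labelled leaves."""
    trees = [[(0, 5), (1, 5), (2, 5)]]
    for leaf in (3, 4):
        nxt = []
        for edges in trees:
            new_node = max(max(e) for e in edges) + 1
            for k in range(len(edges)):
                e = list(edges)
                u, v = e.pop(k)
                nxt.append(e + [(u, new_node), (v, new_node),
                                (leaf, new_node)])
        trees = nxt
    assert len(trees) == 15
    return trees


def fits_additively(edges, d: np.ndarray, n: int) -> bool:
    """Least-squares branch fit; True when the topology fits d exactly."""
    pairs = list(itertools.combinations(range(n), 2))
    import networkx as nx

    g = nx.Graph()
    g.add_edges_from(edges)
    a = np.zeros((len(pairs), len(edges)))
    idx = {frozenset(e): k for k, e in enumerate(edges)}
    for row, (i, j) in enumerate(pairs):
        path = nx.shortest_path(g, i, j)
        for u, v in zip(path, path[1:]):
            a[row, idx[frozenset((u, v))]] = 1.0
    b = np.array([d[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(a, b, rcond=None)
    return bool(np.allclose(a @ x, b, atol=1e-8) and (x > 0).all())


# ---------------------------------------------------------------------------
# Identity
# ---------------------------------------------------------------------------

class TestPairwiseIdentity:
    def test_identical_sequences_are_100_100(self):
        a = ProteinRecord("a", "MNPAVLLGW")
        b = ProteinRecord("b", "MNPAVLLGW")
        res = pairwise_identity(a, b)
        assert res.identity_percent == 100.0
        assert res.similarity_percent == 100.0

    def test_gapless_positional_four_of_five(self):
        res = pairwise_identity(ProteinRecord("a", "MNPAV"),
                                ProteinRecord("b", "MNPAL"),
                                mode="gapless-positional")
        assert res.identity_percent == pytest.approx(80.0)
        # V/L is a positive BLOSUM62 substitution -> similar
        assert res.similarity_percent == pytest.approx(100.0)

    def test_gapless_requires_equal_lengths(self):
        with pytest.raises(ValueError, match="equal lengths"):
            pairwise_identity(ProteinRecord("a", "MNPAV"),
                              ProteinRecord("b", "MNPA"),
                              mode="gapless-positional")

    def test_terminal_gaps_excluded_from_denominator(self):
        # query is an exact N-truncated copy: identity must be 100
        recs, _ = generate_family(BUILTIN_SPECS["glp"], 1, 0.0, seed=0)
        full = recs[0]
        trunc = ProteinRecord("t", full.residues[15:])
        res = pairwise_identity(full, trunc)
        assert res.identity_percent == pytest.approx(100.0)

    def test_symmetry_and_self_identity(self):
        recs, _ = generate_family(BUILTIN_SPECS["water-selective"], 6, 0.3,
                                  seed=13)
        for a, b in itertools.combinations(recs, 2):
            ab = pairwise_identity(a, b).identity_percent
            ba = pairwise_identity(b, a).identity_percent
            assert ab == pytest.approx(ba, abs=1e-9)
        for r in recs:
            assert pairwise_identity(r, r).identity_percent == 100.0


class TestIdentityMatrix:
    def test_identical_triplet_gives_all_100(self):
        recs = [ProteinRecord(f"s{i}", "MNPAVW" * 12) for i in range(3)]
        ident, simil = identity_matrix(recs)
        assert (ident.to_numpy() == 100.0).all()
        assert (simil.to_numpy() == 100.0).all()

    def test_symmetric_with_diagonal_100(self):
        recs, _ = generate_family(BUILTIN_SPECS["glp"], 6, 0.25, seed=2)
        ident, _ = identity_matrix(recs)
        arr = ident.to_numpy()
        assert np.allclose(arr, arr.T)
        assert np.allclose(np.diag(arr), 100.0)

    def test_duplicate_ids_rejected(self):
        recs = [ProteinRecord("same", "MNPAV"), ProteinRecord("same", "MNPAL")]
        with pytest.raises(ValueError, match="duplicate"):
            identity_matrix(recs)


class TestDistances:
    def test_p_distance_and_poisson_values(self):
        ident = pd.DataFrame([[100.0, 50.0], [50.0, 100.0]],
                             index=["a", "b"], columns=["a", "b"])
        p = to_distance(ident, "p-distance")
        assert p["a", "b"] == pytest.approx(0.5)
        pois = to_distance(ident, "poisson")
        assert pois["a", "b"] == pytest.approx(np.log(2))
        assert p["a", "a"] == 0.0

    def test_poisson_rejects_zero_identity(self):
        ident = pd.DataFrame([[100.0, 0.0], [0.0, 100.0]],
                             index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="Poisson"):
            to_distance(ident, "poisson")


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]),
                            ids=list("abc"))
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match=">=3"):
            nj_tree(DistanceMatrix(np.array([[0, 1], [1, 0.0]]), ids=list("ab")))

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        rng = np.random.default_rng(7)
        edges, lengths = random_tree_edges(4, rng)
        d = path_distance_matrix(4, edges, lengths)
        tree = nj_tree(DistanceMatrix(d, ids=list("abcd")))
        got = tree_distance_matrix(tree).loc[list("abcd"), list("abcd")]
        assert np.allclose(got.to_numpy(), d, atol=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6, 7, 8])
    def test_additive_recovery_for_growing_taxon_sets(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            edges, lengths = random_tree_edges(n, rng)
            d = path_distance_matrix(n, edges, lengths)
            ids = [f"t{i}" for i in range(n)]
            tree = nj_tree(DistanceMatrix(d, ids=ids))
            got = tree_distance_matrix(tree).loc[ids, ids]
            assert np.allclose(got.to_numpy(), d, atol=1e-9)

    def test_five_taxon_topology_against_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        edges, lengths = random_tree_edges(5, rng)
        d = path_distance_matrix(5, edges, lengths)
        fitting = [t for t in all_five_taxon_topologies()
                   if fits_additively(t, d, 5)]
        assert len(fitting) == 1  # the generating topology is unique
        ids = [str(i) for i in range(5)]
        tree = nj_tree(DistanceMatrix(d, ids=ids))
        got = tree_distance_matrix(tree).loc[ids, ids]
        assert np.allclose(got.to_numpy(), d, atol=1e-9)

    def test_label_permutation_leaves_tree_invariant(self):
        rng = np.random.default_rng(5)
        edges, lengths = random_tree_edges(6, rng)
        d = path_distance_matrix(6, edges, lengths)
        ids = [f"x{i}" for i in range(6)]
        t1 = nj_tree(DistanceMatrix(d, ids=ids))
        perm = rng.permutation(6)
        t2 = nj_tree(DistanceMatrix(d[np.ix_(perm, perm)],
                                    ids=[ids[i] for i in perm]))
        m1 = tree_distance_matrix(t1).loc[ids, ids].to_numpy()
        m2 = tree_distance_matrix(t2).loc[ids, ids].to_numpy()
        assert np.allclose(m1, m2, atol=1e-9)
        total1 = sum(node.length or 0 for node in t1.traverse())
        total2 = sum(node.length or 0 for node in t2.traverse())
        assert total1 == pytest.approx(total2)

    def test_agrees_with_library_nj_on_noisy_matrix(self):
        # independent cross-check against scikit-bio's implementation
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(17)
        edges, lengths = random_tree_edges(7, rng)
        d = path_distance_matrix(7, edges, lengths)
        noise = rng.uniform(0, 0.01, d.shape)
        d_noisy = d + (noise + noise.T) / 2
        np.fill_diagonal(d_noisy, 0.0)
        ids = [f"t{i}" for i in range(7)]
        ours = tree_distance_matrix(
            nj_tree(DistanceMatrix(d_noisy, ids=ids))).loc[ids, ids]
        theirs_tree = skbio_nj(DistanceMatrix(d_noisy, ids=ids))
        theirs = tree_distance_matrix(theirs_tree).loc[ids, ids]
        assert np.allclose(ours.to_numpy(), theirs.to_numpy(), atol=1e-6)

    def test_newick_roundtrip_lossless(self):
        import io as stdio

        from skbio import TreeNode

        rng = np.random.default_rng(3)
        edges, lengths = random_tree_edges(5, rng)
        d = path_distance_matrix(5, edges, lengths)
        ids = [f"leaf{i}" for i in range(5)]
        tree = nj_tree(DistanceMatrix(d, ids=ids))
        nwk = tree_to_newick(tree)
        back = TreeNode.read(stdio.StringIO(nwk))
        assert {t.name for t in back.tips()} == set(ids)
        m = tree_distance_matrix(back).loc[ids, ids]
        assert np.allclose(m.to_numpy(), d, atol=1e-9)

    def test_negative_branch_estimates_clamped_and_flagged(self):
        d = np.array([
            [0.0, 0.1, 0.6, 0.6],
            [0.1, 0.0, 0.65, 0.1],
            [0.6, 0.65, 0.0, 0.7],
            [0.6, 0.1, 0.7, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(d, ids=list("abcd")))
        assert tree.negative_branches_clamped >= 1
        for node in tree.traverse():
            if node.length is not None:
                assert node.length >= 0.0
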