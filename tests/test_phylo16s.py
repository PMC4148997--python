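"""16S identity threshold, distance matrices, neighbor joining, bootstrap."""

import dendropy
import numpy as np
import pytest

from agios.phylo16s import (
    VERDICT_NEW_SPECIES,
    VERDICT_SAME_SPECIES,
    DistanceMatrix,
    MultipleAlignment,
    bootstrap_support,
    distance_matrix,
    neighbor_joining,
    p_distance_matrix,
    pairwise_identity_16s,
)
from agios.synth_data import evolve_marker_along_tree
from oracles import least_squares_quartet, random_additive_quartet

FIVE_TAXON_NEWICK = "((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05,E:0.1);"


def _leaf_lengths(tree):
    return {leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()}


def _splits(tree):
    """Internal edges as frozensets of the leaf labels on the child side."""
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        labels = frozenset(l.taxon.label for l in node.leaf_iter())
        out[labels] = node.edge.length
    return out


class TestIdentity16S:
    def test_identical_sequences(self):
        seq = "ACGT" * 30
        ident, verdict = pairwise_identity_16s(seq, seq)
        assert (ident, verdict) == (100.0, VERDICT_SAME_SPECIES)

    def test_two_mismatches_in_100(self):
        a = "ACGT" * 25
        b = a[:10] + "C" + a[11:70] + "A" + a[71:]  # G→C at 10, T→A at 70
        ident, verdict = pairwise_identity_16s(a, b)
        assert ident == 98.0
        assert verdict == VERDICT_NEW_SPECIES

    def test_threshold_is_inclusive_above(self):
        a = "ACGT" * 250  # 1000 nt; 13 mismatches → exactly 98.7%
        b = list(a)
        for k in range(13):
            pos = 4 * k
            b[pos] = "C" if a[pos] != "C" else "G"
        ident, verdict = pairwise_identity_16s(a, "".join(b))
        assert ident == 98.7
        assert verdict == VERDICT_SAME_SPECIES

    def test_empty_input(self):
        with pytest.raises(ValueError, match="empty input"):
            pairwise_identity_16s("", "ACGT")


class TestDistances:
    def test_identical_rows_and_direct_count(self):
        msa = MultipleAlignment(("a", "b"), ("ACGT", "ACGA"))
        assert p_distance_matrix(msa).d[0, 1] == 0.25
        same = MultipleAlignment(("a", "b"), ("ACGT", "ACGT"))
        assert p_distance_matrix(same).d[0, 1] == 0.0

    def test_pairwise_deletion_of_gap_columns(self):
        msa = MultipleAlignment(("a", "b"), ("AC-T", "ACGT"))
        assert p_distance_matrix(msa).d[0, 1] == 0.0

    def test_n_columns_are_deleted_too(self):
        msa = MultipleAlignment(("a", "b"), ("ANGT", "ACGA"))
        assert p_distance_matrix(msa).d[0, 1] == pytest.approx(1 / 3)

    def test_no_overlap(self):
        msa = MultipleAlignment(("a", "b"), ("AC--", "--GT"))
        with pytest.raises(ValueError, match="no overlap"):
            p_distance_matrix(msa)

    def test_jc69_exceeds_p(self):
        msa = MultipleAlignment(("a", "b"), ("ACGTACGTAC", "ACGTACGTGG"))
        p = distance_matrix(msa, "p").d[0, 1]
        assert distance_matrix(msa, "jc69").d[0, 1] > p
        assert distance_matrix(msa, "k2p").d[0, 1] > p


class TestNeighborJoining:
    def test_textbook_quartet_recovered_exactly(self):
        D = DistanceMatrix(
            ("A", "B", "C", "D"),
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
            ),
        )
        tree = neighbor_joining(D)
        assert _splits(tree) == {frozenset({"A", "B"}): pytest.approx(1.0)}
        assert _leaf_lengths(tree) == {
            "A": pytest.approx(1.0),
            "B": pytest.approx(2.0),
            "C": pytest.approx(3.0),
            "D": pytest.approx(4.0),
        }

    def test_two_taxa_bisection(self):
        D = DistanceMatrix(("A", "B"), np.array([[0, 0.4], [0.4, 0]]))
        assert _leaf_lengths(neighbor_joining(D)) == {
            "A": pytest.approx(0.2),
            "B": pytest.approx(0.2),
        }

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
        assert _leaf_lengths(tree) == {
            "A": pytest.approx((0.3 + 0.5 - 0.6) / 2),
            "B": pytest.approx((0.3 + 0.6 - 0.5) / 2),
            "C": pytest.approx((0.5 + 0.6 - 0.3) / 2),
        }

    def test_additive_quartets_match_least_squares_oracle(self):
        """On additive matrices NJ recovers the generating topology and
        branch lengths exactly; cross-checked against the LS oracle."""
        rng = np.random.default_rng(7)
        taxa = ("t0", "t1", "t2", "t3")
        for _ in range(10):
            split, lengths, D = random_additive_quartet(rng)
            oracle_split, oracle_lengths, rss = least_squares_quartet(D)
            assert oracle_split == split and rss < 1e-18
            tree = neighbor_joining(DistanceMatrix(taxa, D))
            (clade, internal) = next(iter(_splits(tree).items()))
            assert clade in (
                frozenset(f"t{i}" for i in split[0]),
                frozenset(f"t{i}" for i in split[1]),
            )
            assert internal == pytest.approx(lengths[4], abs=1e-9)
            leaf = _leaf_lengths(tree)
            for i in range(4):
                assert leaf[f"t{i}"] == pytest.approx(lengths[i], abs=1e-9)

    def test_topology_matches_scikit_bio(self):
        """Independent implementation cross-check on a non-additive matrix."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(11)
        n = 6
        d = rng.uniform(0.1, 1.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        taxa = tuple(f"s{i}" for i in range(n))
        mine = set(_splits(neighbor_joining(DistanceMatrix(taxa, d))))
        sk_tree = skbio_nj(skbio.DistanceMatrix(d, ids=list(taxa)))
        theirs = set()
        for node in sk_tree.non_tips():
            labels = frozenset(t.name for t in node.tips())
            if 1 < len(labels) < n - 1:
                theirs.add(labels)
        full = set(taxa)
        mine_norm = {min(s, frozenset(full - s), key=sorted) for s in mine if 1 < len(s) < n - 1}
        theirs_norm = {min(s, frozenset(full - s), key=sorted) for s in theirs}
        assert mine_norm == theirs_norm

    def test_invalid_distances_rejected(self):
        with pytest.raises(ValueError, match="invalid distances"):
            DistanceMatrix(("A", "B"), np.array([[0, -1.0], [-1.0, 0]]))
        with pytest.raises(ValueError, match="invalid distances"):
            DistanceMatrix(("A", "B"), np.array([[0, 1.0], [2.0, 0]]))


@pytest.fixture(scope="module")
def msa():
    tree = dendropy.Tree.get(data=FIVE_TAXON_NEWICK, schema="newick")
    alignment, _ = evolve_marker_along_tree(tree, 1000, 1.0, seed=21)
    return alignment


class TestBootstrap:
    def test_deterministic_for_a_seed(self, msa):
        t1 = bootstrap_support(msa, 30, seed=5)
        t2 = bootstrap_support(msa, 30, seed=5)
        assert _supports(t1) == _supports(t2)

    def test_clear_signal_gets_high_support(self, msa):
        supports = _supports(bootstrap_support(msa, 50, seed=6))
        truth = {frozenset({"A", "B"}), frozenset({"C", "D"})}
        full = set(msa.taxa)
        normalized = {
            min(k, frozenset(full - k), key=lambda s: (len(s), sorted(s))): v
            for k, v in supports.items()
        }
        for clade in truth:
            assert normalized[clade] >= 90

    def test_supports_invariant_under_taxon_permutation(self, msa):
        perm = [3, 1, 4, 0, 2]
        shuffled = MultipleAlignment(
            tuple(msa.taxa[i] for i in perm), tuple(msa.rows[i] for i in perm)
        )
        full = set(msa.taxa)
        norm = lambda sup: {
            min(k, frozenset(full - k), key=sorted): v for k, v in sup.items()
        }
        assert norm(_supports(bootstrap_support(msa, 25, seed=9))) == norm(
            _supports(bootstrap_support(shuffled, 25, seed=9))
        )

    def test_identical_rows_degenerate(self):
        msa = MultipleAlignment(("a", "b", "c", "d"), ("ACGT",) * 4)
        with pytest.raises(ValueError, match="no resolved bipartitions"):
            bootstrap_support(msa, 10, seed=1)

    def test_invalid_replicate_count(self, msa):
        with pytest.raises(ValueError, match="invalid replicate count"):
            bootstrap_support(msa, 0, seed=1)

    def test_newick_round_trip_preserves_supports_and_lengths(self, msa):
        tree = bootstrap_support(msa, 20, seed=3)
        text = tree.as_string(schema="newick", suppress_rooting=True)
        back = dendropy.Tree.get(data=text, schema="newick")
        assert _splits_rounded(back) == _splits_rounded(tree)
        back_supports = {
            frozenset(l.taxon.label for l in node.leaf_iter()): int(node.label)
            for node in back.preorder_node_iter()
            if node is not back.seed_node and not node.is_leaf() and node.label
        }
        assert back_supports == _supports(tree)


def _supports(tree):
    return {
        frozenset(l.taxon.label for l in node.leaf_iter()): node.support
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node and not node.is_leaf()
    }


def _splits_rounded(tree):
    out = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        labels = frozenset(l.taxon.label for l in node.leaf_iter())
        out[labels] = round(node.edge.length, 6)
    return out
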