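"""Distances, neighbor joining, bootstrap and Newick round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrcat.phylogenetics import (
    DistanceMatrix,
    bootstrap_support,
    msa_nj_builder,
    nj_tree,
    p_distance,
    poisson_correct,
    poisson_distance,
    read_newick,
    same_topology,
    tree_splits,
    write_newick,
)
from nrcat.seqcore import ALPHABET, MSA
from conftest import random_peptide


class TestPDistance:
    def test_identical_rows_are_zero(self):
        msa = MSA(("a", "b"), ("MKVL", "MKVL"))
        assert p_distance(msa).matrix[0, 1] == 0.0

    def test_one_in_four_differs(self):
        msa = MSA(("a", "b"), ("AAAA", "AAAT"))
        assert p_distance(msa).matrix[0, 1] == 0.25

    def test_pairwise_deletion_compares_three_sites(self):
        msa = MSA(("a", "b"), ("A-AA", "AAAA"))
        # 3 comparable columns, all equal
        assert p_distance(msa, "pairwise").matrix[0, 1] == 0.0

    def test_complete_deletion_drops_any_gap_column(self):
        msa = MSA(("a", "b", "c"), ("A-AT", "AAAT", "AAAA"))
        dm = p_distance(msa, "complete")
        # column 2 dropped everywhere; rows a,b compare 3 sites, 1 differs...
        assert dm.matrix[0, 2] == pytest.approx(1 / 3)

    def test_no_comparable_sites_is_an_error(self):
        msa = MSA(("a", "b"), ("A--", "-AA"))
        with pytest.raises(ValueError, match="comparable"):
            p_distance(msa)


class TestPoisson:
    def test_zero_maps_to_zero(self):
        assert poisson_distance(0.0) == 0.0

    def test_half_maps_to_ln2(self):
        assert poisson_distance(0.5) == pytest.approx(0.6931, abs=5e-5)

    def test_saturation_rejected(self):
        with pytest.raises(ValueError):
            poisson_distance(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0, 0.999))
    def test_correction_never_below_p(self, p):
        assert poisson_distance(p) >= p


def _tree_distances(parent, lengths, taxa):
    """Path-length matrix of a tree given as parent pointers."""
    n = len(taxa)
    # build adjacency
    adj = {}
    for child, par in parent.items():
        adj.setdefault(child, {})[par] = lengths[child]
        adj.setdefault(par, {})[child] = lengths[child]
    import heapq

    D = np.zeros((n, n))
    for i, src in enumerate(taxa):
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, u = heapq.heappop(heap)
            if d > dist.get(u, np.inf):
                continue
            for v, w in adj.get(u, {}).items():
                nd = d + w
                if nd < dist.get(v, np.inf):
                    dist[v] = nd
                    heapq.heappush(heap, (nd, v))
        for j, dst in enumerate(taxa):
            D[i, j] = dist[dst]
    return D


def _enumerate_topologies(n_taxa):
    """All unrooted binary topologies over t0..t{n-1} as parent-pointer
    maps (edges carry no lengths yet): 3 for 4 taxa, 15 for 5."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    shapes = [({t: "c0" for t in taxa[:3]}, 1)]
    for t in taxa[3:]:
        grown = []
        for parent, internal in shapes:
            for child in list(parent):
                new_parent = dict(parent)
                node = f"c{internal}"
                par = new_parent[child]
                new_parent[child] = node
                new_parent[node] = par
                new_parent[t] = node
                grown.append((new_parent, internal + 1))
        shapes = grown
    return [p for p, _ in shapes], taxa


def _random_additive_tree(n_taxa, rng):
    """Random unrooted binary tree over taxa t0..t{n-1} with branch lengths
    in [0.1, 1]; returns (parent, lengths, taxa)."""
    shapes, taxa = _enumerate_topologies(n_taxa)
    parent = shapes[int(rng.integers(0, len(shapes)))]
    lengths = {node: float(rng.uniform(0.1, 1.0)) for node in parent}
    return parent, lengths, taxa


def _true_splits(parent, taxa):
    children = {}
    for c, p in parent.items():
        children.setdefault(p, []).append(c)

    def tips_below(node):
        if node not in children:
            return {node}
        out = set()
        for c in children[node]:
            out |= tips_below(c)
        return out

    anchor = sorted(taxa)[0]
    full = set(taxa)
    splits = set()
    for node in children:
        below = tips_below(node)
        if node == "c0" or below == full:
            continue
        side = full - below if anchor in below else below
        if 1 < len(side) < len(full) - 1:
            splits.add(frozenset(side))
    return splits


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        )
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(2.0, abs=1e-9)
        assert lengths["B"] == pytest.approx(3.0, abs=1e-9)
        assert lengths["C"] == pytest.approx(7.0, abs=1e-9)

    def test_four_taxon_additive_matrix_recovered(self):
        D = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
        )
        dm = DistanceMatrix(("A", "B", "C", "D"), D)
        tree = nj_tree(dm)
        assert tree_splits(tree) == {frozenset({"C", "D"})}
        # all pairwise path lengths reproduce the input distances
        tip_dist = {t.name: t for t in tree.tips()}
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    d = tip_dist[a].distance(tip_dist[b])
                    assert d == pytest.approx(D[i, j], abs=1e-9)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_additive_matrices_recovered_exhaustively(self, n_taxa):
        """NJ is exact on additive distances: every unrooted topology over
        4 and 5 taxa (enumerated exhaustively) is reconstructed with its
        branch lengths, for several random length draws each."""
        rng = np.random.default_rng(100 + n_taxa)
        shapes, taxa = _enumerate_topologies(n_taxa)
        assert len(shapes) == {4: 3, 5: 15}[n_taxa]
        for parent in shapes:
            for _draw in range(3):
                lengths = {node: float(rng.uniform(0.1, 1.0)) for node in parent}
                D = _tree_distances(parent, lengths, taxa)
                tree = nj_tree(DistanceMatrix(tuple(taxa), D))
                assert tree_splits(tree) == _true_splits(parent, taxa)
                tips = {t.name: t for t in tree.tips()}
                for i, a in enumerate(taxa):
                    for j, b in enumerate(taxa):
                        if i < j:
                            assert tips[a].distance(tips[b]) == pytest.approx(
                                D[i, j], abs=1e-9
                            )

    def test_matches_independent_nj_implementation(self):
        """Topology agreement with scikit-bio's neighbor joining on random
        (noisy, non-additive) matrices."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(5)
        taxa = tuple(f"t{i}" for i in range(7))
        for _ in range(5):
            base = rng.uniform(0.2, 1.5, size=(7, 7))
            D = (base + base.T) / 2
            np.fill_diagonal(D, 0.0)
            mine = nj_tree(DistanceMatrix(taxa, D))
            theirs = skbio_nj(SkbioDM(D, ids=taxa))
            assert same_topology(mine, theirs)

    def test_requires_three_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("a", "b"), np.array([[0, 1], [1, 0]], float)))


class TestBootstrap:
    def test_identical_rows_form_fully_supported_cherry(self):
        rng = np.random.default_rng(21)

        def mutate(base, frac):
            out = list(base)
            for pos in rng.choice(len(base), size=int(frac * len(base)), replace=False):
                out[pos] = random_peptide(rng, 1, ALPHABET[:20])
            return "".join(out)

        base = random_peptide(rng, 120, ALPHABET[:20])
        # a1/a2: identical twins on a long shared branch; b, c, d: a clade
        # of mild divergence from the base
        twin = mutate(base, 0.5)
        msa = MSA(
            ("a1", "a2", "b", "c", "d"),
            (twin, twin, mutate(base, 0.10), mutate(base, 0.15), mutate(base, 0.20)),
        )
        tree = bootstrap_support(msa, B=30, seed=1)
        support = {
            frozenset(t.name for t in node.tips()): node.support
            for node in tree.non_tips(include_self=False)
            if hasattr(node, "support")
        }
        # the a1/a2 cherry (or its complement) must be perfectly supported
        keys = [k for k in support if k == frozenset({"a1", "a2"}) or k == frozenset({"b", "c", "d"})]
        assert keys and all(support[k] == 100.0 for k in keys)

    def test_single_replicate_supports_are_zero_or_hundred(self):
        rng = np.random.default_rng(2)
        msa = MSA(
            tuple(f"s{i}" for i in range(5)),
            tuple(random_peptide(rng, 80, ALPHABET[:20]) for _ in range(5)),
        )
        tree = bootstrap_support(msa, B=1, seed=3)
        for node in tree.non_tips(include_self=False):
            if hasattr(node, "support"):
                assert node.support in (0.0, 100.0)

    def test_fixed_seed_reproduces_supports(self):
        rng = np.random.default_rng(4)
        msa = MSA(
            tuple(f"s{i}" for i in range(6)),
            tuple(random_peptide(rng, 100, ALPHABET[:20]) for _ in range(6)),
        )
        t1 = bootstrap_support(msa, B=20, seed=9)
        t2 = bootstrap_support(msa, B=20, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_b_must_be_positive(self):
        msa = MSA(("a", "b", "c"), ("MKVL", "MKVL", "MKVA"))
        with pytest.raises(ValueError):
            bootstrap_support(msa, B=0)


class TestNewick:
    def test_three_leaf_roundtrip(self):
        text = "(A:1.000000,B:2.000000,C:3.500000);\n"
        tree = read_newick(text)
        assert write_newick(tree) == text

    def test_supports_survive_roundtrip(self):
        text = "((A:1.000000,B:1.000000)95:0.500000,C:2.000000,D:1.000000);\n"
        tree = read_newick(text)
        inner = next(tree.non_tips(include_self=False))
        assert inner.support == 95.0
        assert write_newick(tree) == text

    def test_nesting_parsed_correctly(self):
        tree = read_newick("(A,(B,C));")
        assert {t.name for t in tree.tips()} == {"A", "B", "C"}
        inner = [set(x.name for x in n.tips()) for n in tree.non_tips(include_self=False)]
        assert {"B", "C"} in inner

    def test_duplicate_leaf_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_newick("(A,(A,C));")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(Exception):
            read_newick("((A,B;")


class TestPoissonNJPipeline:
    def test_corrected_distances_dominate_p_distances(self):
        rng = np.random.default_rng(12)
        rows = tuple(random_peptide(rng, 60, ALPHABET[:20]) for _ in range(4))
        msa = MSA(tuple(f"s{i}" for i in range(4)), rows)
        p = p_distance(msa)
        d = poisson_correct(p)
        off = ~np.eye(4, dtype=bool)
        assert np.all(d.matrix[off] >= p.matrix[off])

    def test_builder_runs_end_to_end(self):
        rng = np.random.default_rng(13)
        msa = MSA(
            tuple(f"s{i}" for i in range(5)),
            tuple(random_peptide(rng, 90, ALPHABET[:20]) for _ in range(5)),
        )
        tree = msa_nj_builder()(msa)
        assert {t.name for t in tree.tips()} == set(msa.ids)
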