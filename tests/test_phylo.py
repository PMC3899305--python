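"""Distances, neighbor joining, OLS/ME scoring, CNI search, Newick."""

import math

import networkx as nx
import numpy as np
import pytest
import scipy.linalg

from cypfam.phylo import (
    Alignment,
    DistanceMatrix,
    Tree,
    cni_search,
    distance_matrix,
    enumerate_topologies,
    exhaustive_me_tree,
    family_tree,
    nj_tree,
    nni_neighbors,
    ols_branch_lengths,
    p_distance,
    poisson_distance,
    random_tree,
    tree_distance_matrix,
)


def leaf_splits(tree):
    return tree.splits()


def split_present(tree, group):
    group = frozenset(group)
    other = frozenset(tree.taxa) - group
    return group in tree.splits() or other in tree.splits()


def quartet_tree(lengths):
    """AB|CD quartet: pendant lengths for A,B,C,D plus the internal edge."""
    la, lb, lc, ld, lint = lengths
    g = nx.Graph()
    g.add_edge("A", -1, length=la)
    g.add_edge("B", -1, length=lb)
    g.add_edge("C", -2, length=lc)
    g.add_edge("D", -2, length=ld)
    g.add_edge(-1, -2, length=lint)
    return Tree(g, ("A", "B", "C", "D"))


class TestDistances:
    def test_p_distance_examples(self):
        assert p_distance("AAAA", "AAAA") == 0.0
        assert p_distance("AAAA", "AAAT") == 0.25
        assert p_distance("A-GG", "ATGG") == 0.0  # 3 comparable, 0 differ

    def test_p_distance_no_comparable_columns(self):
        with pytest.raises(ValueError):
            p_distance("A--", "-AA")

    def test_complete_deletion_removes_columns_globally(self):
        aln = Alignment(taxa=("a", "b", "c"), rows=("ATGG", "A-GG", "TTGG"))
        dm = distance_matrix(aln, deletion="complete", correction="p")
        # column 2 dropped everywhere: a vs c differ at 1 of 3 sites
        assert dm.get("a", "c") == pytest.approx(1 / 3)
        assert dm.get("a", "b") == 0.0

    def test_pairwise_deletion_keeps_per_pair_columns(self):
        aln = Alignment(taxa=("a", "b", "c"), rows=("ATGG", "A-GG", "TTGG"))
        dm = distance_matrix(aln, deletion="pairwise", correction="p")
        assert dm.get("a", "c") == pytest.approx(0.25)

    def test_poisson_closed_form(self):
        assert poisson_distance(0.0) == 0.0
        assert poisson_distance(0.5) == pytest.approx(math.log(2), abs=1e-12)
        with pytest.raises(ValueError):
            poisson_distance(1.0)

    def test_poisson_increasing_and_dominates_p(self):
        grid = np.linspace(0.0, 0.99, 200)
        d = np.array([poisson_distance(p) for p in grid])
        assert np.all(np.diff(d) > 0)
        assert np.all(d >= grid)

    def test_saturated_pairs_capped_with_warning(self):
        aln = Alignment(taxa=("a", "b"), rows=("AAAAAAAAAAAAAAAAAAAA", "CDEFGHIKLMNPQRSTVWYC"))
        with pytest.warns(UserWarning, match="saturated"):
            dm = distance_matrix(aln)
        assert dm.get("a", "b") == pytest.approx(-math.log(0.05))


class TestNeighborJoining:
    def test_two_taxa(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 5.0], [5.0, 0.0]]))
        tree = nj_tree(dm)
        assert tree.me_score == 5.0

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        center = next(n for n in tree.graph.nodes if isinstance(n, int))
        assert tree.graph.edges["A", center]["length"] == pytest.approx(1.0)
        assert tree.graph.edges["B", center]["length"] == pytest.approx(1.0)
        assert tree.graph.edges["C", center]["length"] == pytest.approx(3.0)

    def test_quartet_recovery(self):
        gen = quartet_tree([1, 2, 1, 3, 4])
        tree = nj_tree(tree_distance_matrix(gen))
        assert tree.splits() == gen.splits()
        assert split_present(tree, {"A", "B"})
        lengths = tree.split_lengths()
        for e, length in gen.split_lengths().items():
            assert lengths[e] == pytest.approx(length)

    def test_exact_on_random_additive_matrices(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(4, 11))
            gen = random_tree([f"t{k}" for k in range(n)], rng)
            tree = nj_tree(tree_distance_matrix(gen))
            assert tree.splits() == gen.splits()
            lengths = tree.split_lengths()
            for e, length in gen.split_lengths().items():
                assert lengths[e] == pytest.approx(length, abs=1e-8)

    def test_matches_scikit_bio_on_noisy_matrices(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(4, 9))
            taxa = [f"t{k}" for k in range(n)]
            gen = random_tree(taxa, rng)
            d = tree_distance_matrix(gen).values.copy()
            noise = rng.uniform(-0.05, 0.05, size=d.shape)
            noise = (noise + noise.T) / 2
            np.fill_diagonal(noise, 0.0)
            d = np.clip(d + noise, 0.0, None)
            np.fill_diagonal(d, 0.0)
            ours = nj_tree(DistanceMatrix(tuple(taxa), d))
            ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=taxa))
            ref_splits = set()
            for node in ref.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if taxa[0] in side:
                    side = frozenset(taxa) - side
                if 2 <= len(side) <= n - 2:
                    ref_splits.add(side)
            assert ours.splits() == frozenset(ref_splits)

    def test_invalid_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(("A", "B"), np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestOlsAndMe:
    def test_additive_matrix_fits_exactly(self):
        gen = quartet_tree([1, 2, 1, 3, 4])
        fit = ols_branch_lengths(gen, tree_distance_matrix(gen))
        assert fit.ssq == pytest.approx(0.0, abs=1e-16)
        assert fit.me_score == pytest.approx(11.0)
        for e, length in gen.branch_lengths().items():
            assert fit.tree.branch_lengths()[e] == pytest.approx(length)

    def test_zero_matrix_gives_zero_lengths(self):
        gen = quartet_tree([1, 1, 1, 1, 1])
        dm = DistanceMatrix(gen.taxa, np.zeros((4, 4)))
        fit = ols_branch_lengths(gen, dm)
        assert fit.me_score == pytest.approx(0.0, abs=1e-12)

    def test_wrong_topology_has_larger_ssq(self):
        gen = quartet_tree([1, 2, 1, 3, 4])
        dm = tree_distance_matrix(gen)
        fits = {
            frozenset(t.splits()): ols_branch_lengths(t, dm).ssq
            for t in enumerate_topologies(gen.taxa)
        }
        right = frozenset(gen.splits())
        assert fits[right] == pytest.approx(0.0, abs=1e-16)
        for key, ssq in fits.items():
            if key != right:
                assert ssq > 0.1

    def test_ssq_matches_generic_solver(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            taxa = [f"t{k}" for k in range(n)]
            topo = random_tree(taxa, rng)
            d = rng.uniform(0.1, 2.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dm = DistanceMatrix(tuple(taxa), d)
            fit = ols_branch_lengths(topo, dm)
            # independent objective: scipy lstsq on a path-incidence system
            from itertools import combinations

            edges = list(topo.graph.edges())
            pairs = list(combinations(taxa, 2))
            A = np.zeros((len(pairs), len(edges)))
            for r, (a, b) in enumerate(pairs):
                path = nx.shortest_path(topo.graph, a, b)
                for u, v in zip(path, path[1:]):
                    A[r, next(k for k, e in enumerate(edges) if set(e) == {u, v})] = 1
            dvec = np.array([dm.get(a, b) for a, b in pairs])
            x, *_ = scipy.linalg.lstsq(A, dvec)
            assert fit.ssq == pytest.approx(float(np.sum((A @ x - dvec) ** 2)), abs=1e-8)


class TestCniSearch:
    def test_recovers_generating_topology_from_worst_start(self):
        gen = quartet_tree([1, 2, 1, 3, 4])
        dm = tree_distance_matrix(gen)
        worst = max(
            enumerate_topologies(gen.taxa),
            key=lambda t: ols_branch_lengths(t, dm).ssq,
        )
        result = cni_search(worst, dm)
        assert result.tree.splits() == gen.splits()
        assert result.me_score == pytest.approx(11.0)

    def test_nj_start_on_additive_matrix_is_already_optimal(self):
        rng = np.random.default_rng(41)
        gen = random_tree([f"t{k}" for k in range(6)], rng)
        dm = tree_distance_matrix(gen)
        start = nj_tree(dm)
        result = cni_search(start, dm)
        assert result.tree.splits() == start.splits()
        assert result.n_iterations == 0

    def test_never_worse_than_start(self):
        rng = np.random.default_rng(43)
        for _ in range(10):
            d = rng.uniform(0.2, 2.0, size=(5, 5))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            dm = DistanceMatrix(tuple("ABCDE"), d)
            start = nj_tree(dm)
            start_me = ols_branch_lengths(start, dm).me_score
            assert cni_search(start, dm).me_score <= start_me + 1e-12

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(47)
        for _ in range(15):
            n = int(rng.integers(4, 8))
            gen = random_tree([f"t{k}" for k in range(n)], rng)
            dm = tree_distance_matrix(gen)
            result = cni_search(nj_tree(dm), dm)
            oracle = exhaustive_me_tree(dm)
            assert result.tree.splits() == oracle.tree.splits()
            assert result.me_score == pytest.approx(oracle.me_score, abs=1e-9)


class TestExhaustive:
    def test_three_taxa_single_topology(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        fit = exhaustive_me_tree(DistanceMatrix(("A", "B", "C"), d))
        assert fit.me_score == pytest.approx(5.0)

    def test_topology_counts(self):
        assert sum(1 for _ in enumerate_topologies(tuple("ABCD"))) == 3
        assert sum(1 for _ in enumerate_topologies(tuple("ABCDEF"))) == 105

    def test_optimum_bounds_every_topology(self):
        rng = np.random.default_rng(53)
        d = rng.uniform(0.2, 2.0, size=(6, 6))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix(tuple("ABCDEF"), d)
        best = exhaustive_me_tree(dm)
        for topo in enumerate_topologies(dm.taxa):
            assert best.me_score <= ols_branch_lengths(topo, dm).me_score + 1e-9

    def test_too_many_taxa_rejected(self):
        dm = DistanceMatrix(tuple("ABCDEFGHI"), np.zeros((9, 9)))
        with pytest.raises(ValueError):
            exhaustive_me_tree(dm)


class TestNewickAndFamilyTree:
    def test_deterministic_newick(self):
        gen = quartet_tree([1, 2, 1, 3, 4])
        assert gen.to_newick() == "(A:1,B:2,(C:1,D:3):4);"

    def test_negative_lengths_clamped_only_in_newick(self):
        g = nx.Graph()
        g.add_edge("A", -1, length=-0.5)
        g.add_edge("B", -1, length=1.0)
        g.add_edge("C", -1, length=2.0)
        tree = Tree(g, ("A", "B", "C"))
        assert tree.me_score == pytest.approx(2.5)  # raw sum keeps the negative
        assert tree.to_newick() == "(A:0,B:1,C:2);"

    def test_two_member_family(self):
        aln = Alignment(taxa=("x", "y"), rows=("AAAA", "AAAT"))
        result = family_tree(aln)
        assert result.newick.startswith("(x:")
        assert result.me_score == pytest.approx(-math.log(0.75))

    def test_identical_sequences_give_zero_lengths(self):
        aln = Alignment(taxa=("x", "y", "z"), rows=("AAAA",) * 3)
        result = family_tree(aln)
        assert result.me_score == pytest.approx(0.0, abs=1e-12)

    def test_single_member_rejected(self):
        with pytest.raises(ValueError):
            family_tree(Alignment(taxa=("x",), rows=("AAA",)))

    def test_duplicated_genes_form_a_clade(self):
        """Eight within-species duplicates at low divergence group together,
        mirroring species-specific paralog expansion."""
        from cypfam import synth

        cfg = synth.SyntheticConfig(
            species=("SpA", "SpB", "SpC"),
            family_counts={"CYP9001": {"SpA": 1, "SpB": 9, "SpC": 1}},
            mu_speciation=0.2,
            mu_duplication=0.02,
            ortholog_fraction=1.0,
            pseudo_fraction=0.0,
            seed=5,
        )
        ds = synth.generate(cfg)
        aln = synth.make_alignment(ds.records)
        result = family_tree(aln)
        b_genes = {r.id for r in ds.records if r.species == "SpB"}
        assert split_present(result.tree, b_genes)
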