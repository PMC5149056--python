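"""Distances, UPGMA, parsimony, MP search, bootstrap and clade support."""

from itertools import product

import numpy as np
import pytest

from herbdx.alignment import DegenerateInputError, LabeledAlignment, SequenceRecord
from herbdx.phylo import (
    DistanceMatrix,
    Node,
    bootstrap_support,
    collapse_unsupported,
    from_newick,
    group_support,
    is_monophyletic,
    mp_search,
    p_distance_matrix,
    parsimony_score,
    tree_splits,
    upgma,
)

from conftest import random_alignment

BASES = np.array(list("ACGT"))


def _aln(rows, locus="toy"):
    return LabeledAlignment(
        records=[SequenceRecord(id=i, residues=s) for i, s in rows], locus=locus
    )


class TestPDistance:
    def test_identical_sequences_are_at_distance_zero(self):
        dm = p_distance_matrix(_aln([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")]))
        assert np.all(dm.values == 0)

    def test_half_mismatches(self):
        dm = p_distance_matrix(_aln([("a", "AAAA"), ("b", "AATT")]))
        assert dm.distance("a", "b") == 0.5

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bruteforce_pairwise_deletion(self, seed):
        aln = random_alignment(seed, n_records=6, n_cols=30, noise=0.2)
        dm = p_distance_matrix(aln)
        for i, a in enumerate(aln.records):
            for j, b in enumerate(aln.records):
                if i >= j:
                    continue
                shared = [
                    (x, y)
                    for x, y in zip(a.residues, b.residues)
                    if x in "ACGT" and y in "ACGT"
                ]
                expected = sum(1 for x, y in shared if x != y) / len(shared)
                assert dm.values[i, j] == pytest.approx(expected)
                assert 0.0 <= dm.values[i, j] <= 1.0

    def test_no_shared_clean_columns_names_the_pair(self):
        aln = _aln([("a", "AANN"), ("b", "NNTT")])
        with pytest.raises(DegenerateInputError, match="'a'.*'b'"):
            p_distance_matrix(aln)


class TestUpgma:
    def test_two_taxa_make_a_cherry_with_half_distance_branches(self):
        dm = DistanceMatrix(ids=["a", "b"], values=np.array([[0, 0.2], [0.2, 0]]))
        tree = upgma(dm)
        assert sorted(tree.leaves()) == ["a", "b"]
        assert [c.length for c in tree.children] == [pytest.approx(0.1)] * 2

    def test_hand_computed_four_taxon_example(self):
        # d(a,b)=2, d(a,c)=4, d(b,c)=4, d(*,d)=6: merge (a,b) at h=1;
        # then c joins (ab) at avg 4 -> h=2; d joins last at avg 6 -> h=3.
        ids = ["a", "b", "c", "d"]
        values = np.array(
            [
                [0, 2, 4, 6],
                [2, 0, 4, 6],
                [4, 4, 0, 6],
                [6, 6, 6, 0],
            ],
            dtype=float,
        )
        tree = upgma(DistanceMatrix(ids=ids, values=values))
        assert tree_splits(tree) == {frozenset({"c", "d"})} or tree_splits(tree) == {
            frozenset({"a", "b"})
        }
        # heights: leaf depths all equal 3 (ultrametric), cherry at 1
        depths = {}

        def walk(node, depth):
            if node.is_leaf:
                depths[node.name] = depth + (node.length or 0)
            for ch in node.children:
                walk(ch, depth + (node.length or 0))

        walk(tree, 0)
        assert all(d == pytest.approx(3.0) for d in depths.values())
        cherry = next(
            n for n in tree.postorder() if not n.is_leaf and set(n.leaves()) == {"a", "b"}
        )
        assert all(c.length == pytest.approx(1.0) for c in cherry.children)

    @pytest.mark.parametrize("seed", range(10))
    def test_output_is_ultrametric(self, seed):
        aln = random_alignment(seed, n_records=7, n_cols=60)
        tree = upgma(p_distance_matrix(aln))
        depths = []

        def walk(node, depth):
            d = depth + (node.length or 0)
            if node.is_leaf:
                depths.append(d)
            for ch in node.children:
                walk(ch, d)

        walk(tree, 0.0)
        assert max(depths) - min(depths) < 1e-9

    def test_tie_break_is_deterministic(self):
        values = np.zeros((4, 4)) + 0.5
        np.fill_diagonal(values, 0)
        dm = DistanceMatrix(ids=["d", "c", "b", "a"], values=values)
        t1, t2 = upgma(dm), upgma(dm)
        assert t1.to_newick() == t2.to_newick()


def sankoff_oracle(tree, aln):
    """Minimum changes by explicit enumeration of internal-state assignments."""
    leaves = {}
    internals = []
    for node in tree.postorder():
        if node.is_leaf:
            leaves[id(node)] = node.name
        else:
            internals.append(node)
    total = 0
    for pos in range(1, aln.length + 1):
        leaf_sets = {}
        for node_id, name in leaves.items():
            sym = aln.record(name).residues[pos - 1]
            sets = {
                "A": "A", "C": "C", "G": "G", "T": "T",
                "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
            }.get(sym, "ACGT")
            leaf_sets[node_id] = sets
        best = None
        for assignment in product("ACGT", repeat=len(internals)):
            states = {id(n): a for n, a in zip(internals, assignment)}
            cost = 0

            def edge_cost(parent, child):
                ps = states[id(parent)]
                if child.is_leaf:
                    return 0 if ps in leaf_sets[id(child)] else 1
                return 0 if ps == states[id(child)] else 1

            for node in internals:
                for ch in node.children:
                    cost += edge_cost(node, ch)
            best = cost if best is None else min(best, cost)
        total += best
    return total


class TestParsimony:
    def test_invariant_alignment_scores_zero(self):
        aln = _aln([(f"t{i}", "ACGTACGT") for i in range(4)])
        tree = upgma(p_distance_matrix(aln))
        assert parsimony_score(tree, aln) == 0

    def test_single_forced_change(self):
        aln = _aln([("A1", "A"), ("A2", "A"), ("C1", "C"), ("C2", "C")])
        tree = Node(
            children=[
                Node(children=[Node(name="A1"), Node(name="A2")]),
                Node(children=[Node(name="C1"), Node(name="C2")]),
            ]
        )
        assert parsimony_score(tree, aln) == 1

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_state_enumeration(self, seed):
        aln = random_alignment(seed, n_records=5, n_cols=6, noise=0.15)
        tree = upgma(p_distance_matrix(random_alignment(seed + 100, n_records=5, n_cols=20)))
        for leaf, rec in zip(sorted(tree.leaves()), aln.records):
            rec.id = leaf
        assert parsimony_score(tree, aln) == sankoff_oracle(tree, aln)

    def test_invariant_under_rerooting(self):
        aln = random_alignment(3, n_records=6, n_cols=25, noise=0.1)
        tree = upgma(p_distance_matrix(aln))
        score = parsimony_score(tree, aln)
        # reroot: swap root children order and rotate a subtree upward
        swapped = tree.copy()
        swapped.children.reverse()
        assert parsimony_score(swapped, aln) == score
        # root on another internal edge: build from newick of a rotation
        rotated = from_newick(tree.to_newick())
        assert parsimony_score(rotated, aln) == score


def enumerate_topologies(taxa):
    """All rooted-binary encodings of unrooted topologies by edge insertion
    (over-counts rooted placements; the set of split-sets is complete)."""
    if len(taxa) == 3:
        yield Node(
            children=[
                Node(name=taxa[0]),
                Node(children=[Node(name=taxa[1]), Node(name=taxa[2])]),
            ]
        )
        return
    for sub in enumerate_topologies(taxa[:-1]):
        edges = []

        def collect(node):
            for i, ch in enumerate(node.children):
                edges.append((node, i))
                collect(ch)

        collect(sub)
        for parent, idx in edges:
            trial = sub.copy()
            stack = [(sub, trial)]
            tp = None
            while stack:
                o, c = stack.pop()
                if o is parent:
                    tp = c
                    break
                stack.extend(zip(o.children, c.children))
            old = tp.children[idx]
            tp.children[idx] = Node(children=[old, Node(name=taxa[-1])])
            yield trial


class TestMpSearch:
    @pytest.mark.parametrize("n_taxa", [5, 6, 7])
    def test_equals_exhaustive_enumeration(self, n_taxa):
        aln = random_alignment(n_taxa, n_records=n_taxa, n_cols=30)
        aln.records = aln.records[:n_taxa]
        trees, best = mp_search(aln, addition_replicates=8, seed=11)
        exhaustive_best = min(
            parsimony_score(t, aln) for t in enumerate_topologies(aln.ids)
        )
        assert best == exhaustive_best
        assert all(parsimony_score(t, aln) == best for t in trees)

    def test_planted_bipartition_recovered_in_all_best_trees(self):
        rng = np.random.default_rng(0)
        base = rng.integers(0, 4, 50)
        left = base.copy()
        idx = rng.choice(50, 15, replace=False)
        left[idx] = (left[idx] + 1) % 4  # 15 fixed differences split the taxa
        rows = [(f"a{i}", "".join(BASES[base])) for i in range(4)]
        rows += [(f"b{i}", "".join(BASES[left])) for i in range(4)]
        aln = _aln(rows)
        trees, _ = mp_search(aln, addition_replicates=5, seed=2)
        split = frozenset(f"b{i}" for i in range(4))
        for tree in trees:
            assert split in tree_splits(tree) or frozenset(
                f"a{i}" for i in range(4)
            ) in tree_splits(tree)

    def test_same_seed_reproduces_tree_set(self):
        aln = random_alignment(9, n_records=7, n_cols=25)
        t1, s1 = mp_search(aln, addition_replicates=6, seed=5)
        t2, s2 = mp_search(aln, addition_replicates=6, seed=5)
        assert s1 == s2
        assert [t.to_newick() for t in t1] == [t.to_newick() for t in t2]

    def test_best_score_not_worse_than_upgma_topology(self):
        aln = random_alignment(13, n_records=7, n_cols=40, noise=0.05)
        _, best = mp_search(aln, addition_replicates=5, seed=1)
        assert best <= parsimony_score(upgma(p_distance_matrix(aln)), aln)

    def test_fewer_than_four_taxa_is_degenerate(self):
        aln = random_alignment(0, n_records=3)
        with pytest.raises(DegenerateInputError):
            mp_search(aln)


def _two_clade_alignment(n_per=6, n_cols=200, n_diffs=30, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, n_cols)
    other = base.copy()
    idx = rng.choice(n_cols, n_diffs, replace=False)
    other[idx] = (other[idx] + 1) % 4
    rows = [(f"a{i}", "".join(BASES[base])) for i in range(n_per)]
    rows += [(f"b{i}", "".join(BASES[other])) for i in range(n_per)]
    return _aln(rows), frozenset(f"a{i}" for i in range(n_per))


class TestBootstrap:
    def test_planted_split_reaches_high_support(self):
        aln, clade_a = _two_clade_alignment()
        result = bootstrap_support(aln, method="upgma", replicates=200, seed=7)
        report = group_support(result.replicates, "A", clade_a)
        assert report.support >= 99.0

    def test_no_variation_collapses_to_a_star(self):
        aln = _aln([(f"t{i}", "ACGTACGTAC") for i in range(6)])
        result = bootstrap_support(
            aln, method="upgma", replicates=50, seed=1, collapse_below=50
        )
        assert tree_splits(result.tree) == set()

    def test_same_seed_gives_identical_support(self):
        aln, _ = _two_clade_alignment(n_per=4, n_cols=80, n_diffs=10, seed=3)
        r1 = bootstrap_support(aln, replicates=60, seed=9)
        r2 = bootstrap_support(aln, replicates=60, seed=9)
        assert r1.tree.to_newick() == r2.tree.to_newick()

    def test_mp_bootstrap_runs_and_supports_planted_split(self):
        aln, clade_a = _two_clade_alignment(n_per=3, n_cols=60, n_diffs=12, seed=5)
        result = bootstrap_support(
            aln, method="mp", replicates=30, seed=2, mp_kwargs={"addition_replicates": 2}
        )
        report = group_support(result.replicates, "A", clade_a)
        assert report.support >= 90.0


class TestGroupSupport:
    def test_group_of_all_leaves_is_always_monophyletic(self):
        aln, _ = _two_clade_alignment(n_per=3, n_cols=50, n_diffs=5)
        result = bootstrap_support(aln, replicates=25, seed=4)
        report = group_support(result.replicates, "all", frozenset(aln.ids))
        assert report.support == 100.0

    def test_matches_independent_monophyly_count(self):
        aln, clade_a = _two_clade_alignment(n_per=4, n_cols=60, n_diffs=6, seed=8)
        result = bootstrap_support(aln, replicates=40, seed=3)
        report = group_support(result.replicates, "A", clade_a)

        def naive_mono(tree, group):
            # a clade iff some node's leaf set (or its complement) equals it
            leaves = frozenset(tree.leaves())
            for node in tree.postorder():
                side = frozenset(node.leaves())
                if side == group or leaves - side == group:
                    return True
            return False

        count = sum(1 for t in result.replicates if naive_mono(t, clade_a))
        assert report.support == pytest.approx(100.0 * count / 40)

    def test_ignoring_a_rogue_taxon_never_lowers_support(self):
        aln, clade_a = _two_clade_alignment(n_per=5, n_cols=120, n_diffs=20, seed=6)
        # make one member of A rogue: overwrite with B-like sequence
        rogue = "a4"
        aln.record(rogue).residues = aln.record("b0").residues
        result = bootstrap_support(aln, replicates=60, seed=10)
        plain = group_support(result.replicates, "A", clade_a)
        modified = group_support(result.replicates, "A-mod", clade_a, ignored=[rogue])
        assert modified.support >= plain.support
        assert modified.support >= 99.0  # pruning the rogue restores the clade

    def test_empty_group_rejected(self):
        with pytest.raises(DegenerateInputError):
            group_support([Node(name="x")], "empty", [])


class TestNewick:
    def test_round_trip_preserves_topology_and_support(self):
        aln, _ = _two_clade_alignment(n_per=3, n_cols=50, n_diffs=8, seed=2)
        result = bootstrap_support(aln, replicates=20, seed=5)
        text = result.tree.to_newick()
        back = from_newick(text)
        assert tree_splits(back) == tree_splits(result.tree)
        supports = sorted(
            n.support for n in result.tree.postorder() if n.support is not None
        )
        back_supports = sorted(
            n.support for n in back.postorder() if n.support is not None
        )
        assert back_supports == supports

    def test_collapse_threshold_removes_weak_edges(self):
        tree = from_newick("((a,b)40,(c,d)90);")
        collapsed = collapse_unsupported(tree, 50)
        assert tree_splits(collapsed) == {frozenset({"c", "d"})}

    def test_monophyly_checker_on_hand_tree(self):
        tree = from_newick("((a,b),(c,(d,e)));")
        assert is_monophyletic(tree, frozenset({"d", "e"}))
        assert is_monophyletic(tree, frozenset({"c", "d", "e"}))
        assert not is_monophyletic(tree, frozenset({"b", "c"}))
        # pruning the interloper rescues the group
        assert is_monophyletic(
            tree, frozenset({"b", "c"}), ignored=frozenset({"a", "d", "e"})
        )
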