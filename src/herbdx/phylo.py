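"""Distance and parsimony trees with bootstrap clade support.

The tracing of an unknown sample to a taxonomic group rests on whether
named groups (a subfamily, its tribes, individual genera) come out
monophyletic in bootstrapped trees.  This module provides the pieces:

* p-distances with pairwise deletion of ambiguous positions,
* UPGMA (average-linkage, ultrametric) trees with deterministic tie-breaks,
* Fitch small parsimony and a seeded random-addition + SPR hill-climbing
  maximum-parsimony search,
* nonparametric bootstrap (column resampling) for either method, and
* per-group support scoring, including "modified" groups in which named
  rogue taxa are pruned before monophyly is assessed.

Trees are rooted binary structures used with unrooted semantics: scores
and bipartitions are invariant to the root placement.  Newick is the
exchange format (support values as internal node labels), so replicate
sets produced elsewhere (e.g. likelihood trees) can be scored too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import (
    IUPAC_SETS,
    DegenerateInputError,
    FrameError,
    LabeledAlignment,
)

_BASE_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15


def _symbol_bits(symbol: str) -> int:
    base_set = IUPAC_SETS.get(symbol.upper())
    if not base_set:  # gap or unknown symbol: missing, no cost
        return _MISSING
    bits = 0
    for b in base_set:
        bits |= _BASE_BITS[b]
    return bits


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


def p_distance_matrix(aln: LabeledAlignment) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion.

    For each pair, only columns where both sequences carry an unambiguous
    base are compared; the distance is the mismatch proportion over those
    columns.  A pair sharing no clean column is an error.
    """
    if len(aln.records) < 2:
        raise DegenerateInputError("p-distance needs >= 2 records")
    n = len(aln.records)
    clean = np.array(
        [
            [sym in "ACGT" for sym in rec.residues]
            for rec in aln.records
        ]
    )
    codes = np.array(
        [[ord(sym) for sym in rec.residues] for rec in aln.records], dtype=np.int16
    )
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = clean[i] & clean[j]
            total = int(shared.sum())
            if total == 0:
                raise DegenerateInputError(
                    f"pair ({aln.records[i].id!r}, {aln.records[j].id!r}) shares "
                    "no unambiguous column; p-distance undefined"
                )
            mismatches = int((codes[i][shared] != codes[j][shared]).sum())
            values[i, j] = values[j, i] = mismatches / total
    return DistanceMatrix(ids=list(aln.ids), values=values)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class Node:
    """Rooted tree node; leaves carry names, internal nodes children."""

    name: str = ""
    children: list["Node"] = field(default_factory=list)
    length: float | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def copy(self) -> "Node":
        return Node(
            name=self.name,
            children=[c.copy() for c in self.children],
            length=self.length,
            support=self.support,
        )

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                label = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                sup = ""
                if with_support and node.support is not None:
                    sup = f"{node.support:g}"
                label = f"({inner}){sup}"
            if node.length is not None:
                label += f":{node.length:g}"
            return label

        return fmt(self) + ";"


def from_newick(text: str) -> Node:
    """Parse a newick string (internal labels read as support values)."""
    tree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> Node:
        node = Node(
            name=dnode.taxon.label if dnode.taxon else "",
            length=dnode.edge.length,
        )
        label = getattr(dnode, "label", None)
        if label and not dnode.is_leaf():
            try:
                node.support = float(label)
            except ValueError:
                node.name = label
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return convert(tree.seed_node)


def read_replicates(path) -> list[Node]:
    """Read a multi-tree newick file into a replicate tree list."""
    with open(path) as fh:
        return [from_newick(line) for line in fh if line.strip()]


def write_replicates(trees: list[Node], path) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(tree.to_newick() + "\n")


def tree_splits(tree: Node) -> set[frozenset[str]]:
    """Nontrivial unrooted bipartitions, each as its canonical side.

    The canonical side is the one *not* containing the lexicographically
    smallest leaf, so the set is invariant under re-rooting.
    """
    all_leaves = frozenset(tree.leaves())
    anchor = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(node.leaves())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(side)
    return splits


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------

def upgma(dm: DistanceMatrix, tie_order: list[str] | None = None) -> Node:
    """Average-linkage ultrametric tree; node heights are half the merge
    distance.  Equidistant merge candidates are broken deterministically by
    the lexicographically smallest member id, or by the priority ranking in
    ``tie_order`` when given (the bootstrap uses a random per-replicate
    ranking so that ties do not masquerade as support)."""
    if len(dm.ids) < 2:
        raise DegenerateInputError("UPGMA needs >= 2 taxa")
    rank = {tid: i for i, tid in enumerate(tie_order)} if tie_order else None
    clusters: dict[frozenset[str], tuple[Node, float, int]] = {
        frozenset([tid]): (Node(name=tid), 0.0, 1) for tid in dm.ids
    }
    dist: dict[frozenset[frozenset[str]], float] = {}
    keys = list(clusters)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            dist[frozenset((a, b))] = dm.distance(next(iter(a)), next(iter(b)))

    def tie_key(pair: frozenset[frozenset[str]]):
        members = sorted(m for cl in pair for m in cl)
        if rank is not None:
            return tuple(sorted(rank[m] for m in members))
        return tuple(members)

    while len(clusters) > 1:
        best_pair = min(dist, key=lambda p: (dist[p], tie_key(p)))
        d = dist[best_pair]
        a, b = sorted(best_pair, key=lambda cl: min(cl))
        node_a, height_a, size_a = clusters.pop(a)
        node_b, height_b, size_b = clusters.pop(b)
        height = d / 2.0
        node_a.length = height - height_a
        node_b.length = height - height_b
        merged_key = a | b
        merged = Node(children=[node_a, node_b])
        # average-linkage update
        new_dist: dict[frozenset[frozenset[str]], float] = {}
        for pair, value in dist.items():
            if a in pair or b in pair:
                continue
            new_dist[pair] = value
        for other in clusters:
            da = dist[frozenset((a, other))]
            db = dist[frozenset((b, other))]
            size_o = clusters[other][2]
            new_dist[frozenset((merged_key, other))] = (
                size_a * da + size_b * db
            ) / (size_a + size_b)
        dist = new_dist
        clusters[merged_key] = (merged, height, size_a + size_b)
    (root, _, _) = next(iter(clusters.values()))
    return root


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def _pattern_matrix(aln: LabeledAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Column patterns (as bit codes per taxon) with multiplicities."""
    coded = np.array(
        [[_symbol_bits(sym) for sym in rec.residues] for rec in aln.records],
        dtype=np.uint8,
    )
    patterns, counts = np.unique(coded, axis=1, return_counts=True)
    return patterns, counts


def _fitch_score(tree: Node, patterns: np.ndarray, counts: np.ndarray, ids: list[str]) -> int:
    index = {tid: i for i, tid in enumerate(ids)}
    changes = np.zeros(patterns.shape[1], dtype=np.int64)

    def visit(node: Node) -> np.ndarray:
        if node.is_leaf:
            return patterns[index[node.name]]
        sets = visit(node.children[0])
        for child in node.children[1:]:
            other = visit(child)
            inter = sets & other
            empty = inter == 0
            changes[empty] += 1
            sets = np.where(empty, sets | other, inter)
        return sets

    visit(tree)
    return int((changes * counts).sum())


def parsimony_score(tree: Node, aln: LabeledAlignment) -> int:
    """Fitch small-parsimony changes summed over all columns.

    Ambiguity codes contribute their base sets; gaps are missing data and
    never cost a change.  The score is invariant under re-rooting.
    """
    tree_leaves = sorted(tree.leaves())
    if tree_leaves != sorted(aln.ids):
        raise FrameError(
            "tree leaves do not match alignment ids: "
            f"{tree_leaves} vs {sorted(aln.ids)}"
        )
    patterns, counts = _pattern_matrix(aln)
    return _fitch_score(tree, patterns, counts, list(aln.ids))


# ---------------------------------------------------------------------------
# maximum-parsimony search
# ---------------------------------------------------------------------------

def _attach_points(tree: Node) -> list[tuple[Node, int]]:
    """(parent, child-index) pairs naming every edge of the rooted tree."""
    points = []

    def walk(node: Node) -> None:
        for i, child in enumerate(node.children):
            points.append((node, i))
            walk(child)

    walk(tree)
    return points


def _attach_on_edge(tree: Node, parent: Node, idx: int, subtree: Node) -> None:
    old = parent.children[idx]
    parent.children[idx] = Node(children=[old, subtree])


def _stepwise_addition(
    order: list[str], patterns: np.ndarray, counts: np.ndarray, ids: list[str]
) -> Node:
    tree = Node(children=[Node(name=order[0]), Node(name=order[1])])
    if len(order) > 2:
        tree.children.append(Node(name=order[2]))
        tree = Node(children=[tree.children[0], Node(children=tree.children[1:])])
    for taxon in order[3:]:
        best_score = None
        best = None
        for parent, idx in _attach_points(tree):
            trial = tree.copy()
            # find matching edge in the copy by position
            t_parent, t_idx = _edge_in_copy(tree, trial, parent, idx)
            _attach_on_edge(trial, t_parent, t_idx, Node(name=taxon))
            score = _fitch_score(trial, patterns, counts, ids)
            if best_score is None or score < best_score:
                best_score = score
                best = trial
        tree = best
    return tree


def _edge_in_copy(orig: Node, copy: Node, parent: Node, idx: int) -> tuple[Node, int]:
    """Locate the copy of an (parent, idx) edge via parallel traversal."""
    stack = [(orig, copy)]
    while stack:
        o, c = stack.pop()
        if o is parent:
            return c, idx
        stack.extend(zip(o.children, c.children))
    raise RuntimeError("edge not found in copied tree")


def _spr_neighbors(tree: Node):
    """Yield SPR rearrangements of a rooted-binary tree (unrooted meaning)."""
    # enumerate prunable subtrees by (parent, index)
    edges = _attach_points(tree)
    for p_parent, p_idx in edges:
        trial_base = tree.copy()
        c_parent, c_idx = _edge_in_copy(tree, trial_base, p_parent, p_idx)
        pruned = c_parent.children[c_idx]
        # remove pruned; splice its sibling up
        sibling = c_parent.children[1 - c_idx]
        remaining = trial_base
        if c_parent is trial_base:
            remaining = sibling
            if remaining.is_leaf:
                continue  # cannot make a tree from a lone leaf
        else:
            _replace_child(trial_base, c_parent, sibling)
        pruned_leaves = set(pruned.leaves())
        for r_parent, r_idx in _attach_points(remaining):
            target = r_parent.children[r_idx]
            if target is sibling and c_parent is not trial_base:
                continue  # reattaching where it came from: same topology
            if set(target.leaves()) & pruned_leaves:
                continue
            trial = remaining.copy()
            pruned_copy = pruned.copy()
            t_parent, t_idx = _edge_in_copy(remaining, trial, r_parent, r_idx)
            _attach_on_edge(trial, t_parent, t_idx, pruned_copy)
            yield trial


def _replace_child(tree: Node, old_parent: Node, replacement: Node) -> None:
    for node in tree.postorder():
        for i, child in enumerate(node.children):
            if child is old_parent:
                node.children[i] = replacement
                return
    raise RuntimeError("parent not found")


def _canonical(tree: Node) -> frozenset[frozenset[str]]:
    return frozenset(tree_splits(tree))


def mp_search(
    aln: LabeledAlignment,
    addition_replicates: int = 10,
    seed: int = 0,
) -> tuple[list[Node], int]:
    """Heuristic maximum-parsimony search.

    Each replicate builds a stepwise random-addition start tree and then
    hill-climbs with SPR, accepting the first improving rearrangement until
    none exists.  Returns (all distinct equally-best trees found, best
    score); fully reproducible from ``seed``.
    """
    if len(aln.records) < 4:
        raise DegenerateInputError("MP search needs >= 4 taxa")
    rng = np.random.default_rng(seed)
    patterns, counts = _pattern_matrix(aln)
    ids = list(aln.ids)
    best_score: int | None = None
    best_trees: dict[frozenset[frozenset[str]], Node] = {}
    for _ in range(addition_replicates):
        order = list(ids)
        rng.shuffle(order)
        tree = _stepwise_addition(order, patterns, counts, ids)
        score = _fitch_score(tree, patterns, counts, ids)
        improved = True
        while improved:
            improved = False
            for neighbor in _spr_neighbors(tree):
                n_score = _fitch_score(neighbor, patterns, counts, ids)
                if n_score < score:
                    tree, score = neighbor, n_score
                    improved = True
                    break
        if best_score is None or score < best_score:
            best_score = score
            best_trees = {_canonical(tree): tree}
        elif score == best_score:
            best_trees.setdefault(_canonical(tree), tree)
    return list(best_trees.values()), int(best_score)


# ---------------------------------------------------------------------------
# bootstrap and group support
# ---------------------------------------------------------------------------

def _resample_alignment(aln: LabeledAlignment, rng: np.random.Generator) -> LabeledAlignment:
    """Resample columns with replacement and shuffle taxon order.

    The taxon shuffle matters: tree construction breaks ties
    deterministically, so without it an entirely uninformative alignment
    would reproduce the same arbitrary topology in every replicate and
    ties would masquerade as full support.
    """
    cols = rng.integers(0, aln.length, size=aln.length)
    from dataclasses import replace as _replace

    records = [
        _replace(
            rec,
            residues="".join(rec.residues[c] for c in cols),
            labels=dict(rec.labels),
        )
        for rec in aln.records
    ]
    order = rng.permutation(len(records))
    return LabeledAlignment(records=[records[i] for i in order], locus=aln.locus)


def _build_tree(
    aln: LabeledAlignment,
    method: str,
    seed: int,
    mp_kwargs: dict,
    tie_order: list[str] | None = None,
) -> Node:
    if method == "upgma":
        return upgma(p_distance_matrix(aln), tie_order=tie_order)
    if method == "mp":
        trees, _ = mp_search(aln, seed=seed, **mp_kwargs)
        return trees[0]
    raise ValueError(f"unknown method {method!r} (expected 'upgma' or 'mp')")


@dataclass
class BootstrapResult:
    tree: Node  # tree on the full data, support annotated
    replicates: list[Node]
    method: str
    n_replicates: int


def bootstrap_support(
    aln: LabeledAlignment,
    method: str = "upgma",
    replicates: int = 500,
    seed: int = 0,
    collapse_below: float | None = None,
    mp_kwargs: dict | None = None,
) -> BootstrapResult:
    """Column-resampling bootstrap with per-bipartition support.

    Support for each internal edge of the full-data tree is the percentage
    of replicate trees containing the same bipartition.  Per-replicate
    seeds are derived from ``seed`` by counter.  ``collapse_below`` (e.g.
    50) collapses poorly supported edges into polytomies.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    mp_kwargs = mp_kwargs or {"addition_replicates": 2}
    if method == "mp":
        mp_kwargs.setdefault("addition_replicates", 2)
    main_tree = _build_tree(aln, method, seed, mp_kwargs if method == "mp" else {})
    replicate_trees: list[Node] = []
    split_counts: dict[frozenset[str], int] = {}
    for i in range(replicates):
        rng = np.random.default_rng((seed, i))
        sample = _resample_alignment(aln, rng)
        tie_order = [aln.ids[j] for j in rng.permutation(len(aln.ids))]
        rep_tree = _build_tree(
            sample,
            method,
            seed + i + 1,
            mp_kwargs if method == "mp" else {},
            tie_order=tie_order,
        )
        replicate_trees.append(rep_tree)
        for split in tree_splits(rep_tree):
            split_counts[split] = split_counts.get(split, 0) + 1

    all_leaves = frozenset(aln.ids)
    anchor = min(all_leaves)
    for node in main_tree.postorder():
        if node.is_leaf or node is main_tree:
            continue
        side = frozenset(node.leaves())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            node.support = 100.0 * split_counts.get(side, 0) / replicates

    tree = main_tree
    if collapse_below is not None:
        tree = collapse_unsupported(main_tree, collapse_below)
    return BootstrapResult(
        tree=tree, replicates=replicate_trees, method=method, n_replicates=replicates
    )


def collapse_unsupported(tree: Node, threshold: float) -> Node:
    """Collapse internal edges with support below ``threshold`` percent."""
    out = tree.copy()

    def collapse(node: Node) -> None:
        new_children: list[Node] = []
        for child in node.children:
            collapse(child)
            if (
                not child.is_leaf
                and child.support is not None
                and child.support < threshold
            ):
                new_children.extend(child.children)
            else:
                new_children.append(child)
        node.children = new_children

    collapse(out)
    return out


@dataclass
class CladeSupportReport:
    group_name: str
    taxa: frozenset[str]
    ignored: frozenset[str]
    support: float
    method: str = ""
    dataset: str = ""
    n_replicates: int = 0


def is_monophyletic(tree: Node, group: frozenset[str], ignored: frozenset[str] = frozenset()) -> bool:
    """Unrooted monophyly of a taxon group, after pruning ignored taxa."""
    leaves = frozenset(tree.leaves()) - ignored
    target = group - ignored
    if not target:
        return False
    if len(target) <= 1 or len(target) >= len(leaves) - 1:
        return True
    all_leaves = frozenset(tree.leaves())
    for node in tree.postorder():
        if node.is_leaf or node is tree:
            continue
        side = frozenset(node.leaves()) - ignored
        if target == side or target == leaves - side:
            return True
    # also check the implicit split at the root of the rooted representation
    if tree.children:
        side = frozenset(tree.children[0].leaves()) - ignored
        if target == side or target == leaves - side:
            return True
    return False


def group_support(
    replicate_trees: list[Node],
    group_name: str,
    taxa: list[str] | frozenset[str],
    ignored: list[str] | frozenset[str] = frozenset(),
    method: str = "",
    dataset: str = "",
) -> CladeSupportReport:
    """Percentage of replicate trees in which the group is monophyletic
    (ignored rogue taxa pruned before assessment)."""
    taxa = frozenset(taxa)
    ignored = frozenset(ignored)
    if not taxa:
        raise DegenerateInputError(f"group {group_name!r} is empty")
    if not replicate_trees:
        raise DegenerateInputError("no replicate trees")
    leaf_set = frozenset(replicate_trees[0].leaves())
    if not taxa <= leaf_set:
        raise FrameError(
            f"group {group_name!r} has taxa outside the tree leaf set: "
            f"{sorted(taxa - leaf_set)}"
        )
    hits = sum(1 for t in replicate_trees if is_monophyletic(t, taxa, ignored))
    return CladeSupportReport(
        group_name=group_name,
        taxa=taxa,
        ignored=ignored,
        support=100.0 * hits / len(replicate_trees),
        method=method,
        dataset=dataset,
        n_replicates=len(replicate_trees),
    )
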