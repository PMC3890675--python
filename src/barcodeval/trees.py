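"""Neighbour-joining phylograms and species-monophyly scoring.

Trees are stored rooted for traversal but monophyly is assessed on
unrooted bipartitions: a species is monophyletic when some edge
separates exactly its specimens from everything else, which makes the
test independent of root placement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

from .distances import DistanceMatrix, round_half_up
from .io_alignments import SpecimenRecord


class Node:
    """A tree node; ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = length
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Tree:
    """A phylogram with named leaves; supports bipartition queries.

    The root is a bookkeeping device: a tree produced by neighbour
    joining is rooted at an internal node of degree three and should be
    read as unrooted.
    """

    def __init__(self, root: Node):
        self.root = root

    # -- traversal -----------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        yield from reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    # -- bipartitions --------------------------------------------------
    def bipartitions(self) -> Iterator[frozenset]:
        """Yield the leaf set below every non-root edge.

        Each edge of the unrooted tree corresponds to the split
        (yielded set | complement).  Trivial splits (single leaves) are
        included.
        """
        below: dict[int, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.name])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children)
                )
            if node is not self.root:
                yield below[id(node)]

    # -- metrics -------------------------------------------------------
    def depths(self) -> dict[int, float]:
        """Root-to-node path lengths keyed by id(node)."""
        out = {id(self.root): 0.0}
        for node in self.preorder():
            for c in node.children:
                out[id(c)] = out[id(node)] + c.length
        return out

    def path_length_matrix(self, order: Optional[Sequence[str]] = None) -> DistanceMatrix:
        """Leaf-to-leaf path lengths (additive distances) on the tree."""
        leaves = self.leaves()
        if order is not None:
            by_name = {n.name: n for n in leaves}
            leaves = [by_name[name] for name in order]
        names = [n.name for n in leaves]
        depth = self.depths()
        # ancestor chains for LCA lookup
        chains = []
        for leaf in leaves:
            chain = []
            node: Optional[Node] = leaf
            while node is not None:
                chain.append(id(node))
                node = node.parent
            chains.append(set(chain))
        anc_depth = depth
        n = len(leaves)
        d = np.zeros((n, n))
        for i in range(n):
            node_i = leaves[i]
            for j in range(i + 1, n):
                # deepest common ancestor of leaf i and leaf j
                node: Optional[Node] = leaves[j]
                while id(node) not in chains[i]:
                    node = node.parent
                lca = node
                dij = anc_depth[id(node_i)] + anc_depth[id(leaves[j])] - 2 * anc_depth[id(lca)]
                d[i, j] = d[j, i] = dij
        return DistanceMatrix(labels=tuple(names), d=d, method="path_length")

    # -- serialisation -------------------------------------------------
    def newick(self, precision: int = 10) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node is self.root:
                return body
            return f"{body}:{node.length:.{precision}g}"

        return fmt(self.root) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def nj_tree(matrix: DistanceMatrix) -> Tree:
    """Neighbour joining (Saitou & Nei) with deterministic tie-breaking.

    At each step the pair minimising the Studier-Keppler criterion
    Q(i,j) = (r-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k) is joined; ties
    are broken toward the lexicographically smallest pair of cluster
    keys, each cluster being keyed by its smallest leaf label, so the
    topology is invariant to input row order.  Negative branch lengths
    are clamped to zero with the deficit moved to the sister branch
    (path lengths through the new node are preserved).
    """
    if matrix.n < 3:
        raise ValueError("neighbour joining needs at least 3 specimens")
    if np.isnan(matrix.d).any():
        bad = [
            matrix.labels[i]
            for i in range(matrix.n)
            if np.isnan(matrix.d[i]).any()
        ]
        raise ValueError(
            "distance matrix has UNDEFINED cells (specimens: "
            f"{bad[:5]}{'...' if len(bad) > 5 else ''}); drop or re-estimate "
            "these specimens before tree building"
        )
    # active clusters: parallel lists of keys and nodes, plus the matrix
    keys = [(lab,) for lab in matrix.labels]  # key = smallest leaf label, as 1-tuple
    keys = [min(k) for k in keys]
    nodes = [Node(name=lab) for lab in matrix.labels]
    d = matrix.d.astype(float).copy()

    def clamp_pair(a: Node, b: Node) -> None:
        if a.length < 0:
            b.length += a.length
            a.length = 0.0
        if b.length < 0:
            a.length += b.length
            b.length = 0.0
        a.length = max(a.length, 0.0)
        b.length = max(b.length, 0.0)

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        # deterministic tie-break: smallest sorted key pair
        best = min(
            (tuple(sorted((keys[i], keys[j]))), i, j)
            for i, j in cand
            if i < j
        )
        _, i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        new = Node()
        ni, nj = nodes[i], nodes[j]
        ni.length, nj.length = li, lj
        clamp_pair(ni, nj)
        new.add_child(ni)
        new.add_child(nj)
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]

    # terminal three-way join: closed-form branch lengths
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    root = Node()
    a.length = 0.5 * (dab + dac - dbc)
    b.length = 0.5 * (dab + dbc - dac)
    c.length = 0.5 * (dac + dbc - dab)
    for node in (a, b, c):
        node.length = max(node.length, 0.0)
    for node in (a, b, c):
        root.add_child(node)
    return Tree(root)


@dataclass(frozen=True)
class SpeciesMonophyly:
    species: str
    n_specimens: int
    monophyletic: bool
    singleton: bool


@dataclass(frozen=True)
class MonophylyReport:
    """Per-species monophyly calls and summary proportions.

    ``pct_monophyletic`` counts singletons as monophyletic (they
    trivially cluster); ``pct_monophyletic_multi`` excludes them, since
    singleton-heavy datasets otherwise overstate resolution.
    """

    records: tuple[SpeciesMonophyly, ...]

    @property
    def n_species(self) -> int:
        return len(self.records)

    @property
    def n_monophyletic(self) -> int:
        return sum(r.monophyletic for r in self.records)

    @property
    def pct_monophyletic(self) -> int:
        return round_half_up(100.0 * self.n_monophyletic / self.n_species)

    @property
    def pct_monophyletic_multi(self) -> Optional[int]:
        multi = [r for r in self.records if not r.singleton]
        if not multi:
            return None
        return round_half_up(100.0 * sum(r.monophyletic for r in multi) / len(multi))


def species_monophyly(
    tree: Tree, specimens: Sequence[SpecimenRecord]
) -> MonophylyReport:
    """Score each species as monophyletic or not on an (unrooted) tree.

    A species with >= 2 sampled specimens is monophyletic iff some
    bipartition side equals exactly its specimen set (or its
    complement).  Singletons are counted monophyletic and flagged.
    """
    species_of = {s.specimen_id: s.species for s in specimens}
    leaf_names = tree.leaf_names()
    unknown = [name for name in leaf_names if name not in species_of]
    if unknown:
        raise ValueError(f"leaves without species assignment: {unknown[:5]}")
    all_leaves = frozenset(leaf_names)
    members: dict[str, set] = {}
    for name in leaf_names:
        members.setdefault(species_of[name], set()).add(name)
    sides = set()
    for side in tree.bipartitions():
        sides.add(side)
        sides.add(all_leaves - side)
    records = []
    for sp in sorted(members):
        group = frozenset(members[sp])
        singleton = len(group) == 1
        mono = singleton or group == all_leaves or group in sides
        records.append(
            SpeciesMonophyly(
                species=sp,
                n_specimens=len(group),
                monophyletic=bool(mono),
                singleton=singleton,
            )
        )
    return MonophylyReport(records=tuple(records))
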