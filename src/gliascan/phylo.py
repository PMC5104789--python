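"""Poisson-corrected distances, neighbor joining and bootstrap supports.

Distances use the Poisson correction d = -ln(1 - p) where p is the
proportion of differing sites over columns where neither sequence has a
gap or an ``X`` (pairwise deletion).  Tree construction is the classical
Saitou-Nei neighbor-joining agglomeration with deterministic
tie-breaking (lowest active-index pair); on an additive matrix the
leaf-to-leaf path lengths reproduce the input exactly.  Negative branch
length estimates are clamped to zero with a warning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "TreeNode",
    "PhyloTree",
    "poisson_distance",
    "neighbor_joining",
    "bootstrap_support",
    "confirm_assignment",
]

_SKIP_CHARS = frozenset("-X")


@dataclass
class Alignment:
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        if not ids:
            raise ValueError(f"no records in {path}")
        return cls(ids=ids, rows=rows)

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_sites, size=self.n_sites)
        rows = ["".join(row[c] for c in cols) for row in self.rows]
        return Alignment(ids=list(self.ids), rows=rows)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix is not symmetric")
        if (m < 0).any():
            raise ValueError("distance matrix has negative entries")
        if not np.all(np.isfinite(m)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("distance matrix diagonal is not zero")
        self.matrix = m


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Unrooted tree held with an arbitrary internal root."""

    def __init__(self, root: TreeNode):
        self.root = root

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(child for child, _ in reversed(node.children))
        return out

    def leaf_names(self) -> list[str]:
        return [leaf.name for leaf in self.leaves()]

    def _adjacency(self) -> dict[int, list[tuple[TreeNode, float]]]:
        adj: dict[int, list[tuple[TreeNode, float]]] = {}
        nodes = [self.root]
        while nodes:
            node = nodes.pop()
            for child, length in node.children:
                adj.setdefault(id(node), []).append((child, length))
                adj.setdefault(id(child), []).append((node, length))
                nodes.append(child)
        return adj

    def path_lengths(self) -> dict[tuple[str, str], float]:
        """Leaf-to-leaf path lengths, keyed by sorted name pairs."""
        adj = self._adjacency()
        leaves = self.leaves()
        dists: dict[tuple[str, str], float] = {}
        for start in leaves:
            seen = {id(start): 0.0}
            stack = [start]
            while stack:
                node = stack.pop()
                for nbr, length in adj.get(id(node), []):
                    if id(nbr) not in seen:
                        seen[id(nbr)] = seen[id(node)] + length
                        stack.append(nbr)
            for other in leaves:
                if other.name > start.name:
                    dists[(start.name, other.name)] = seen[id(other)]
        return dists

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the leaf side not containing
        the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        parts: set[frozenset[str]] = set()

        def clade(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            out: frozenset[str] = frozenset()
            for child, _ in node.children:
                side = clade(child)
                if 1 < len(side) < len(all_leaves) - 1:
                    canonical = side if anchor not in side else all_leaves - side
                    parts.add(canonical)
                out |= side
            return out

        clade(self.root)
        return parts

    def to_newick(self, support_as_percent: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name or ""
            inner = ",".join(
                f"{fmt(child)}:{length:.6f}" for child, length in node.children
            )
            label = ""
            if node.support is not None:
                label = (
                    f"{round(node.support * 100)}"
                    if support_as_percent
                    else f"{node.support:.3f}"
                )
            return f"({inner}){label}"

        return fmt(self.root) + ";"


def poisson_distance(aln: Alignment) -> DistanceMatrix:
    """Pairwise Poisson-corrected distances with pairwise deletion."""
    n = len(aln.ids)
    if n < 2:
        raise ValueError("need at least 2 rows")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aln.rows[i], aln.rows[j]
            compared = diffs = 0
            for x, y in zip(a, b):
                if x in _SKIP_CHARS or y in _SKIP_CHARS:
                    continue
                compared += 1
                if x != y:
                    diffs += 1
            pair = f"({aln.ids[i]!r}, {aln.ids[j]!r})"
            if compared == 0:
                raise ValueError(f"no comparable sites for pair {pair}")
            p = diffs / compared
            if p >= 1.0:
                raise ValueError(f"saturated pair {pair}: p = {p:.3f}")
            m[i, j] = m[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(ids=list(aln.ids), matrix=m)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with lowest-index-pair tie-breaking."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    d = dm.matrix.copy()
    active = list(range(n))

    def clamp(length: float) -> float:
        if length < 0:
            if length < -1e-9:
                warnings.warn(
                    f"negative NJ branch length {length:.3g} clamped to 0",
                    stacklevel=2,
                )
            return 0.0
        return length

    while len(active) > 2:
        m = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[(nodes[i], clamp(li)), (nodes[j], clamp(lj))])
        new_index = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
            d[new_index, k] = d[k, new_index] = dk
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [new_index]

    a, b = active
    # attach the remaining pair; prefer an internal node as root
    if nodes[a].is_leaf and not nodes[b].is_leaf:
        a, b = b, a
    root = nodes[a]
    root.children.append((nodes[b], clamp(d[a, b])))
    return PhyloTree(root)


def bootstrap_support(
    aln: Alignment, n_reps: int, seed: int
) -> tuple[PhyloTree, dict[frozenset[str], float]]:
    """NJ tree on the full alignment with bipartition bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; support is
    the fraction of replicate trees containing each internal bipartition
    of the full-data tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = neighbor_joining(poisson_distance(aln))
    targets = tree.bipartitions()
    counts = {bp: 0 for bp in targets}
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        rep_tree = neighbor_joining(poisson_distance(rep))
        rep_parts = rep_tree.bipartitions()
        for bp in targets:
            if bp in rep_parts:
                counts[bp] += 1
    supports = {bp: c / n_reps for bp, c in counts.items()}
    _annotate_supports(tree, supports)
    return tree, supports


def _annotate_supports(
    tree: PhyloTree, supports: Mapping[frozenset[str], float]
) -> None:
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)

    def visit(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])
        side: frozenset[str] = frozenset()
        for child, _ in node.children:
            side |= visit(child)
        canonical = side if anchor not in side else all_leaves - side
        if canonical in supports:
            node.support = supports[canonical]
        return side

    visit(tree.root)


def confirm_assignment(
    tree: PhyloTree,
    reference_labels: Mapping[str, str],
    motif_calls: Mapping[str, str] | None = None,
    k: int = 3,
) -> dict[str, tuple[str, Optional[bool]]]:
    """Genome per unlabeled leaf from its k nearest labeled references.

    Each unlabeled leaf inherits the majority genome among its ``k``
    nearest references by path length (distance ties resolved by leaf
    order); a majority tie leaves the sequence unassigned.  Returns
    ``{leaf: (genome, concordant_with_motif_call)}``.
    """
    leaf_names = tree.leaf_names()
    refs = [name for name in leaf_names if name in reference_labels]
    if not refs:
        raise ValueError("tree contains no labeled references")
    present = {reference_labels[r] for r in refs}
    for genome in ("A", "B", "D"):
        if genome not in present:
            raise ValueError(f"no reference for genome {genome} in tree")
    dists = tree.path_lengths()

    def dist(x: str, y: str) -> float:
        return 0.0 if x == y else dists[tuple(sorted((x, y)))]

    ref_order = {name: i for i, name in enumerate(leaf_names)}
    out: dict[str, tuple[str, Optional[bool]]] = {}
    for leaf in leaf_names:
        if leaf in reference_labels:
            continue
        nearest = sorted(refs, key=lambda r: (dist(leaf, r), ref_order[r]))[:k]
        votes: dict[str, int] = {}
        for r in nearest:
            votes[reference_labels[r]] = votes.get(reference_labels[r], 0) + 1
        top = max(votes.values())
        winners = [g for g, v in votes.items() if v == top]
        genome = winners[0] if len(winners) == 1 else "unassigned"
        concordant = None
        if motif_calls is not None and leaf in motif_calls:
            concordant = motif_calls[leaf] == genome
        out[leaf] = (genome, concordant)
    return out
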