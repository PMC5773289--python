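"""Rooted phylogenies with branch lengths in millions of years.

The tree container is a small array-backed structure tuned for repeated
postorder likelihood passes; Newick I/O is delegated to dendropy.  Node ages
follow the palaeontological convention: age = tree depth - distance from the
root, so tips of an ultrametric tree sit at age 0 and ages increase into the
past ("million years ago").
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_newick", "prune_to_taxa"]


class Phylogeny:
    """A rooted tree with branch lengths (My).

    Nodes are integer-indexed in preorder (root = 0, so every node's parent
    has a smaller index).  ``edge_length[i]`` is the length of the branch
    above node ``i`` (0 for the root).  Tips carry labels; internal nodes may.
    """

    __slots__ = ("parent", "edge_length", "labels", "children", "postorder",
                 "_depths", "_tip_index")

    def __init__(self, parent: Sequence[int], edge_length: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=np.float64)
        self.labels = [lb if lb else None for lb in labels]
        n = len(self.parent)
        if not (len(self.edge_length) == len(self.labels) == n):
            raise ValueError("parent, edge_length and labels must have equal length")
        if (self.parent == -1).sum() != 1 or self.parent[0] != -1:
            raise ValueError("exactly one root expected, at index 0")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("nodes must be in preorder (parent index < child index)")
        if not np.all(np.isfinite(self.edge_length)) or np.any(self.edge_length < 0):
            raise ValueError("branch lengths must be finite and >= 0")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        tips = [i for i in range(n) if not self.children[i]]
        tip_labels = [self.labels[i] for i in tips]
        if any(lb is None for lb in tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            dup = sorted({lb for lb in tip_labels if tip_labels.count(lb) > 1})
            raise ValueError(f"duplicate tip labels: {dup}")
        # preorder indexing makes reversed(range(n)) a valid postorder
        self.postorder = np.arange(n - 1, -1, -1)
        self._depths = None
        self._tip_index = {self.labels[i]: i for i in tips}

    # -- basic structure -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    @property
    def tip_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self._tip_index)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    def tip_index(self, label: str) -> int:
        return self._tip_index[label]

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    # -- metrics ---------------------------------------------------------

    @property
    def node_depths(self) -> np.ndarray:
        """Distance from the root to each node (My)."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for i in range(1, self.n_nodes):
                d[i] = d[self.parent[i]] + self.edge_length[i]
            self._depths = d
        return self._depths

    @property
    def depth(self) -> float:
        """Tree depth: the largest root-to-tip distance (My)."""
        return float(self.node_depths[self.tip_indices].max())

    @property
    def node_ages(self) -> np.ndarray:
        """Age of each node, My before present (tips of an ultrametric tree = 0)."""
        return self.depth - self.node_depths

    @property
    def total_branch_length(self) -> float:
        return float(self.edge_length.sum())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        tip_depths = self.node_depths[self.tip_indices]
        return bool(np.ptp(tip_depths) <= rel_tol * max(self.depth, 1e-300))

    def patristic_distances(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise path-length matrix between tips, in ``labels`` order."""
        labels = list(labels) if labels is not None else self.tip_labels
        idx = [self.tip_index(lb) for lb in labels]
        depths = self.node_depths
        m = len(idx)
        out = np.zeros((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                mrca = self.mrca(idx[a], idx[b])
                out[a, b] = out[b, a] = depths[idx[a]] + depths[idx[b]] - 2 * depths[mrca]
        return out

    def mrca(self, i: int, j: int) -> int:
        anc = set()
        a = i
        while a != -1:
            anc.add(a)
            a = self.parent[a]
        b = j
        while b not in anc:
            b = self.parent[b]
        return b

    def shared_path_matrix(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Root-to-MRCA shared path lengths between tips (Brownian covariance
        up to a rate factor)."""
        labels = list(labels) if labels is not None else self.tip_labels
        idx = [self.tip_index(lb) for lb in labels]
        depths = self.node_depths
        m = len(idx)
        out = np.empty((m, m))
        for a in range(m):
            out[a, a] = depths[idx[a]]
            for b in range(a + 1, m):
                out[a, b] = out[b, a] = depths[self.mrca(idx[a], idx[b])]
        return out

    # -- I/O ---------------------------------------------------------------

    def to_newick(self) -> str:
        parts: dict[int, str] = {}
        for i in self.postorder:
            lb = self.labels[i]
            name = _quote_label(lb) if lb else ""
            if self.children[i]:
                inner = ",".join(parts.pop(c) for c in self.children[i])
                name = f"({inner}){name}"
            if i == self.root:
                parts[i] = f"{name};"
            else:
                parts[i] = f"{name}:{self.edge_length[i]:.10g}"
        return parts[self.root]

    def rescale(self, factor: float) -> "Phylogeny":
        """Return a copy with every branch length multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Phylogeny(self.parent, self.edge_length * factor, self.labels)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny: {self.n_tips} tips, depth {self.depth:.4g} My>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " (),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    parent, lengths, labels = [], [], []
    index: dict[int, int] = {}
    for node in dtree.preorder_node_iter():
        i = len(parent)
        index[id(node)] = i
        if node.parent_node is None:
            parent.append(-1)
            lengths.append(0.0)
        else:
            parent.append(index[id(node.parent_node)])
            if node.edge.length is None:
                where = node.taxon.label if node.taxon else "an internal node"
                raise ValueError(f"missing branch length on the edge above {where}")
            lengths.append(float(node.edge.length))
        if node.taxon is not None:
            labels.append(node.taxon.label)
        else:
            labels.append(node.label)
    return Phylogeny(parent, lengths, labels)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths mandatory) into a Phylogeny.

    Raises ``ValueError`` on malformed input, quoting the parser's position
    information, or when a branch length is missing.
    """
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse failure: {exc}") from exc
    if dtree.seed_node is None or not dtree.seed_node.child_nodes():
        raise ValueError("Newick parse failure: empty tree")
    return _from_dendropy(dtree)


def prune_to_taxa(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Restrict ``tree`` to the tips in ``keep``.

    Unary internal nodes created by the pruning are suppressed with their
    branch lengths summed, so path lengths between retained tips are
    preserved exactly.
    """
    keep = set(keep)
    missing = sorted(keep - set(tree.tip_labels))
    if missing:
        raise ValueError(f"taxa not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")

    n = tree.n_nodes
    retained = np.zeros(n, dtype=np.int64)  # retained tip descendants per node
    for i in tree.postorder:
        if tree.is_tip(i):
            retained[i] = 1 if tree.labels[i] in keep else 0
        else:
            retained[i] = sum(retained[c] for c in tree.children[i])

    # new root: deepest node through which all retained tips pass
    root = tree.root
    while True:
        live = [c for c in tree.children[root] if retained[c] > 0]
        if len(live) == 1 and retained[live[0]] == retained[root]:
            root = live[0]
        else:
            break

    parent_new: list[int] = [-1]
    length_new: list[float] = [0.0]
    labels_new: list[str | None] = [tree.labels[root]]
    # stack of (old node, new parent index, accumulated edge length)
    stack = [(c, 0, tree.edge_length[c]) for c in reversed(tree.children[root])
             if retained[c] > 0]
    while stack:
        old, newpar, acc = stack.pop()
        live = [c for c in tree.children[old] if retained[c] > 0]
        if len(live) == 1 and not tree.is_tip(old):
            stack.append((live[0], newpar, acc + tree.edge_length[live[0]]))
            continue
        i = len(parent_new)
        parent_new.append(newpar)
        length_new.append(acc)
        labels_new.append(tree.labels[old])
        for c in reversed(live):
            stack.append((c, i, tree.edge_length[c]))
    return Phylogeny(parent_new, length_new, labels_new)
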