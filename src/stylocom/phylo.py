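"""Phylogenetic trees, Brownian-motion covariance and ancestral states.

Trees are rooted with branch lengths (Newick, read/written through
dendropy).  Under Brownian motion with rate sigma^2, the covariance between
two tips equals sigma^2 times the root-to-MRCA path length they share
(:func:`brownian_vcv` returns that shared-path matrix).

Ancestral state reconstruction (:func:`asr_brownian`) gives the maximum-
likelihood states of a continuous trait at every internal node.  The
implementation is the two-pass weighted-mean algorithm: a pruning downpass
computes, for each node, the inverse-branch-length-weighted estimate from
its descendants; an uppass propagates the estimate from the rest of the
tree, so each node's state is the estimate obtained by re-rooting the tree
at that node — equivalent to the GLS estimator on the full Brownian
covariance extended to internal nodes, but O(n) per node.  The Brownian
rate sigma^2 is the ML estimate (contrast sum of squares divided by n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "AsrResult",
    "parse_newick",
    "read_newick",
    "brownian_vcv",
    "asr_brownian",
]


class PhyloTree:
    """A rooted tree with branch lengths and unique tip labels.

    Thin wrapper over a :class:`dendropy.Tree`; internal nodes get stable
    ``node<k>`` identifiers in preorder where unlabelled.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate_and_label()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                suppress_internal_node_taxa=True,
                suppress_leaf_node_taxa=True,
            )
        except Exception as exc:  # dendropy reader errors -> uniform ValueError
            raise ValueError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def _validate_and_label(self) -> None:
        seen: set[str] = set()
        counter = 0
        for node in self._tree.preorder_node_iter():
            is_root = node.parent_node is None
            if not is_root and node.edge.length is None:
                raise ValueError(
                    f"missing branch length on edge above node "
                    f"{_node_name(node) or '<unlabelled internal>'}"
                )
            if not is_root and node.edge.length < 0:
                raise ValueError(f"negative branch length above {_node_name(node)}")
            if node.is_leaf():
                label = _node_name(node)
                if not label:
                    raise ValueError("tip without a label")
                if label in seen:
                    raise ValueError(f"duplicate tip label {label!r}")
                seen.add(label)
                node.stylocom_id = label
            else:
                label = _node_name(node)
                node.stylocom_id = label if label else f"node{counter}"
                counter += 1

    # -- queries ------------------------------------------------------------

    @property
    def tips(self) -> list[str]:
        """Tip labels in tree (preorder) traversal order."""
        return [_node_name(n) for n in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def root(self):
        return self._tree.seed_node

    def depths(self) -> dict[str, float]:
        """Root-to-node path length for every node, keyed by node id.

        A root edge (the stem retained by :meth:`prune_to` when the kept
        taxa coalesce below the original root) counts towards every depth.
        """
        out: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                depth = node.edge.length or 0.0
            else:
                depth = out[parent.stylocom_id] + node.edge.length
            out[node.stylocom_id] = depth
        return out

    def prune_to(self, labels: list[str]) -> "PhyloTree":
        """Subtree induced by the given tip labels (order-insensitive).

        Root-to-tip path lengths are preserved: branches below the kept
        taxa's MRCA are accumulated into a root edge, so the Brownian
        covariance of the pruned tree is exactly the corresponding
        submatrix of the full tree's covariance.
        """
        keep = set(labels)
        missing = keep - set(self.tips)
        if missing:
            raise ValueError(f"taxa absent from tree: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        # drop unwanted leaves until every leaf is a kept taxon
        changed = True
        while changed:
            changed = False
            for leaf in list(tree.leaf_node_iter()):
                if _node_name(leaf) not in keep:
                    if leaf.parent_node is None:
                        raise ValueError("cannot prune away every taxon")
                    leaf.parent_node.remove_child(leaf)
                    changed = True
        # merge unifurcations, accumulating lengths; keep the stem on the root
        for node in list(tree.postorder_node_iter()):
            children = node.child_nodes()
            if len(children) != 1 or node.parent_node is None:
                continue
            child = children[0]
            child.edge.length += node.edge.length
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
        root = tree.seed_node
        stem = root.edge.length or 0.0
        while len(root.child_nodes()) == 1:
            child = root.child_nodes()[0]
            stem += child.edge.length
            child.parent_node = None
            root = child
        root.edge.length = stem if stem > 0 else None
        tree.seed_node = root
        return PhyloTree(tree)

    def to_newick(self) -> str:
        def render(node) -> str:
            if node.is_leaf():
                out = node.stylocom_id
            else:
                out = "(" + ",".join(render(c) for c in node.child_nodes()) + ")"
                out += node.stylocom_id  # keep internal ids stable across round trips
            length = node.edge.length
            if length is not None and (node.parent_node is not None or length > 0):
                out += f":{length:.10g}"
            return out

        return render(self.root) + ";"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick() + "\n")


def _node_name(node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian shared-path-length matrix in a declared taxon order."""

    taxa: list[str]
    matrix: np.ndarray

    def dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.taxa, columns=self.taxa)


@dataclass(frozen=True)
class AsrResult:
    """ML ancestral states: internal-node estimates, Brownian rate, root."""

    node_states: dict[str, float]
    rate: float
    root_state: float


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`."""
    return PhyloTree.from_newick(text)


def read_newick(path: str | Path) -> PhyloTree:
    return parse_newick(Path(path).read_text())


def brownian_vcv(tree: PhyloTree, taxa: list[str] | None = None) -> PhyloCovariance:
    """Shared root-to-MRCA path lengths between all tip pairs.

    Entry (i, j) is the depth of the most recent common ancestor of tips i
    and j; the diagonal holds root-to-tip distances.  Computed in one
    postorder sweep: each internal node at depth d contributes d as the
    covariance of every tip pair split between different child subtrees.
    """
    order = taxa if taxa is not None else tree.tips
    pos = {label: k for k, label in enumerate(order)}
    if len(pos) != len(order):
        raise ValueError("duplicate taxa in requested order")
    n = len(order)
    V = np.zeros((n, n))
    depths = tree.depths()

    tipsets: dict[int, list[int]] = {}
    for node in tree._tree.postorder_node_iter():
        if node.is_leaf():
            label = _node_name(node)
            tipsets[id(node)] = [pos[label]] if label in pos else []
            if label in pos:
                V[pos[label], pos[label]] = depths[node.stylocom_id]
            continue
        children = [tipsets.pop(id(c)) for c in node.child_nodes()]
        d = depths[node.stylocom_id]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    for j in children[b]:
                        V[i, j] = V[j, i] = d
        tipsets[id(node)] = [i for group in children for i in group]
    covered = tipsets.pop(id(tree.root))
    if len(covered) != n:
        raise ValueError("requested taxa not all present in tree")
    return PhyloCovariance(taxa=list(order), matrix=V)


def _combine(estimates: list[tuple[float, float]], context: str) -> tuple[float, float, float]:
    """Inverse-variance combination of (estimate, variance) pairs.

    Returns the pooled estimate, pooled variance, and the contrast sum of
    squares accumulated while merging (each merge of two independent
    estimates contributes (x1 - x2)^2 / (v1 + v2)).
    """
    x, v = estimates[0]
    ss = 0.0
    for x2, v2 in estimates[1:]:
        denom = v + v2
        if denom <= 0:
            if x != x2:
                raise ValueError(
                    f"singular system at {context}: zero-length branches join "
                    "tips with conflicting values"
                )
            continue
        ss += (x - x2) ** 2 / denom
        x = (x * v2 + x2 * v) / denom
        v = v * v2 / denom
    return x, v, ss


def asr_brownian(tree: PhyloTree, tip_values: dict[str, float]) -> AsrResult:
    """ML ancestral states of a continuous trait under Brownian motion.

    Every tip must have a value.  Zero-length *internal* branches are
    collapsed (with a warning) before reconstruction; zero-length terminal
    branch pairs carrying conflicting values make the system singular and
    are rejected.
    """
    missing = set(tree.tips) - set(tip_values)
    if missing:
        raise ValueError(f"tips without trait values: {sorted(missing)}")

    work = PhyloTree(tree._tree.clone(depth=1))
    collapsed = []
    for node in list(work._tree.postorder_node_iter()):
        if (
            node.parent_node is not None
            and not node.is_leaf()
            and node.edge.length == 0
        ):
            collapsed.append(node.stylocom_id)
            node.edge.collapse()
    if collapsed:
        warnings.warn(
            f"collapsed zero-length internal branches above nodes {collapsed}",
            stacklevel=2,
        )
        work = PhyloTree(work._tree)

    # Downpass: below-estimate (x, v) per node from its subtree only.
    below: dict[int, tuple[float, float]] = {}
    total_ss = 0.0
    for node in work._tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = (float(tip_values[_node_name(node)]), 0.0)
            continue
        ests = [
            (below[id(c)][0], below[id(c)][1] + c.edge.length)
            for c in node.child_nodes()
        ]
        x, v, ss = _combine(ests, context=f"node {node.stylocom_id}")
        total_ss += ss
        below[id(node)] = (x, v)

    n = work.n_tips
    root = work.root
    root_state = below[id(root)][0]
    rate = total_ss / n  # ML (divide by n), consistent with joint-ML states

    # Uppass: above-estimate (A, S) per non-root node, positioned at its
    # parent, from everything outside the node's subtree.
    above: dict[int, tuple[float, float]] = {}
    node_states: dict[str, float] = {root.stylocom_id: root_state}
    for node in work._tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = node.parent_node
        ests = [
            (below[id(s)][0], below[id(s)][1] + s.edge.length)
            for s in parent.child_nodes()
            if s is not node
        ]
        if parent.parent_node is not None:
            A_p, S_p = above[id(parent)]
            ests.append((A_p, S_p + parent.edge.length))
        A, S, _ = _combine(ests, context=f"node {node.stylocom_id}")
        above[id(node)] = (A, S)
        if not node.is_leaf():
            x_b, v_b = below[id(node)]
            state, _, _ = _combine([(x_b, v_b), (A, S + node.edge.length)],
                                   context=f"node {node.stylocom_id}")
            node_states[node.stylocom_id] = state

    return AsrResult(node_states=node_states, rate=rate, root_state=root_state)
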