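"""Rooted-phylogeny data model, Newick I/O, and tree surgery.

The tree container is :class:`dendropy.Tree`; every function in this module
accepts and returns rooted dendropy trees with non-negative branch lengths.
Tree surgery (pruning, polytomy operations) is implemented here so that its
contracts — exact preservation of patristic distances under pruning, exact
preservation of root-to-tip path lengths under polytomy collapse — hold to
the last bit, which the diversity metrics downstream rely on.

Conventions
-----------
* Trees are rooted as given in the Newick string; no re-rooting is ever
  performed.
* Unifurcations (nodes with exactly one child) never appear in a returned
  tree; suppressing one sums the two incident branch lengths.
* Wherever iteration order could leak into output, tips are processed in
  lexicographic label order; no metric depends on the order.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "TreeError",
    "NewickParseError",
    "DistanceMatrix",
    "read_newick",
    "write_newick",
    "tip_labels",
    "total_tree_length",
    "patristic_distances",
    "prune_to_tips",
    "collapse_short_edges",
    "collapse_group_to_polytomy",
    "resolution_fraction",
    "monophyly_rate",
    "read_taxonomy",
    "edge_incidence",
]


class TreeError(ValueError):
    """A tree violates a structural precondition."""


class NewickParseError(TreeError):
    """Malformed Newick input; the message carries dendropy's line/column."""


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def read_newick(
    text: str, *, missing_length: str = "error", allow_negative: bool = False
) -> dendropy.Tree:
    """Parse a rooted tree from a Newick string.

    Parameters
    ----------
    text:
        Newick string with a terminating semicolon.  Polytomies and quoted
        labels are allowed; underscores inside unquoted labels are kept
        literal (quote a label to embed spaces).
    missing_length:
        ``"error"`` (default) rejects trees with absent branch lengths;
        ``"zero"`` assigns 0 to absent lengths.
    allow_negative:
        Accept negative branch lengths (e.g. re-reading an MPL chronogram
        kept under the ``warn`` policy); by default they are rejected.

    Unifurcations present in the input are suppressed (their branch lengths
    summed) with a warning.  Duplicate tip labels and negative branch
    lengths are rejected.
    """
    if missing_length not in ("error", "zero"):
        raise ValueError(f"missing_length must be 'error' or 'zero', got {missing_length!r}")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        raise NewickParseError(str(exc)) from None

    # dendropy rejects duplicate leaf taxa itself, but double-check cheaply
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    seen: set[str] = set()
    for lab in labels:
        if not lab:
            raise TreeError("empty tip label")
        if lab in seen:
            raise TreeError(f"duplicate tip label: {lab!r}")
        seen.add(lab)

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            if missing_length == "zero":
                node.edge.length = 0.0
            else:
                raise TreeError(
                    "branch length missing (pass missing_length='zero' to assign 0)"
                )
        elif node.edge.length < 0 and not allow_negative:
            raise TreeError(f"negative branch length {node.edge.length} in input")
    # the root's own edge is not part of the tree
    tree.seed_node.edge.length = None

    if _has_unifurcation(tree):
        warnings.warn("input contains unifurcations; suppressing (lengths summed)")
        _suppress_unifurcations(tree)
    if sum(1 for _ in tree.leaf_node_iter()) < 2:
        warnings.warn("tree has fewer than 2 tips")
    return tree


def write_newick(tree: dendropy.Tree, precision: int = 12) -> str:
    """Serialize a tree to Newick.  Labels with spaces are quoted so the
    output re-parses; round trip is stable to ``precision`` digits."""
    s = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        preserve_spaces=True,
        unquoted_underscores=True,
        real_value_format_specifier=f".{precision}f",
    )
    return s.strip() + "\n"


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in lexicographic order."""
    return sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())


def total_tree_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (the root's stub edge excluded)."""
    return float(
        sum(
            n.edge.length or 0.0
            for n in tree.preorder_node_iter()
            if n is not tree.seed_node
        )
    )


# ---------------------------------------------------------------------------
# Internal surgery helpers
# ---------------------------------------------------------------------------

def _has_unifurcation(tree: dendropy.Tree) -> bool:
    return any(len(n.child_nodes()) == 1 for n in tree.preorder_node_iter())


def _suppress_unifurcations(tree: dendropy.Tree, *, drop_root_stub: bool = True) -> None:
    """Remove every degree-2 node in place, summing branch lengths.

    A chain of single-child nodes at the root is collapsed onto the first
    multifurcating (or leaf) descendant, which becomes the new root; the
    lengths traversed are dropped with it when ``drop_root_stub`` (the
    root-side path does not separate any pair of tips).
    """
    for node in list(tree.preorder_node_iter()):
        if node is tree.seed_node:
            continue
        children = node.child_nodes()
        if len(children) == 1:
            child = children[0]
            child.edge.length = (child.edge.length or 0.0) + (node.edge.length or 0.0)
            parent = node.parent_node
            parent.remove_child(node)
            parent.add_child(child)
    root = tree.seed_node
    stub = 0.0
    collapsed_root = False
    while len(root.child_nodes()) == 1:
        collapsed_root = True
        child = root.child_nodes()[0]
        stub += child.edge.length or 0.0
        child.edge.length = None
        child.parent_node = None
        tree.seed_node = child
        root = child
    if collapsed_root and not drop_root_stub:
        # keep the root-side path as the new root's stub edge length
        tree.seed_node.edge.length = stub


def _clone(tree: dendropy.Tree) -> dendropy.Tree:
    # depth=1: new nodes/edges, shared taxon namespace (taxa are never mutated)
    return tree.clone(depth=1)


def _leaf_map(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def _require_tips(tree: dendropy.Tree, tipset: Iterable[str]) -> list[str]:
    present = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    tips = sorted(set(tipset))
    missing = [t for t in tips if t not in present]
    if missing:
        raise TreeError(f"tips not in tree: {missing}")
    return tips


# ---------------------------------------------------------------------------
# Patristic distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric patristic-distance matrix with an ordered label index."""

    labels: list[str]
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels), len(self.labels)):
            raise ValueError("labels/values shape mismatch")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def indices(self, labels: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._index[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise TreeError(f"unknown tip label: {exc.args[0]!r}") from None

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, labels: Sequence[str]) -> np.ndarray:
        idx = self.indices(labels)
        return self.values[np.ix_(idx, idx)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def patristic_distances(
    tree: dendropy.Tree, tips: Sequence[str] | None = None
) -> DistanceMatrix:
    """All pairwise path-length (patristic) distances between tips.

    Computed in one postorder pass: each node carries the tip indices below
    it and their distances to it; a pair's distance is filled in at its
    most recent common ancestor.  O(n^2) time, vectorized per node.
    """
    labels = tip_labels(tree)
    if tips is not None:
        requested = _require_tips(tree, tips)
    else:
        requested = labels
    n = len(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    D = np.zeros((n, n))

    carry: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            carry[id(node)] = (
                np.array([index[node.taxon.label]], dtype=int),
                np.zeros(1),
            )
            continue
        groups = []
        for child in node.child_nodes():
            t_idx, t_dist = carry.pop(id(child))
            groups.append((t_idx, t_dist + (child.edge.length or 0.0)))
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                ai, ad = groups[i]
                bi, bd = groups[j]
                block = ad[:, None] + bd[None, :]
                D[np.ix_(ai, bi)] = block
                D[np.ix_(bi, ai)] = block.T
        carry[id(node)] = (
            np.concatenate([g[0] for g in groups]),
            np.concatenate([g[1] for g in groups]),
        )

    if requested is labels:
        return DistanceMatrix(labels, D)
    idx = np.array([index[l] for l in requested], dtype=int)
    return DistanceMatrix(requested, D[np.ix_(idx, idx)])


def edge_incidence(
    tree: dendropy.Tree,
) -> tuple[list[str], sparse.csr_matrix, np.ndarray]:
    """Tip-by-edge incidence of the tree, for fast spanning-subtree sums.

    Returns ``(labels, M, lengths)`` where ``M[i, e] = 1`` iff edge ``e``
    lies on the path from tip ``i`` to the root, and ``lengths[e]`` is the
    branch length of edge ``e``.  The root's stub edge is excluded.
    """
    labels = tip_labels(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    edges = [n for n in tree.preorder_node_iter() if n is not tree.seed_node]
    edge_idx = {id(n): e for e, n in enumerate(edges)}
    lengths = np.array([n.edge.length or 0.0 for n in edges])

    rows: list[int] = []
    cols: list[int] = []
    for leaf in tree.leaf_node_iter():
        i = index[leaf.taxon.label]
        node = leaf
        while node is not tree.seed_node:
            rows.append(i)
            cols.append(edge_idx[id(node)])
            node = node.parent_node
    M = sparse.csr_matrix(
        (np.ones(len(rows), dtype=np.int32), (rows, cols)),
        shape=(len(labels), len(edges)),
    )
    return labels, M, lengths


# ---------------------------------------------------------------------------
# Pruning and polytomy surgery
# ---------------------------------------------------------------------------

def prune_to_tips(
    tree: dendropy.Tree, tipset: Iterable[str], *, keep_root_stub: bool = False
) -> dendropy.Tree:
    """Restrict a tree to a subset of its tips.

    The result contains exactly ``tipset`` as tips; degree-2 nodes created
    by leaf removal are suppressed with branch lengths summed, so patristic
    distances among retained tips are preserved exactly.  By default the
    tree is re-rooted at the most recent common ancestor of the retained
    set and the root-side stub path is discarded, making the pruned tree's
    total length equal the length of the spanning (Steiner) subtree of the
    retained tips.  ``keep_root_stub=True`` keeps the root-side path length
    as the new root's stub edge (``tree.seed_node.edge.length``) for
    root-inclusive diversity sums.
    """
    tips = _require_tips(tree, tipset)
    if len(tips) < 2:
        raise TreeError("prune_to_tips requires at least 2 tips")
    out = _clone(tree)
    keep = set(tips)
    for leaf in list(out.leaf_node_iter()):
        if leaf.taxon.label not in keep:
            _remove_leaf(out, leaf)
    _suppress_unifurcations(out, drop_root_stub=not keep_root_stub)
    return out


def _remove_leaf(tree: dendropy.Tree, leaf: dendropy.Node) -> None:
    parent = leaf.parent_node
    parent.remove_child(leaf)
    # cascade: an internal node left childless must go too
    while parent is not tree.seed_node and not parent.child_nodes():
        grand = parent.parent_node
        grand.remove_child(parent)
        parent = grand


def collapse_short_edges(tree: dendropy.Tree, tol: float = 0.0) -> dendropy.Tree:
    """Contract every internal edge with length <= ``tol`` into a polytomy.

    Tip edges are never contracted.  Realizes unresolved relationships
    (zero-length branches in an ML tree) as explicit polytomies.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    out = _clone(tree)
    # postorder so that chains of short edges collapse all the way up
    for node in list(out.postorder_node_iter()):
        if node is out.seed_node or node.is_leaf():
            continue
        if (node.edge.length or 0.0) <= tol:
            parent = node.parent_node
            for child in node.child_nodes():
                node.remove_child(child)
                parent.add_child(child)
            parent.remove_child(node)
    return out


def collapse_group_to_polytomy(
    tree: dendropy.Tree, tipset: Iterable[str]
) -> dendropy.Tree:
    """Flatten a monophyletic group to a polytomy at its common ancestor.

    All internal structure strictly below the group's MRCA is removed; the
    MRCA's children become exactly the group's tips, each attached with its
    original MRCA-to-tip path length so every root-to-tip distance is
    preserved exactly.  Non-monophyletic groups are rejected.
    """
    tips = _require_tips(tree, tipset)
    out = _clone(tree)
    leaves = _leaf_map(out)
    mrca = out.mrca(taxa=[leaves[t].taxon for t in tips])
    below = sorted(l.taxon.label for l in mrca.leaf_iter())
    if below != tips:
        extra = sorted(set(below) - set(tips))
        raise TreeError(f"group is not monophyletic; MRCA also spans: {extra}")
    if mrca.is_leaf():
        return out
    # record each tip's path length to the MRCA before detaching
    depths: dict[str, float] = {}
    for t in tips:
        node = leaves[t]
        d = 0.0
        while node is not mrca:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[t] = d
    for child in list(mrca.child_nodes()):
        mrca.remove_child(child)
    for t in tips:
        leaf = leaves[t]
        leaf.parent_node = None
        leaf.edge.length = depths[t]
        mrca.add_child(leaf)
    return out


# ---------------------------------------------------------------------------
# Resolution and monophyly metrics
# ---------------------------------------------------------------------------

def resolution_fraction(tree: dendropy.Tree, tol: float = 0.0) -> float:
    """Fraction of resolved internal branches.

    Counts internal edges with length > ``tol`` and divides by ``n - 2``,
    the internal-edge count of a fully resolved rooted binary tree on the
    same ``n`` tips, capping at 1.  A fully bifurcating tree with all
    positive internal branches scores 1.0; a star tree scores 0.0.  The
    default ``tol=0`` treats parsed branch lengths as literal.
    """
    n = sum(1 for _ in tree.leaf_node_iter())
    if n < 3:
        raise TreeError("resolution_fraction is undefined for trees with < 3 tips")
    resolved = 0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        if (node.edge.length or 0.0) > tol:
            resolved += 1
    return min(1.0, resolved / (n - 2))


RANKS = ("genus", "family", "order")


def monophyly_rate(
    tree: dendropy.Tree,
    taxonomy: Mapping[str, tuple[str, str, str]],
    rank: str,
    *,
    include_singletons: bool = False,
) -> float:
    """Fraction of taxonomic groups at ``rank`` that are monophyletic.

    A group is monophyletic when its MRCA's descendant tips are exactly the
    group's tips.  Groups of a single tip are trivially monophyletic and by
    default excluded from the denominator (``include_singletons`` counts
    them).  Invariant under any rescaling of branch lengths.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}, got {rank!r}")
    pos = RANKS.index(rank)
    tips = tip_labels(tree)
    missing = [t for t in tips if t not in taxonomy]
    if missing:
        raise TreeError(f"tips missing from taxonomy: {missing}")
    groups: dict[str, list[str]] = {}
    for t in tips:
        groups.setdefault(taxonomy[t][pos], []).append(t)

    leaves = _leaf_map(tree)
    n_eval = 0
    n_mono = 0
    for name in sorted(groups):
        members = groups[name]
        if len(members) < 2:
            if include_singletons:
                n_eval += 1
                n_mono += 1
            continue
        n_eval += 1
        mrca = tree.mrca(taxa=[leaves[t].taxon for t in members])
        if sorted(l.taxon.label for l in mrca.leaf_iter()) == sorted(members):
            n_mono += 1
    if n_eval == 0:
        raise TreeError("no groups to evaluate")
    return n_mono / n_eval


def read_taxonomy(source) -> dict[str, tuple[str, str, str]]:
    """Read a species -> (genus, family, order) table.

    Delimited text (comma or tab, sniffed) with a header naming at least
    ``species, genus, family, order``.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    needed = {"species", "genus", "family", "order"}
    if not needed.issubset(df.columns):
        raise ValueError(f"taxonomy table must have columns {sorted(needed)}")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species in taxonomy: {dups}")
    if (df["species"].astype(str).str.len() == 0).any():
        raise ValueError("empty species name in taxonomy")
    return {
        str(r.species): (str(r.genus), str(r.family), str(r.order))
        for r in df.itertuples()
    }
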