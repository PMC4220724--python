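"""Mean path length (MPL) calibration of phylograms into chronograms.

MPL dating assigns every internal node an age equal to the mean path length
from that node to its descendant tips, then rewrites each branch as the age
difference between its endpoints.  Rescaling by the root age yields an
ultrametric chronogram in relative time (root age 1 by default), which is
the minimal-alteration route from molecular branch lengths to a clock-like
tree — no rate model, no calibration points.

MPL can produce a *negative* branch when a node's mean tip depth exceeds
its parent's (typical around strongly rate-heterogeneous clades).  The
``negative_policy`` controls what happens then: ``warn`` keeps the negative
lengths and reports a count, ``clamp`` floors them at zero (the tree is
then no longer exactly ultrametric), ``error`` aborts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy

from .tree import TreeError, _clone

__all__ = ["Chronogram", "mpl_node_ages", "mpl_chronogram"]


@dataclass
class Chronogram:
    """An MPL-calibrated tree plus its node ages.

    Attributes
    ----------
    tree:
        The calibrated tree; branch lengths in relative time.
    ages:
        Mapping from nodes of ``tree`` to their age (tips age 0, root age
        ``root_age``).
    root_age:
        The age the root was scaled to (1 by default).
    negative_edge_count:
        Number of branches whose MPL length came out negative.
    is_ultrametric:
        True when no negative branch was produced (or clamped away); then
        every tip-to-root path length equals ``root_age`` to within 1e-9
        relative.
    """

    tree: dendropy.Tree
    ages: dict[dendropy.Node, float]
    root_age: float
    negative_edge_count: int
    is_ultrametric: bool

    def mrca_age(self, labels) -> float:
        """Age of the most recent common ancestor of a set of tip labels."""
        leaves = {l.taxon.label: l for l in self.tree.leaf_node_iter()}
        node = self.tree.mrca(taxa=[leaves[l].taxon for l in labels])
        return self.ages[node]


def mpl_node_ages(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Raw (unscaled) MPL age of every node of ``tree``.

    The age of an internal node is the mean, over all tips descending from
    it, of the path length from the node to the tip; tips have age 0.
    One postorder pass carrying (tip count, summed path length) per
    subtree; polytomies need no special casing.
    """
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 2:
        raise TreeError("MPL calibration needs at least 2 tips")
    ages: dict[dendropy.Node, float] = {}
    agg: dict[int, tuple[int, float]] = {}  # node id -> (tips below, summed path)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            agg[id(node)] = (1, 0.0)
            ages[node] = 0.0
            continue
        count = 0
        total = 0.0
        for child in node.child_nodes():
            c, s = agg.pop(id(child))
            count += c
            total += s + c * (child.edge.length or 0.0)
        agg[id(node)] = (count, total)
        ages[node] = total / count
    return ages


def mpl_chronogram(
    tree: dendropy.Tree,
    root_age: float = 1.0,
    negative_policy: str = "warn",
) -> Chronogram:
    """Calibrate a phylogram to an ultrametric chronogram by MPL.

    Branch lengths become age differences ``age(parent) - age(child)`` and
    all ages are rescaled so the root sits at ``root_age`` (default 1,
    i.e. relative time).  See the module docstring for ``negative_policy``.

    Raises
    ------
    TreeError
        If the tree has total length 0 (root age 0 cannot be scaled), or a
        negative branch arises under ``negative_policy='error'``.
    """
    if negative_policy not in ("warn", "clamp", "error"):
        raise ValueError(f"unknown negative_policy {negative_policy!r}")
    out = _clone(tree)
    raw = mpl_node_ages(out)
    raw_root = raw[out.seed_node]
    if raw_root <= 0:
        raise TreeError("root MPL age is 0 (all branch lengths zero?); cannot calibrate")
    scale = root_age / raw_root

    negatives: list[str] = []
    for node in out.preorder_node_iter():
        if node is out.seed_node:
            node.edge.length = None
            continue
        length = (raw[node.parent_node] - raw[node]) * scale
        if length < 0:
            negatives.append(
                f"edge to {'tip ' + node.taxon.label if node.is_leaf() else 'internal node'}"
                f" (length {length:.6g})"
            )
            if negative_policy == "clamp":
                length = 0.0
        node.edge.length = length

    n_neg = len(negatives)
    if n_neg:
        if negative_policy == "error":
            raise TreeError(
                f"MPL produced {n_neg} negative branch length(s): {negatives}"
            )
        warnings.warn(f"MPL produced {n_neg} negative branch length(s)")
    ages = {node: raw[node] * scale for node in out.preorder_node_iter()}
    return Chronogram(
        tree=out,
        ages=ages,
        root_age=root_age,
        negative_edge_count=n_neg,
        is_ultrametric=(n_neg == 0),
    )
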