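"""Within-community phylogenetic diversity: Faith's PD, MPD, MNTD.

All three metrics use presence/absence only.  PD is the total branch
length of the minimal subtree spanning a community's species (the Steiner
subtree); by default the path from that subtree up to the tree root is
*not* included, so a plot's PD on the shared mega-phylogeny equals the
total tree length of the plot's pruned tree.  MPD averages patristic
distance over all unordered species pairs and is dominated by deep
divergences; MNTD averages each species' distance to its nearest co-occurring
relative and tracks shallow structure, so MNTD <= MPD always.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .tree import DistanceMatrix, TreeError, edge_incidence, patristic_distances

__all__ = ["faith_pd", "mpd", "mntd", "diversity_table"]


def faith_pd(
    tree: dendropy.Tree, tipset: Iterable[str], *, include_root: bool = False
) -> float:
    """Faith's phylogenetic diversity of a set of tips.

    Sum of branch lengths of the minimal connected subtree spanning
    ``tipset``; with ``include_root`` the path from that subtree to the
    tree root is added as well.
    """
    tips = sorted(set(tipset))
    if len(tips) < 2:
        raise TreeError("faith_pd requires at least 2 tips")
    labels, M, lengths = edge_incidence(tree)
    index = {lab: i for i, lab in enumerate(labels)}
    missing = [t for t in tips if t not in index]
    if missing:
        raise TreeError(f"species absent from the tree: {missing}")
    idx = np.array([index[t] for t in tips])
    counts = np.asarray(M[idx].sum(axis=0)).ravel()
    k = len(tips)
    inside = (counts >= 1) & (counts < k)
    pd_value = float(lengths[inside].sum())
    if include_root:
        pd_value += float(lengths[counts == k].sum())
    return pd_value


def _distances(tree_or_dm, tipset: Sequence[str]) -> np.ndarray:
    if isinstance(tree_or_dm, DistanceMatrix):
        return tree_or_dm.submatrix(tipset)
    return patristic_distances(tree_or_dm, tips=tipset).values


def mpd(tree_or_dm, tipset: Iterable[str]) -> float:
    """Mean patristic distance over all unordered pairs in the community.

    Accepts either a tree or a precomputed :class:`DistanceMatrix`.
    """
    tips = sorted(set(tipset))
    if len(tips) < 2:
        raise TreeError("mpd requires at least 2 tips")
    d = _distances(tree_or_dm, tips)
    k = len(tips)
    return float(d.sum() / (k * (k - 1)))  # off-diagonal mean; matrix symmetric


def mntd(tree_or_dm, tipset: Iterable[str]) -> float:
    """Mean distance from each community member to its nearest neighbor in
    the same community."""
    tips = sorted(set(tipset))
    if len(tips) < 2:
        raise TreeError("mntd requires at least 2 tips")
    d = _distances(tree_or_dm, tips).copy()
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def diversity_table(
    tree: dendropy.Tree,
    communities: CommunityMatrix,
    *,
    include_root: bool = False,
) -> pd.DataFrame:
    """Per-plot SR, PD, MPD and MNTD on a shared tree.

    Returns one row per plot; plots must have at least 2 species.  All
    community species must be tips of ``tree``.
    """
    communities.check_against_tree(tree)
    dm = patristic_distances(tree, tips=communities.species)
    rows = []
    for plot in communities.plots:
        tips = communities.tips_of(plot)
        if len(tips) < 2:
            raise TreeError(f"plot {plot!r} has fewer than 2 species")
        rows.append(
            {
                "plot": plot,
                "SR": len(tips),
                "PD": faith_pd(tree, tips, include_root=include_root),
                "MPD": mpd(dm, tips),
                "MNTD": mntd(dm, tips),
            }
        )
    return pd.DataFrame(rows).set_index("plot")
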