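"""Independent brute-force reference implementations used to check the
package's metrics.  These deliberately take a different computational route
(ancestor-path sets and explicit double loops) from the library code."""

from __future__ import annotations

import itertools


def ancestor_path(tree, leaf):
    """List of nodes from a leaf up to (and excluding) the root."""
    path = []
    node = leaf
    while node is not tree.seed_node:
        path.append(node)
        node = node.parent_node
    return path


def leaf_by_label(tree):
    return {l.taxon.label: l for l in tree.leaf_node_iter()}


def brute_distance(tree, a: str, b: str) -> float:
    """Patristic distance as the symmetric difference of root paths."""
    leaves = leaf_by_label(tree)
    pa = ancestor_path(tree, leaves[a])
    pb = ancestor_path(tree, leaves[b])
    sa, sb = set(map(id, pa)), set(map(id, pb))
    d = sum(n.edge.length or 0.0 for n in pa if id(n) not in sb)
    d += sum(n.edge.length or 0.0 for n in pb if id(n) not in sa)
    return d


def brute_pd(tree, tipset, include_root=False) -> float:
    """Faith's PD by edge marking: walk each tip up to the set's MRCA
    (or the root), marking edges; sum marked lengths once each."""
    leaves = leaf_by_label(tree)
    paths = {t: ancestor_path(tree, leaves[t]) for t in tipset}
    common = set.intersection(*(set(map(id, p)) for p in paths.values()))
    marked = {}
    for p in paths.values():
        for node in p:
            if id(node) not in common:
                marked[id(node)] = node.edge.length or 0.0
    total = sum(marked.values())
    if include_root:
        # the shared ancestral path from the MRCA up to the root
        any_path = next(iter(paths.values()))
        total += sum(n.edge.length or 0.0 for n in any_path if id(n) in common)
    return total


def brute_mpd(tree, tipset) -> float:
    tips = sorted(tipset)
    dists = [
        brute_distance(tree, a, b) for a, b in itertools.combinations(tips, 2)
    ]
    return sum(dists) / len(dists)


def brute_mntd(tree, tipset) -> float:
    tips = sorted(tipset)
    total = 0.0
    for a in tips:
        total += min(brute_distance(tree, a, b) for b in tips if b != a)
    return total / len(tips)


def brute_comdist(tree, comm_a, comm_b) -> float:
    a, b = sorted(comm_a), sorted(comm_b)
    total = sum(brute_distance(tree, i, j) for i in a for j in b)
    return total / (len(a) * len(b))


def brute_comdistnt(tree, comm_a, comm_b) -> float:
    a, b = sorted(comm_a), sorted(comm_b)
    terms = [min(brute_distance(tree, i, j) for j in b) for i in a]
    terms += [min(brute_distance(tree, j, i) for i in a) for j in b]
    return sum(terms) / len(terms)
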