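"""Tip-label randomization null model, standardized effect sizes and
clustering/overdispersion classification.

The null ("taxa.labels") shuffles species names across the tips of the
phylogeny while leaving the tree and every plot's species list untouched,
so each replicate preserves the species richness of every plot and the
number of plots each species occupies; only the evolutionary relationships
among co-occurring species are randomized.  Only species that actually
appear in the community data take part in the shuffle — tips absent from
every plot keep their labels.

For each plot and metric the observed value is ranked within its null
distribution: ``obs_rank = 1 + #(null < obs) + 0.5 * #(null == obs)`` and
``p_low = obs_rank / (nreps + 1)``.  ``SES = (obs - mean(null)) / sd(null)``.
A plot is *clustered* when ``p_low < alpha`` (observed diversity smaller
than expected), *overdispersed* when ``p_low > 1 - alpha``, otherwise
*random*; a null distribution with zero spread (e.g. a plot holding every
tip) is flagged *degenerate*.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .community import CommunityMatrix
from .tree import TreeError, edge_incidence, patristic_distances

__all__ = ["NullResult", "shuffle_tip_labels", "ses_metric", "classify"]

METRICS = ("PD", "MPD", "MNTD")


@dataclass
class NullResult:
    """Observed metric, null summary and classification for one plot."""

    plot: str
    metric: str
    obs: float
    null_mean: float
    null_sd: float
    ses: float
    obs_rank: float
    p_low: float
    nreps: int
    seed: int | None
    classification: str


def shuffle_tip_labels(labels: Sequence[str], rng: np.random.Generator) -> list[str]:
    """Uniform random permutation of a label set.

    The caller interprets the result positionally: ``labels[i]`` is
    re-bound to the tip that carried ``shuffled[i]``.  Equivalent to
    permuting the rows/columns of the patristic distance matrix.
    """
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise ValueError("labels must be unique")
    perm = rng.permutation(len(labels))
    return [labels[i] for i in perm]


def _classify_p(p_low: float, alpha: float) -> str:
    if p_low < alpha:
        return "clustered"
    if p_low > 1 - alpha:
        return "overdispersed"
    return "random"


def classify(result: NullResult, alpha: float = 0.05) -> str:
    """Clustered / overdispersed / random label for a null-model result.

    Observed diversity below the null mean with ``p_low < alpha`` reads as
    phylogenetic clustering; above the null with ``1 - p_low < alpha`` as
    overdispersion.  Degenerate results pass through unchanged.
    """
    if result.classification == "degenerate":
        return "degenerate"
    return _classify_p(result.p_low, alpha)


def ses_metric(
    tree: dendropy.Tree,
    communities: CommunityMatrix,
    metric: str,
    *,
    nreps: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
    include_root: bool = False,
) -> pd.DataFrame:
    """Standardized effect size of PD, MPD or MNTD under the tip-shuffle null.

    One label permutation is drawn per replicate and serves every plot, so
    cross-plot structure is preserved within a replicate and results are
    comparable across metrics run with the same seed.  Returns a DataFrame
    (one row per plot) with the :class:`NullResult` fields.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if nreps < 1:
        raise ValueError("nreps must be >= 1")
    communities.check_against_tree(tree)
    pool = communities.species  # only species present in the data shuffle
    npool = len(pool)
    rng = np.random.default_rng(seed)
    # draw all permutations up front: the stream depends only on the seed
    # and pool size, never on the metric evaluated
    perms = rng.permuted(
        np.tile(np.arange(npool), (nreps, 1)), axis=1
    )

    plot_idx = {
        p: np.array([pool.index(s) for s in communities.tips_of(p)], dtype=int)
        for p in communities.plots
    }

    evaluate = _make_evaluator(tree, pool, metric, include_root)

    results: list[NullResult] = []
    null_values = {p: np.empty(nreps) for p in communities.plots}
    obs = {p: evaluate(idx) for p, idx in plot_idx.items()}
    for r in range(nreps):
        perm = perms[r]
        for p, idx in plot_idx.items():
            null_values[p][r] = evaluate(perm[idx])

    for p in communities.plots:
        nulls = null_values[p]
        null_mean = float(nulls.mean())
        null_sd = float(nulls.std(ddof=1)) if nreps > 1 else 0.0
        o = obs[p]
        rank = 1.0 + float((nulls < o).sum()) + 0.5 * float((nulls == o).sum())
        p_low = rank / (nreps + 1)
        degenerate = null_sd <= 1e-12 * max(1.0, abs(null_mean))
        if degenerate:
            ses = 0.0
            label = "degenerate"
        else:
            ses = (o - null_mean) / null_sd
            label = _classify_p(p_low, alpha)
        results.append(
            NullResult(
                plot=p,
                metric=metric,
                obs=o,
                null_mean=null_mean,
                null_sd=null_sd,
                ses=ses,
                obs_rank=rank,
                p_low=p_low,
                nreps=nreps,
                seed=seed,
                classification=label,
            )
        )
    return pd.DataFrame([asdict(r) for r in results]).set_index("plot")


def _make_evaluator(tree, pool: Sequence[str], metric: str, include_root: bool):
    """Return f(pool-index array) -> metric value, with tree structure
    precomputed once."""
    if metric == "PD":
        labels, M, lengths = edge_incidence(tree)
        tip_index = {lab: i for i, lab in enumerate(labels)}
        pool_tip = np.array([tip_index[s] for s in pool], dtype=int)

        def evaluate(idx: np.ndarray) -> float:
            rows = pool_tip[idx]
            counts = np.asarray(M[rows].sum(axis=0)).ravel()
            k = len(rows)
            if k < 2:
                raise TreeError("PD requires at least 2 species per plot")
            inside = (counts >= 1) & (counts < k)
            value = float(lengths[inside].sum())
            if include_root:
                value += float(lengths[counts == k].sum())
            return value

        return evaluate

    dm = patristic_distances(tree, tips=pool).values
    if metric == "MPD":

        def evaluate(idx: np.ndarray) -> float:
            k = len(idx)
            if k < 2:
                raise TreeError("MPD requires at least 2 species per plot")
            sub = dm[np.ix_(idx, idx)]
            return float(sub.sum() / (k * (k - 1)))

        return evaluate

    def evaluate(idx: np.ndarray) -> float:
        if len(idx) < 2:
            raise TreeError("MNTD requires at least 2 species per plot")
        sub = dm[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        return float(sub.min(axis=1).mean())

    return evaluate
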