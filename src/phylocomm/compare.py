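"""Plot-level vs. mega-phylogeny comparison pipeline.

The headline analysis: for every plot, diversity metrics estimated from an
individually built plot phylogeny are compared with the same metrics
estimated by pruning the plot out of a shared mega-phylogeny.  The
comparison statistic is the percent difference
``100 * (M_i - M_j) / M_j`` (i = individual-tree estimate, j = mega-tree
estimate; zero means perfect agreement, negative means the individual tree
underestimates).  Phylogenetic resolution is measured on the raw
(pre-calibration) trees, since MPL averaging would destroy the zero-length
branches that mark unresolved nodes; the diversity metrics are computed on
MPL chronograms with root age 1 each, so differences are proportional, not
absolute.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .alpha import faith_pd, mntd, mpd
from .community import CommunityMatrix
from .mpl import mpl_chronogram
from .tree import TreeError, prune_to_tips, resolution_fraction, tip_labels

__all__ = [
    "percent_difference",
    "CorrelationResult",
    "spearman",
    "ComparisonReport",
    "run_comparison",
]

_METRICS = ("PD", "MPD", "MNTD")


def percent_difference(m_i: float, m_j: float) -> float:
    """Signed percent difference ``100 * (m_i - m_j) / m_j``.

    ``m_i`` is the individual-tree estimate, ``m_j`` the mega-tree
    estimate; negative values mean the individual tree gives the smaller
    value.
    """
    if m_j == 0:
        raise ValueError("reference value m_j is 0; percent difference undefined")
    return 100.0 * (m_i - m_j) / m_j


@dataclass
class CorrelationResult:
    """Spearman rank correlation between two named variables."""

    x_name: str
    y_name: str
    rho: float
    n: int
    p: float
    method: str  # "exact-permutation" | "asymptotic-t" | "undefined"


_EXACT_N_MAX = 10


def spearman(x, y, names=("x", "y")) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    rho is the Pearson correlation of mid-ranks.  The two-sided p-value is
    an exact permutation enumeration for n <= 10 and the asymptotic
    t-approximation otherwise.  A constant input vector leaves rho
    undefined (NaN, method ``"undefined"``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("spearman requires n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(names[0], names[1], math.nan, n, math.nan, "undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rho = float((rx_c * ry_c).sum() / denom)

    if n <= _EXACT_N_MAX:
        p = _exact_perm_p(rx_c, ry_c, denom, rho)
        method = "exact-permutation"
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
        method = "asymptotic-t"
    return CorrelationResult(names[0], names[1], rho, n, min(1.0, p), method)


def _exact_perm_p(rx_c, ry_c, denom, rho_obs, chunk=200_000):
    """Two-sided p by full enumeration of permutations of one rank vector."""
    n = len(rx_c)
    total = math.factorial(n)
    hits = 0
    it = itertools.permutations(range(n))
    thresh = abs(rho_obs) - 1e-12
    while True:
        block = list(itertools.islice(it, chunk))
        if not block:
            break
        P = np.array(block, dtype=np.intp)
        rhos = (ry_c[P] @ rx_c) / denom
        hits += int((np.abs(rhos) >= thresh).sum())
    return hits / total


@dataclass
class ComparisonReport:
    """Tables produced by :func:`run_comparison`.

    ``resolution``: per-plot resolution of the individually built tree, of
    the pruned mega-tree, and their difference.  ``diversity_individual`` /
    ``diversity_mega``: per-plot SR/PD/MPD/MNTD estimated each way.
    ``pct_diff``: per-plot percent differences per metric;
    ``mean_pct_diff``: their across-plot averages.  ``correlations``:
    Spearman tests among resolution, richness, diversity and latitude.
    """

    resolution: pd.DataFrame
    diversity_individual: pd.DataFrame
    diversity_mega: pd.DataFrame
    pct_diff: pd.DataFrame
    mean_pct_diff: pd.Series
    correlations: pd.DataFrame
    skipped_plots: list[str] = field(default_factory=list)

    def write(self, outdir) -> None:
        """Emit table2.csv (resolution), table3.csv (diversity),
        pctdiff.csv and correlations.csv into ``outdir``."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.resolution.to_csv(out / "table2.csv")
        both = self.diversity_individual.join(
            self.diversity_mega, lsuffix="_individual", rsuffix="_mega"
        )
        both.to_csv(out / "table3.csv")
        self.pct_diff.to_csv(out / "pctdiff.csv")
        self.correlations.to_csv(out / "correlations.csv", index=False)


def run_comparison(
    mega: dendropy.Tree,
    plot_trees: Mapping[str, dendropy.Tree],
    communities: CommunityMatrix,
    *,
    include_root: bool = False,
    negative_policy: str = "warn",
    tol: float = 0.0,
    root_age: float = 1.0,
    absolute_latitude: bool = True,
) -> ComparisonReport:
    """Compare plot-level phylogenies against the mega-phylogeny.

    Stages: (1) resolution of each individually built tree vs. the plot
    pruned from the mega-tree, on the raw branch lengths; (2) MPL
    calibration of every tree to root age ``root_age``; (3) per-plot
    SR/PD/MPD/MNTD both ways on the chronograms; (4) percent difference
    per plot and metric, and their across-plot means; (5) Spearman
    correlations of resolution with richness, MPD, MNTD and latitude, of
    each diversity metric with latitude, and of each metric's percent
    difference with richness.  Plots without an individual tree are
    skipped with a warning.
    """
    communities.check_against_tree(mega)
    plots = [p for p in communities.plots]
    skipped = [p for p in plots if p not in plot_trees]
    for p in skipped:
        warnings.warn(f"no individual tree for plot {p!r}; skipping")
    plots = [p for p in plots if p in plot_trees]
    if not plots:
        raise TreeError("no plots with individual trees")

    for p in plots:
        have = set(tip_labels(plot_trees[p]))
        need = set(communities.tips_of(p))
        if not need.issubset(have):
            raise TreeError(
                f"plot {p!r}: species missing from its tree: {sorted(need - have)}"
            )

    # --- resolution on raw (uncalibrated) branch lengths
    res_rows = []
    pruned: dict[str, dendropy.Tree] = {}
    for p in plots:
        tips = communities.tips_of(p)
        pruned[p] = prune_to_tips(mega, tips)
        indiv = (
            prune_to_tips(plot_trees[p], tips)
            if set(tip_labels(plot_trees[p])) != set(tips)
            else plot_trees[p]
        )
        r_i = resolution_fraction(indiv, tol) if len(tips) >= 3 else np.nan
        r_m = resolution_fraction(pruned[p], tol) if len(tips) >= 3 else np.nan
        res_rows.append(
            {
                "plot": p,
                "SR": len(tips),
                "resolution_individual": r_i,
                "resolution_mega": r_m,
                "resolution_difference": r_m - r_i,
            }
        )
    resolution = pd.DataFrame(res_rows).set_index("plot")

    # --- MPL calibration, then diversity both ways.  Both estimates are
    # calibrated per plot to the same root age so they live on the same
    # relative-time scale: the mega-side estimate for a plot is computed on
    # the plot's subtree pruned from the mega-phylogeny (its topology and
    # branch lengths inherited from the mega-tree), MPL-calibrated exactly
    # like the individually built tree it is compared against.
    def _row(plot: str, tree: dendropy.Tree) -> dict:
        chrono = mpl_chronogram(tree, root_age=root_age, negative_policy=negative_policy)
        tips = communities.tips_of(plot)
        return {
            "plot": plot,
            "SR": len(tips),
            "PD": faith_pd(chrono.tree, tips, include_root=include_root),
            "MPD": mpd(chrono.tree, tips),
            "MNTD": mntd(chrono.tree, tips),
        }

    div_mega = pd.DataFrame([_row(p, pruned[p]) for p in plots]).set_index("plot")
    div_indiv = pd.DataFrame([_row(p, plot_trees[p]) for p in plots]).set_index("plot")

    # --- percent differences
    pct = pd.DataFrame(
        {
            m: [
                percent_difference(div_indiv.loc[p, m], div_mega.loc[p, m])
                for p in plots
            ]
            for m in _METRICS
        },
        index=pd.Index(plots, name="plot"),
    )
    mean_pct = pct.mean()

    # --- correlations
    corr_rows = []

    def _corr(xname, x, yname, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3:
            return
        r = spearman(x[ok], y[ok], names=(xname, yname))
        corr_rows.append(
            {
                "x": r.x_name,
                "y": r.y_name,
                "rho": r.rho,
                "n": r.n,
                "p": r.p,
                "method": r.method,
            }
        )

    res_i = resolution["resolution_individual"]
    _corr("resolution_individual", res_i, "SR", resolution["SR"])
    _corr("resolution_individual", res_i, "MPD", div_mega["MPD"])
    _corr("resolution_individual", res_i, "MNTD", div_mega["MNTD"])
    for m in _METRICS:
        _corr(f"pct_diff_{m}", pct[m], "SR", resolution["SR"])
    if communities.metadata is not None and "latitude" in communities.metadata.columns:
        lat = communities.metadata.loc[plots, "latitude"].astype(float)
        if absolute_latitude:
            lat = lat.abs()
        _corr("resolution_individual", res_i, "latitude", lat)
        for m in _METRICS:
            _corr(m, div_mega[m], "latitude", lat)
    correlations = pd.DataFrame(
        corr_rows, columns=["x", "y", "rho", "n", "p", "method"]
    )

    return ComparisonReport(
        resolution=resolution,
        diversity_individual=div_indiv,
        diversity_mega=div_mega,
        pct_diff=pct,
        mean_pct_diff=mean_pct,
        correlations=correlations,
        skipped_plots=skipped,
    )
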