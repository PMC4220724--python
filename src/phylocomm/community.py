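"""Plot-by-species incidence matrix binding communities to tree tips."""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .tree import TreeError

__all__ = ["CommunityMatrix", "read_communities", "read_communities_long"]


@dataclass
class CommunityMatrix:
    """Presence/absence of species (columns) across plots (rows).

    ``incidence`` is a 0/1 integer DataFrame indexed by plot name;
    ``metadata`` optionally carries one row per plot (``latitude`` and
    ``longitude`` in decimal degrees, plus any extra columns).  Species are
    bound to tree tips at analysis time via :meth:`check_against_tree`, not
    at construction.
    """

    incidence: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        inc = self.incidence
        if inc.index.has_duplicates:
            raise ValueError("duplicate plot names")
        if inc.columns.has_duplicates:
            raise ValueError("duplicate species names")
        values = inc.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        empty = inc.columns[values.sum(axis=0) == 0].tolist()
        if empty:
            raise ValueError(f"species with no presence in any plot: {empty}")
        self.incidence = inc.astype(int)
        if self.metadata is not None:
            missing = [p for p in inc.index if p not in self.metadata.index]
            if missing:
                raise ValueError(f"plots missing from metadata: {missing}")

    @property
    def plots(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def species(self) -> list[str]:
        return list(self.incidence.columns)

    def richness(self) -> pd.Series:
        return self.incidence.sum(axis=1)

    def tips_of(self, plot: str) -> list[str]:
        row = self.incidence.loc[plot]
        return sorted(row.index[row == 1])

    def check_against_tree(self, tree: dendropy.Tree) -> None:
        """Raise listing every species that is not a tip of ``tree``."""
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        absent = sorted(s for s in self.species if s not in tips)
        if absent:
            raise TreeError(f"species absent from the tree: {absent}")

    def latitudes(self, *, absolute: bool = True) -> pd.Series:
        if self.metadata is None or "latitude" not in self.metadata.columns:
            raise ValueError("no latitude metadata")
        lat = self.metadata.loc[self.plots, "latitude"].astype(float)
        return lat.abs() if absolute else lat

    def write_csv(self, path) -> None:
        self.incidence.to_csv(path, index_label="plot")


def read_communities(source, metadata=None) -> CommunityMatrix:
    """Read a wide-format incidence table (first column plot name, one
    column per species, 0/1 entries); delimiter sniffed."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    inc = pd.read_csv(source, sep=None, engine="python", index_col=0)
    meta = _read_metadata(metadata) if metadata is not None else None
    return CommunityMatrix(incidence=inc, metadata=meta)


def read_communities_long(source, metadata=None) -> CommunityMatrix:
    """Read long-format (plot, species) presence pairs."""
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns[:2]] + list(df.columns[2:])
    inc = pd.crosstab(df.iloc[:, 0], df.iloc[:, 1]).clip(upper=1)
    inc.index.name = "plot"
    meta = _read_metadata(metadata) if metadata is not None else None
    return CommunityMatrix(incidence=inc, metadata=meta)


def _read_metadata(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    meta = pd.read_csv(source, sep=None, engine="python", index_col=0)
    meta.columns = [c.strip().lower() for c in meta.columns]
    return meta
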