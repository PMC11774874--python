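"""Species-by-trait tables and the variable transforms used before analysis.

Morphological and chemical root traits (diameter, tissue density,
specific root length/area, dry-matter, N and C content) are strictly
positive and right-skewed, so they are natural-log transformed.
Mycorrhizal colonization (colM) is a percentage; it is rescaled to a
proportion and arcsine-square-root transformed instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import PhyloTree

__all__ = [
    "TraitTable",
    "TRANSFORMS",
    "transform_traits",
    "align_tree_and_traits",
]

#: recognised per-trait transforms
TRANSFORMS = ("log", "asin_sqrt_prop", "none")

#: trait names in the order used throughout (colonization first)
DEFAULT_TRAITS = ("colM", "RD", "RTD", "SRA", "SRL", "RDMC", "RNC", "RC:N", "RCC")

#: default transform map: log everything except colM
DEFAULT_TRANSFORMS = {t: ("asin_sqrt_prop" if t == "colM" else "log")
                      for t in DEFAULT_TRAITS}


@dataclass
class TraitTable:
    """Complete-case species x trait matrix with transform metadata.

    ``data`` is a DataFrame indexed by species label.  ``transforms``
    maps trait name -> one of :data:`TRANSFORMS` and records what has
    been *requested*; ``applied`` flips to True once
    :func:`transform_traits` has run.
    """

    data: pd.DataFrame
    transforms: dict = field(default_factory=dict)
    applied: bool = False

    def __post_init__(self):
        if self.data.isna().any().any():
            bad = self.data.index[self.data.isna().any(axis=1)].tolist()
            raise ValueError(f"missing trait values for species {bad}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate species labels in trait table")
        unknown = set(self.transforms) - set(self.data.columns)
        if unknown:
            raise KeyError(f"transforms for unknown traits: {sorted(unknown)}")
        for k, v in self.transforms.items():
            if v not in TRANSFORMS:
                raise ValueError(f"unknown transform {v!r} for trait {k!r}")

    @property
    def species(self) -> tuple:
        return tuple(self.data.index)

    @property
    def trait_names(self) -> tuple:
        return tuple(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path, transforms=None, sep=None) -> "TraitTable":
        """Read a CSV/TSV whose first column is the species label."""
        df = pd.read_csv(path, sep=sep, index_col=0, engine="python")
        df = df.dropna(how="all")
        return cls(df.astype(float), transforms=dict(transforms or {}))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="species")

    def reorder(self, species) -> "TraitTable":
        return TraitTable(self.data.loc[list(species)], dict(self.transforms),
                          self.applied)

    def drop_trait(self, name: str) -> "TraitTable":
        tr = {k: v for k, v in self.transforms.items() if k != name}
        return TraitTable(self.data.drop(columns=[name]), tr, self.applied)


def transform_traits(table: TraitTable, transforms: dict | None = None) -> TraitTable:
    """Apply per-trait transforms; returns a new table.

    * ``log``: natural log; requires strictly positive values.
    * ``asin_sqrt_prop``: for percentages in [0, 100] — rescale to [0, 1]
      then arcsin(sqrt(p)); 0 -> 0, 50 -> pi/4, 100 -> pi/2.
    * ``none``: passthrough.
    """
    tmap = dict(table.transforms if transforms is None else transforms)
    df = table.data.copy()
    for trait in df.columns:
        how = tmap.get(trait, "none")
        col = df[trait].astype(float)
        if how == "log":
            bad = col.index[col <= 0].tolist()
            if bad:
                raise ValueError(
                    f"log transform of trait {trait!r}: non-positive values "
                    f"for species {bad}")
            df[trait] = np.log(col)
        elif how == "asin_sqrt_prop":
            bad = col.index[(col < 0) | (col > 100)].tolist()
            if bad:
                raise ValueError(
                    f"arcsine-sqrt transform of trait {trait!r}: values outside "
                    f"[0, 100] for species {bad}")
            df[trait] = np.arcsin(np.sqrt(col / 100.0))
        elif how != "none":
            raise ValueError(f"unknown transform {how!r}")
    return TraitTable(df, tmap, applied=True)


def align_tree_and_traits(tree: PhyloTree, table: TraitTable,
                          normalize_labels: bool = False):
    """Match tree tips to trait rows; return (pruned tree, reordered table).

    The tree is pruned to the shared species and the table reordered to
    the pruned tree's tip order.  Dropped names on either side are
    reported via warnings.  Label matching is exact and case-sensitive
    unless ``normalize_labels`` maps underscores to spaces first.
    """
    if normalize_labels:
        tree = tree.normalize_labels()
        table = TraitTable(
            table.data.rename(index=lambda s: s.replace("_", " ")),
            dict(table.transforms), table.applied)
    tips = set(tree.tip_labels)
    rows = set(table.species)
    shared = tips & rows
    if not shared:
        raise ValueError("no species shared between tree and trait table")
    drop_tips = sorted(tips - shared)
    drop_rows = sorted(rows - shared)
    if drop_tips:
        warnings.warn(f"dropping {len(drop_tips)} tree tips without trait data: "
                      f"{drop_tips}", UserWarning, stacklevel=2)
        tree = tree.prune_to(shared)
    if drop_rows:
        warnings.warn(f"dropping {len(drop_rows)} trait rows not in tree: "
                      f"{drop_rows}", UserWarning, stacklevel=2)
    table = table.reorder(tree.tip_labels)
    return tree, table
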