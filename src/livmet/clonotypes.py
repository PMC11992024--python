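"""TCR clonotype expansion classes and tissue sharing.

A clonotype is the set of T cells sharing an identical CDR3β amino-acid
sequence. Expansion classes follow the standard repertoire binning: unique
(1 cell), small (2–5), large (6–30), hyperexpanded (>30). Sharing between two
tissues (healthy liver parenchyma vs liver metastasis) is keyed on the
clonotype sequence; every shared clonotype is reported with its size and
class in each tissue.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

REQUIRED_COLUMNS = ("cell_id", "clonotype", "tissue")


class CloneClass(enum.IntEnum):
    """Expansion class of a clonotype; ordering follows clone size."""

    UNIQUE = 1
    SMALL = 2
    LARGE = 3
    HYPEREXPANDED = 4

    @property
    def label(self) -> str:
        return self.name.lower()


def classify(size) -> CloneClass:
    """Map a clone size (cells per clonotype) to its expansion class.

    Boundaries are inclusive as conventionally printed: 1 → unique,
    2–5 → small, 6–30 → large, ≥31 → hyperexpanded.
    """
    size = int(size)
    if size < 1:
        raise ValueError(f"clone size must be >= 1, got {size}")
    if size == 1:
        return CloneClass.UNIQUE
    if size <= 5:
        return CloneClass.SMALL
    if size <= 30:
        return CloneClass.LARGE
    return CloneClass.HYPEREXPANDED


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"clonotype table missing columns: {missing}")
    if len(table) and table["clonotype"].astype(str).str.len().eq(0).any():
        raise ValueError("empty clonotype keys in table")


def clone_sizes(
    table: pd.DataFrame,
    tissue: Optional[str] = None,
    group: Optional[str] = None,
) -> pd.Series:
    """Cells per clonotype within a stratum (tissue and/or group selection).

    The counts sum to the number of cells in the stratum; an empty stratum
    yields an empty series.
    """
    _check_table(table)
    sel = table
    if tissue is not None:
        sel = sel[sel["tissue"] == tissue]
    if group is not None:
        if "group" not in table.columns:
            raise ValueError("table has no 'group' column")
        sel = sel[sel["group"] == group]
    return sel.groupby("clonotype", sort=True).size().rename("n_cells")


def class_counts(table: pd.DataFrame, by=("tissue",)) -> pd.DataFrame:
    """Per-stratum tallies of expansion classes.

    Emits both tallies — cells per class and clonotypes per class — since
    repertoire figures use either. Strata are the distinct combinations of
    the ``by`` columns.
    """
    _check_table(table)
    by = list(by)
    for col in by:
        if col not in table.columns:
            raise ValueError(f"stratification column {col!r} not in table")
    rows = []
    for keys, sub in table.groupby(by, sort=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        sizes = sub.groupby("clonotype").size()
        classes = sizes.map(lambda s: classify(s).label)
        for cls in CloneClass:
            in_cls = classes == cls.label
            rows.append(
                dict(zip(by, keys))
                | {
                    "clone_class": cls.label,
                    "n_clonotypes": int(in_cls.sum()),
                    "n_cells": int(sizes[in_cls].sum()),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SharedClonotypes:
    """Clonotypes present in both tissues, with per-tissue sizes and classes."""

    table: pd.DataFrame  # clonotype, size_a, size_b, class_a, class_b
    tissue_a: str
    tissue_b: str
    contingency: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def keys(self) -> set:
        return set(self.table["clonotype"])


def shared_clonotypes(
    table: pd.DataFrame,
    tissue_a: str = "liver",
    tissue_b: str = "tumor",
    group: Optional[str] = None,
) -> SharedClonotypes:
    """Clonotypes observed in both tissues.

    The key set is symmetric in the two tissue arguments; the report carries
    each shared clonotype's size and expansion class per tissue plus a
    class_a × class_b contingency summary.
    """
    sizes_a = clone_sizes(table, tissue=tissue_a, group=group)
    sizes_b = clone_sizes(table, tissue=tissue_b, group=group)
    shared = sorted(set(sizes_a.index) & set(sizes_b.index))
    out = pd.DataFrame(
        {
            "clonotype": shared,
            "size_a": [int(sizes_a[k]) for k in shared],
            "size_b": [int(sizes_b[k]) for k in shared],
        }
    )
    out["class_a"] = out["size_a"].map(lambda s: classify(s).label) if len(out) else []
    out["class_b"] = out["size_b"].map(lambda s: classify(s).label) if len(out) else []
    cont = (
        pd.crosstab(out["class_a"], out["class_b"])
        if len(out)
        else pd.DataFrame()
    )
    return SharedClonotypes(table=out, tissue_a=tissue_a, tissue_b=tissue_b, contingency=cont)


def sharing_fraction(
    table: pd.DataFrame, tissue_a: str = "liver", tissue_b: str = "tumor"
) -> float:
    """Fraction of tissue_b clonotypes also observed in tissue_a."""
    sizes_b = clone_sizes(table, tissue=tissue_b)
    if len(sizes_b) == 0:
        return float("nan")
    shared = shared_clonotypes(table, tissue_a, tissue_b).keys
    return len(shared) / len(sizes_b)
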