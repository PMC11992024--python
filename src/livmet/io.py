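"""Tabular input/output for transcript tables and co-localization matrices.

Transcript tables follow the MERSCOPE detected-transcripts CSV export: one row
per decoded transcript with the gene name, stitched planar coordinates in
micrometres, and the segmented cell the transcript was assigned to. Column
names vary between export versions, so the reader takes an explicit
:class:`TranscriptDialect`. Negative-control "blank" barcodes are dropped on
read (they are decoding controls, not genes).

Matrices are written as TSV with a gene-name header row and index column;
floats are serialized with 17 significant digits so that a write/read
round-trip is bit-exact, and missing entries use the literal token ``NA``.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel used in-memory for transcripts the segmentation did not assign to a cell.
UNASSIGNED = "unassigned"

TRANSCRIPT_COLUMNS = ("gene", "x", "y", "cell_id")


class FormatError(ValueError):
    """A file does not conform to the declared dialect or schema."""


@dataclass(frozen=True)
class TranscriptDialect:
    """Column naming and conventions of a transcript CSV.

    ``unassigned`` is the sentinel value the export uses for transcripts
    outside any segmented cell (MERSCOPE uses ``-1``). Coordinates are
    micrometres in a single global (stitched) frame.
    """

    gene: str = "gene"
    x: str = "global_x"
    y: str = "global_y"
    cell: str = "cell_id"
    unassigned: str = "-1"
    blank_prefix: str = "Blank-"


DEFAULT_DIALECT = TranscriptDialect()


class GenePanel(Sequence):
    """Ordered list of unique gene names; defines matrix row/column order."""

    def __init__(self, genes: Iterable[str]):
        genes = tuple(str(g) for g in genes)
        if not genes:
            raise ValueError("gene panel is empty")
        dupes = pd.Index(genes)[pd.Index(genes).duplicated()].unique().tolist()
        if dupes:
            raise ValueError(f"duplicate genes in panel: {dupes}")
        self.genes = genes
        self._index = {g: i for i, g in enumerate(genes)}

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "GenePanel":
        """Panel in first-seen order of a transcript table."""
        return cls(pd.unique(table["gene"]))

    @classmethod
    def from_file(cls, path) -> "GenePanel":
        """One gene per line; blank lines and ``#`` comments ignored."""
        names = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                names.append(line)
        return cls(names)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene not in panel: {gene!r}") from None

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, i):
        return self.genes[i]

    def __contains__(self, gene) -> bool:
        return gene in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, GenePanel) and self.genes == other.genes

    def __repr__(self) -> str:
        return f"GenePanel(n={len(self)})"


def read_transcripts(
    path,
    dialect: TranscriptDialect = DEFAULT_DIALECT,
    keep_blanks: bool = False,
) -> pd.DataFrame:
    """Read a transcript CSV into the canonical (gene, x, y, cell_id) frame.

    Blank-barcode rows are dropped (unless ``keep_blanks``) and the dropped
    count is logged and stored in ``df.attrs["blanks_dropped"]``. Unassigned
    cell identities are mapped to the :data:`UNASSIGNED` sentinel. A
    ``section`` column, if present, is carried through for per-section pooling.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (dialect.gene, dialect.x, dialect.y, dialect.cell):
        if col not in raw.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")

    coords = {}
    for axis, col in (("x", dialect.x), ("y", dialect.y)):
        vals = pd.to_numeric(raw[col], errors="coerce").to_numpy(float)
        bad = ~np.isfinite(vals)
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad)[0]) + 2
            raise FormatError(
                f"non-numeric coordinate in column {col!r} at line {line} of {path}"
            )
        coords[axis] = vals

    gene = raw[dialect.gene].astype(str)
    if gene.str.len().eq(0).any():
        line = int(np.flatnonzero(gene.str.len().eq(0))[0]) + 2
        raise FormatError(f"empty gene name at line {line} of {path}")

    cell = raw[dialect.cell].astype(str).str.strip()
    cell = cell.where(~cell.isin({dialect.unassigned, ""}), UNASSIGNED)

    df = pd.DataFrame(
        {"gene": gene.to_numpy(), "x": coords["x"], "y": coords["y"], "cell_id": cell.to_numpy()}
    )
    if "section" in raw.columns:
        df["section"] = raw["section"].to_numpy()

    n_blank = 0
    if not keep_blanks:
        blank = df["gene"].str.startswith(dialect.blank_prefix)
        n_blank = int(blank.sum())
        if n_blank:
            log.info("dropped %d blank-barcode transcripts from %s", n_blank, path)
            df = df.loc[~blank].reset_index(drop=True)
    df.attrs["blanks_dropped"] = n_blank
    df.attrs["source"] = str(path)
    return df


def write_transcripts(df: pd.DataFrame, path, dialect: TranscriptDialect = DEFAULT_DIALECT) -> None:
    """Write a canonical transcript frame back out in the given CSV dialect."""
    out = pd.DataFrame(
        {
            dialect.gene: df["gene"],
            dialect.x: df["x"],
            dialect.y: df["y"],
            dialect.cell: df["cell_id"].replace({UNASSIGNED: dialect.unassigned}),
        }
    )
    if "section" in df.columns:
        out["section"] = df["section"]
    out.to_csv(path, index=False)


def _as_frame(matrix) -> pd.DataFrame:
    """Accept a ColocMatrix-like object (``.to_frame()``) or a labelled DataFrame."""
    frame = matrix.to_frame() if hasattr(matrix, "to_frame") else matrix
    if not isinstance(frame, pd.DataFrame):
        raise TypeError(f"cannot serialize matrix of type {type(matrix).__name__}")
    if frame.shape[0] != frame.shape[1] or list(frame.index) != list(frame.columns):
        raise ValueError(
            f"matrix is not square with matching labels: shape {frame.shape}"
        )
    return frame


def write_matrix(matrix, path) -> None:
    """Serialize a square labelled matrix to TSV; NA entries become ``"NA"``.

    17 significant digits guarantee exact float round-trip through
    :func:`read_matrix`.
    """
    frame = _as_frame(matrix)
    frame.to_csv(path, sep="\t", float_format="%.17g", na_rep="NA", index_label="gene")


def read_matrix(path) -> pd.DataFrame:
    """Read a matrix TSV written by :func:`write_matrix`."""
    frame = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False,
        float_precision="round_trip",
    )
    frame.index.name = None
    if frame.shape[0] != frame.shape[1] or list(frame.index) != list(frame.columns):
        raise FormatError(f"{path} is not a square labelled matrix")
    return frame.astype(float)


def matrix_to_long(matrix) -> pd.DataFrame:
    """Long-format (gene_a, gene_b, score) export for plotting tools."""
    frame = _as_frame(matrix)
    long = frame.stack(future_stack=True).rename("score").reset_index()
    long.columns = ["gene_a", "gene_b", "score"]
    return long
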