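"""Pairwise transcript co-localization scoring on imaging-based spatial data.

The score asks, for an ordered gene pair (A, B): what fraction of transcripts
participate in a "close" A→B interaction? A transcript of the source gene A is
close to the partner gene B if at least one B transcript lies strictly within
the radius (default 30 µm — a disc covering a handful of cells) *and* in a
different cell. Each source transcript contributes at most one interaction no
matter how many partners are near; the count is then normalized as

    score(A, B) = 2 * close_count(A, B) / (n_A + n_B)

which is 1.0 for an equal-count, fully-paired configuration. Because the
unique-interaction rule is applied on the source side only, score(A, B) and
score(B, A) generally differ and the gene×gene matrix is asymmetric.

Counting semantics, spelled out: entry (A, B) counts A transcripts having at
least one close B partner in another cell. This is the only reading under
which the unique-interaction rule produces an asymmetric matrix; summing both
directions would be symmetric.

Same-cell exclusion keeps the score about tissue-level neighbourhoods rather
than co-expression within a single cell. Transcripts the segmentation left
unassigned are, by default, each treated as their own singleton cell (the
exclusion rule is keyed on sharing a cell identity, which they never do); a
``drop`` policy removes them instead.

Scores can exceed 1 when n_source >> n_partner; values are reported unclamped
with a warning, since the [0, 1] range is only guaranteed for
n_source <= n_partner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import UNASSIGNED, GenePanel

log = logging.getLogger(__name__)

_UNASSIGNED_POLICIES = ("singleton", "drop")


@dataclass(frozen=True)
class ColocParams:
    """Parameters of the co-localization score.

    radius
        Close-interaction threshold in µm; the comparison is strictly
        less-than ("below the threshold").
    same_cell_exclusion
        Ignore partner transcripts sharing the source transcript's cell.
    unassigned_policy
        ``singleton`` — every unassigned transcript is its own cell (never
        excluded by the same-cell rule); ``drop`` — remove unassigned
        transcripts before scoring.
    include_diagonal
        Compute (A, A) entries (with self-pairing forbidden); when off the
        diagonal is NA.
    """

    radius: float = 30.0
    same_cell_exclusion: bool = True
    unassigned_policy: str = "singleton"
    include_diagonal: bool = True

    def __post_init__(self):
        if not np.isfinite(self.radius) or self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if self.unassigned_policy not in _UNASSIGNED_POLICIES:
            raise ValueError(
                f"unassigned_policy must be one of {_UNASSIGNED_POLICIES}, "
                f"got {self.unassigned_policy!r}"
            )


@dataclass
class ColocMatrix:
    """Square, ordered-panel matrix of normalized co-localization scores.

    ``values[i, j]`` is score(panel[i] as source, panel[j] as partner), NaN
    where n_i + n_j == 0. ``counts`` holds per-gene transcript counts used in
    the normalization.
    """

    panel: GenePanel
    values: np.ndarray
    counts: np.ndarray
    params: ColocParams
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        g = len(self.panel)
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.values.shape != (g, g):
            raise ValueError(f"values shape {self.values.shape} != ({g}, {g})")
        if self.counts.shape != (g,):
            raise ValueError(f"counts shape {self.counts.shape} != ({g},)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.panel.genes, columns=self.panel.genes)

    def score(self, source_gene: str, partner_gene: str) -> float:
        return float(
            self.values[self.panel.index_of(source_gene), self.panel.index_of(partner_gene)]
        )


@dataclass
class DiffMatrix:
    """Elementwise case − control differential of two score matrices.

    Positive entries mean the gene pair is closer (higher score) in the case
    condition; the convention is recorded in ``meta['sign_convention']``.
    """

    panel: GenePanel
    values: np.ndarray
    case_label: str = "case"
    control_label: str = "control"
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.panel.genes, columns=self.panel.genes)

    def score(self, source_gene: str, partner_gene: str) -> float:
        return float(
            self.values[self.panel.index_of(source_gene), self.panel.index_of(partner_gene)]
        )


def _prepare(table: pd.DataFrame, params: ColocParams):
    """Return (points, cell codes, kept frame) honouring the unassigned policy.

    Cell codes are integers; under the singleton policy each unassigned
    transcript receives a unique negative code so it never shares a cell.
    """
    cell = table["cell_id"].astype(str).to_numpy()
    una = cell == UNASSIGNED
    if params.unassigned_policy == "drop" and una.any():
        table = table.loc[~una].reset_index(drop=True)
        cell = cell[~una]
        una = np.zeros(len(table), dtype=bool)
    codes = pd.factorize(cell)[0].astype(np.int64)
    if una.any():
        codes = codes.copy()
        codes[una] = -1 - np.arange(int(una.sum()), dtype=np.int64)
    pts = np.column_stack([table["x"].to_numpy(float), table["y"].to_numpy(float)])
    if not np.isfinite(pts).all():
        raise ValueError("transcript coordinates must be finite")
    return pts, codes, table


def close_count(
    source_gene: str,
    partner_gene: str,
    table: pd.DataFrame,
    params: ColocParams = ColocParams(),
    panel: Optional[GenePanel] = None,
) -> int:
    """Number of source-gene transcripts with ≥1 close partner-gene transcript.

    Close means Euclidean distance strictly below ``params.radius`` and (with
    the exclusion on) a different cell; a transcript is never its own partner.
    """
    if panel is not None:
        for g in (source_gene, partner_gene):
            if g not in panel:
                raise KeyError(f"gene not in panel: {g!r}")
    pts, cells, kept = _prepare(table, params)
    genes = kept["gene"].to_numpy()
    src = genes == source_gene
    par = genes == partner_gene
    if panel is None:
        known = set(pd.unique(genes))
        for g in (source_gene, partner_gene):
            if g not in known:
                raise KeyError(f"gene not in table (no panel supplied): {g!r}")
    if not src.any() or not par.any():
        return 0

    src_idx = np.flatnonzero(src)
    par_idx = np.flatnonzero(par)
    tree = cKDTree(pts[par_idx])
    neighbours = tree.query_ball_point(pts[src_idx], params.radius)
    r2 = params.radius**2
    count = 0
    for k, neigh in enumerate(neighbours):
        if not neigh:
            continue
        i = src_idx[k]
        cand = par_idx[np.asarray(neigh)]
        cand = cand[cand != i]  # never its own partner
        if cand.size == 0:
            continue
        d2 = ((pts[cand] - pts[i]) ** 2).sum(axis=1)
        ok = d2 < r2  # tree uses <= r; enforce strict
        if params.same_cell_exclusion:
            ok &= cells[cand] != cells[i]
        if ok.any():
            count += 1
    return count


def coloc_score(
    source_gene: str,
    partner_gene: str,
    table: pd.DataFrame,
    params: ColocParams = ColocParams(),
    panel: Optional[GenePanel] = None,
) -> float:
    """Normalized score 2·close_count/(n_source + n_partner); NaN if both absent."""
    c = close_count(source_gene, partner_gene, table, params, panel)
    _, _, kept = _prepare(table, params)
    genes = kept["gene"].to_numpy()
    n = int((genes == source_gene).sum()) + int((genes == partner_gene).sum())
    if source_gene == partner_gene:
        n = int((genes == source_gene).sum()) * 2
    if n == 0:
        return float("nan")
    return 2.0 * c / n


def _pair_counts(table: pd.DataFrame, panel: GenePanel, params: ColocParams):
    """Close-interaction count matrix and per-gene transcript counts for one section.

    Single global k-d tree over all transcripts; candidate pairs within the
    radius are re-filtered to strict distance, the same-cell rule is applied,
    and each (source transcript, partner gene) pair is counted once.
    """
    pts, cells, kept = _prepare(table, params)
    g = len(panel)
    gene_codes = kept["gene"].map(dict(zip(panel.genes, range(g))))
    known = gene_codes.notna().to_numpy()
    if not known.all():
        dropped = kept.loc[~known, "gene"].nunique()
        log.info("ignoring %d transcripts of %d off-panel genes", int((~known).sum()), dropped)
        pts, cells = pts[known], cells[known]
        gene_codes = gene_codes[known]
    gcode = gene_codes.to_numpy(dtype=np.int64)

    n_g = np.bincount(gcode, minlength=g).astype(np.int64)
    counts = np.zeros((g, g), dtype=np.int64)
    if len(pts) == 0:
        return counts, n_g

    tree = cKDTree(pts)
    pairs = tree.query_pairs(params.radius, output_type="ndarray")
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d2 = ((pts[i] - pts[j]) ** 2).sum(axis=1)
        keep = d2 < params.radius**2  # strict comparison
        if params.same_cell_exclusion:
            keep &= cells[i] != cells[j]
        i, j = i[keep], j[keep]
        if len(i):
            # both directions: each transcript acts as source toward the other's gene
            src = np.concatenate([i, j])
            partner_gene = np.concatenate([gcode[j], gcode[i]])
            key = src * g + partner_gene  # unique (source transcript, partner gene)
            uniq = np.unique(key)
            np.add.at(counts, (gcode[uniq // g], uniq % g), 1)
    return counts, n_g


def coloc_matrix(
    table: pd.DataFrame,
    panel: Optional[GenePanel] = None,
    params: ColocParams = ColocParams(),
    section_col: Optional[str] = None,
    combine: str = "pooled",
) -> ColocMatrix:
    """Full gene×gene co-localization matrix.

    Uses fixed-radius k-d tree indexing (subquadratic in transcript count);
    the result is identical to the all-pairs brute force.

    Multiple sections (``section_col``) are combined either by pooling the
    interaction counts and transcript counts before normalization
    (``combine="pooled"``, default) or by averaging per-section score
    matrices (``combine="mean"``).
    """
    if panel is None:
        if len(table) == 0:
            raise ValueError("cannot infer a panel from an empty table")
        panel = GenePanel.from_table(table)
    if combine not in ("pooled", "mean"):
        raise ValueError(f"combine must be 'pooled' or 'mean', got {combine!r}")
    if section_col is None and "section" in table.columns:
        section_col = "section"

    sections = (
        [tab for _, tab in table.groupby(section_col, sort=True)]
        if section_col is not None and table[section_col].nunique() > 1
        else [table]
    )

    g = len(panel)
    if combine == "pooled" or len(sections) == 1:
        total_counts = np.zeros((g, g), dtype=np.int64)
        total_n = np.zeros(g, dtype=np.int64)
        for sec in sections:
            c, n = _pair_counts(sec, panel, params)
            total_counts += c
            total_n += n
        denom = total_n[:, None] + total_n[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(denom > 0, 2.0 * total_counts / np.maximum(denom, 1), np.nan)
        values[denom == 0] = np.nan
        n_out = total_n
    else:
        per_section = []
        total_n = np.zeros(g, dtype=np.int64)
        for sec in sections:
            c, n = _pair_counts(sec, panel, params)
            denom = n[:, None] + n[None, :]
            with np.errstate(invalid="ignore", divide="ignore"):
                v = np.where(denom > 0, 2.0 * c / np.maximum(denom, 1), np.nan)
            v[denom == 0] = np.nan
            per_section.append(v)
            total_n += n
        with np.errstate(invalid="ignore"):
            values = np.nanmean(np.stack(per_section), axis=0)
        n_out = total_n

    if not params.include_diagonal:
        np.fill_diagonal(values, np.nan)
    over = np.nansum(values > 1.0)
    if over:
        log.warning(
            "%d score(s) exceed 1 (possible when n_source >> n_partner); reported unclamped",
            int(over),
        )
    meta = {
        "n_sections": len(sections),
        "combine": combine,
        "diagonal_included": params.include_diagonal,
        "source": table.attrs.get("source"),
    }
    return ColocMatrix(panel=panel, values=values, counts=n_out, params=params, meta=meta)


def differential_matrix(case: ColocMatrix, control: ColocMatrix) -> DiffMatrix:
    """case − control, elementwise and NA-propagating.

    Positive entries indicate closer proximity (higher score) in the case
    condition. Panels and parameters must match.
    """
    if case.panel != control.panel:
        a, b = set(case.panel.genes), set(control.panel.genes)
        diff = sorted(a.symmetric_difference(b))
        raise ValueError(
            f"panel mismatch between case and control; symmetric difference: {diff}"
            if diff
            else "panels contain the same genes but in different order"
        )
    if case.params != control.params:
        raise ValueError(
            f"parameter mismatch: case {case.params} vs control {control.params}"
        )
    values = case.values - control.values
    meta = {
        "sign_convention": "positive = closer in case",
        "params": case.params,
    }
    return DiffMatrix(
        panel=case.panel,
        values=values,
        case_label=case.meta.get("condition", "case"),
        control_label=control.meta.get("condition", "control"),
        meta=meta,
    )


def subset_heatmap(diff: DiffMatrix, gene_subset, out_path=None):
    """Slice a differential matrix to a gene subset and render a heatmap.

    Returns ``(sliced frame, matplotlib figure)``. The colour scale is
    diverging and centred at 0 so sign (closer in case vs control) is
    immediately readable.
    """
    genes = list(gene_subset)
    if not genes:
        raise ValueError("gene subset is empty")
    unknown = [g for g in genes if g not in diff.panel]
    if unknown:
        raise KeyError(f"genes not in panel: {unknown}")
    idx = [diff.panel.index_of(g) for g in genes]
    sliced = pd.DataFrame(
        diff.values[np.ix_(idx, idx)], index=genes, columns=genes
    )

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import TwoSlopeNorm

    vmax = float(np.nanmax(np.abs(sliced.to_numpy()))) if np.isfinite(
        sliced.to_numpy()
    ).any() else 1.0
    vmax = vmax or 1.0
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(genes)),) * 2)
    im = ax.imshow(
        sliced.to_numpy(),
        cmap="RdBu_r",
        norm=TwoSlopeNorm(vcenter=0.0, vmin=-vmax, vmax=vmax),
    )
    ax.set_xticks(range(len(genes)), genes, rotation=90, fontsize=7)
    ax.set_yticks(range(len(genes)), genes, fontsize=7)
    ax.set_title(f"{diff.case_label} − {diff.control_label}")
    fig.colorbar(im, ax=ax, label="Δ co-localization score")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return sliced, fig
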