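"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Three generators, all bit-reproducible under a fixed seed:

* :func:`gen_transcripts` — spatial point patterns per gene on a square
  field with a square cell mosaic (20 µm pitch by default, so a 30 µm disc
  covers roughly 7 cells, matching the "handful of cells" the close radius
  is meant to capture). Co-localization is planted for chosen gene pairs by
  placing a fraction of the second gene's transcripts at a Gaussian offset
  from randomly chosen transcripts of the first; everything else is uniform.
* :func:`gen_clonotypes` — clone-size distributions (geometric by default,
  power-law as alternative) for two tissues with a configurable fraction of
  tumor clonotypes shared into the liver.
* :func:`gen_variants` — four overlapping variant call sets with independent
  per-set detection, plus per-variant predictor score tables and expression,
  with the consensus (≥3-of-4 missense) ground truth recorded for recovery
  tests.

The generators emulate the statistical structure only: no imaging optics,
blank-barcode decoding errors, segmentation errors, or read-level sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import UNASSIGNED
from .neoantigen import VariantCallSet

AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    """A simulation config violates its invariants."""


# --- spatial transcripts ----------------------------------------------------


@dataclass(frozen=True)
class ColocPair:
    """Planted co-localization: a fraction of gene_b transcripts is placed at
    Gaussian offset (sigma, µm) from random gene_a transcripts."""

    gene_a: str
    gene_b: str
    sigma: float = 2.0
    coupled_fraction: float = 0.8

    def __post_init__(self):
        if self.sigma < 0:
            raise ConfigError(f"dispersion sigma must be >= 0, got {self.sigma}")
        if not 0.0 <= self.coupled_fraction <= 1.0:
            raise ConfigError(
                f"coupled_fraction must be in [0, 1], got {self.coupled_fraction}"
            )


@dataclass(frozen=True)
class SpatialSimConfig:
    """Square field of ``field_size`` µm; ``n_genes`` genes with uniform
    transcripts except where a :class:`ColocPair` plants structure.

    ``transcripts_per_gene`` may be a single count or a per-gene vector.
    ``unassigned_fraction`` emits that fraction of transcripts without a cell
    identity, to exercise the scorer's unassigned policy.
    """

    seed: int = 0
    field_size: float = 1000.0
    n_genes: int = 50
    transcripts_per_gene: object = 200
    cell_grid_pitch: float = 20.0
    coloc_pairs: tuple = ()
    unassigned_fraction: float = 0.0
    gene_names: Optional[tuple] = None

    def __post_init__(self):
        if self.field_size <= 0:
            raise ConfigError(f"field_size must be positive, got {self.field_size}")
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.cell_grid_pitch <= 0:
            raise ConfigError(f"cell_grid_pitch must be positive, got {self.cell_grid_pitch}")
        if not 0.0 <= self.unassigned_fraction <= 1.0:
            raise ConfigError("unassigned_fraction must be in [0, 1]")
        counts = self.per_gene_counts()
        if (counts < 0).any():
            raise ConfigError("transcript counts must be non-negative")
        names = self.genes()
        if len(names) != self.n_genes:
            raise ConfigError("gene_names length must equal n_genes")
        for p in self.coloc_pairs:
            if p.gene_a not in names or p.gene_b not in names:
                raise ConfigError(f"coloc pair references unknown gene: {p}")

    def genes(self) -> tuple:
        if self.gene_names is not None:
            return tuple(self.gene_names)
        width = max(3, len(str(self.n_genes - 1)))
        return tuple(f"gene_{i:0{width}d}" for i in range(self.n_genes))

    def per_gene_counts(self) -> np.ndarray:
        if np.isscalar(self.transcripts_per_gene):
            return np.full(self.n_genes, int(self.transcripts_per_gene), dtype=np.int64)
        counts = np.asarray(self.transcripts_per_gene, dtype=np.int64)
        if counts.shape != (self.n_genes,):
            raise ConfigError(
                f"transcripts_per_gene vector length {counts.shape} != n_genes {self.n_genes}"
            )
        return counts


def _mosaic_cell_ids(x: np.ndarray, y: np.ndarray, pitch: float) -> np.ndarray:
    ix = np.floor(x / pitch).astype(int)
    iy = np.floor(y / pitch).astype(int)
    return np.char.add(np.char.add(ix.astype(str), "_"), iy.astype(str))


def gen_transcripts(config: SpatialSimConfig) -> pd.DataFrame:
    """Generate a transcript table (gene, x, y, cell_id) from the config.

    Coupled transcripts falling outside the field are re-drawn (fresh anchor
    and offset) so per-gene counts stay exact; cell identity is the square
    mosaic cell containing the point.
    """
    rng = np.random.default_rng(config.seed)
    genes = config.genes()
    counts = config.per_gene_counts()
    L = config.field_size

    coords = {
        g: rng.uniform(0.0, L, size=(int(n), 2)) for g, n in zip(genes, counts)
    }
    for pair in config.coloc_pairs:
        anchors = coords[pair.gene_a]
        pts_b = coords[pair.gene_b]
        if len(anchors) == 0 or len(pts_b) == 0:
            continue
        n_coupled = int(round(pair.coupled_fraction * len(pts_b)))
        which = rng.choice(len(pts_b), size=n_coupled, replace=False)
        for idx in which:
            for _ in range(10_000):  # rejection: keep counts exact
                anchor = anchors[rng.integers(len(anchors))]
                cand = anchor + rng.normal(0.0, pair.sigma, size=2)
                if 0.0 <= cand[0] < L and 0.0 <= cand[1] < L:
                    pts_b[idx] = cand
                    break
            else:
                raise RuntimeError("rejection sampling failed to place a coupled transcript")

    frames = []
    for g in genes:
        pts = coords[g]
        frames.append(pd.DataFrame({"gene": g, "x": pts[:, 0], "y": pts[:, 1]}))
    df = pd.concat(frames, ignore_index=True)
    df["cell_id"] = _mosaic_cell_ids(
        df["x"].to_numpy(), df["y"].to_numpy(), config.cell_grid_pitch
    )
    if config.unassigned_fraction > 0:
        n_un = int(round(config.unassigned_fraction * len(df)))
        which = rng.choice(len(df), size=n_un, replace=False)
        df.loc[which, "cell_id"] = UNASSIGNED
    return df


# --- clonotypes -------------------------------------------------------------


@dataclass(frozen=True)
class ClonotypeSimConfig:
    """Clone-size law per tissue plus a tumor→liver sharing fraction.

    ``clone_size_law`` is ``geometric`` (parameter ``p``) or ``power``
    (Zipf exponent ``alpha``); neither law is a claim about real repertoires,
    they just give a realistic long tail.
    """

    seed: int = 0
    n_cells_liver: int = 1000
    n_cells_tumor: int = 1000
    clone_size_law: str = "geometric"
    p: float = 0.5
    alpha: float = 2.5
    sharing_fraction: float = 0.3

    def __post_init__(self):
        if self.n_cells_liver < 1 or self.n_cells_tumor < 1:
            raise ConfigError("cell counts must be positive")
        if self.clone_size_law not in ("geometric", "power"):
            raise ConfigError(f"unknown clone_size_law {self.clone_size_law!r}")
        if not 0.0 < self.p <= 1.0:
            raise ConfigError(f"geometric p must be in (0, 1], got {self.p}")
        if self.alpha <= 1.0:
            raise ConfigError(f"power-law alpha must be > 1, got {self.alpha}")
        if not 0.0 <= self.sharing_fraction <= 1.0:
            raise ConfigError("sharing_fraction must be in [0, 1]")


def _clone_size(rng: np.random.Generator, config: ClonotypeSimConfig) -> int:
    if config.clone_size_law == "geometric":
        return int(rng.geometric(config.p))
    return int(rng.zipf(config.alpha))


def _cdr3_key(rng: np.random.Generator) -> str:
    middle = "".join(rng.choice(list(AA), size=int(rng.integers(6, 12))))
    return f"CASS{middle}F"


def gen_clonotypes(config: ClonotypeSimConfig) -> pd.DataFrame:
    """Per-cell clonotype table (cell_id, clonotype, tissue).

    Tumor clones are drawn first; a ``sharing_fraction`` of tumor clonotype
    keys is re-used (with fresh sizes) among the liver clones. The last clone
    in each tissue is truncated so cell counts are exact; if the shared keys
    alone cannot fit in the liver the config is rejected.
    """
    rng = np.random.default_rng(config.seed)

    def draw_clones(n_cells: int, fixed_keys: Sequence[str] = ()):
        sizes, keys = [], []
        total = 0
        for k in fixed_keys:
            s = _clone_size(rng, config)
            keys.append(k)
            sizes.append(s)
            total += s
        while total < n_cells:
            s = _clone_size(rng, config)
            keys.append(_cdr3_key(rng))
            sizes.append(s)
            total += s
        # truncate overshoot from the tail; fixed keys shrink to 1 but are never dropped
        excess = total - n_cells
        i = len(sizes) - 1
        while excess > 0 and i >= 0:
            if i >= len(fixed_keys):
                cut = min(excess, sizes[i])
                sizes[i] -= cut
                excess -= cut
                if sizes[i] == 0:
                    del sizes[i], keys[i]
            else:
                cut = min(excess, sizes[i] - 1)
                sizes[i] -= cut
                excess -= cut
            i -= 1
        if excess > 0:
            raise ConfigError(
                "sharing_fraction demands more liver clones than liver cells"
            )
        return keys, sizes

    tumor_keys, tumor_sizes = draw_clones(config.n_cells_tumor)
    n_shared = int(round(config.sharing_fraction * len(tumor_keys)))
    shared = list(rng.choice(tumor_keys, size=n_shared, replace=False)) if n_shared else []
    liver_keys, liver_sizes = draw_clones(config.n_cells_liver, fixed_keys=shared)

    rows = []
    counter = 0
    for tissue, keys, sizes in (
        ("tumor", tumor_keys, tumor_sizes),
        ("liver", liver_keys, liver_sizes),
    ):
        for k, s in zip(keys, sizes):
            for _ in range(s):
                rows.append({"cell_id": f"cell_{counter:06d}", "clonotype": k, "tissue": tissue})
                counter += 1
    return pd.DataFrame(rows)


# --- variants ---------------------------------------------------------------


@dataclass(frozen=True)
class VariantSimConfig:
    """Four overlapping call sets with independent per-set detection.

    Score distributions (log-normal affinity and TPM, log-normal
    agretopicity centred at 1, uniform foreignness) are free parameters with
    defaults in the range epitope predictors typically report.
    """

    seed: int = 0
    n_variants: int = 1000
    detection_probs: tuple = (0.9, 0.9, 0.9, 0.9)
    missense_fraction: float = 0.8
    germline_fraction: float = 0.0
    affinity_log_mean: float = np.log(150.0)
    affinity_log_sigma: float = 1.2
    tpm_log_mean: float = np.log(10.0)
    tpm_log_sigma: float = 1.5
    agretopicity_log_sigma: float = 0.7
    predictor_report_prob: float = 0.8

    def __post_init__(self):
        if self.n_variants < 1:
            raise ConfigError("n_variants must be positive")
        if len(self.detection_probs) != 4:
            raise ConfigError(
                f"exactly 4 detection probabilities required, got {len(self.detection_probs)}"
            )
        for p in self.detection_probs + (
            self.missense_fraction,
            self.germline_fraction,
            self.predictor_report_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability out of [0, 1]: {p}")


@dataclass
class SimulatedVariants:
    """Four call sets, two predictor tables, expression, and the ground truth."""

    sets: list
    predictor_tables: list
    expression: pd.Series
    truth: pd.DataFrame


SET_NAMES = ("WES_invivo", "WES_invitro", "RNA_invivo", "RNA_invitro")


def gen_variants(config: VariantSimConfig) -> SimulatedVariants:
    """Simulate the variant-calling inputs of the consensus filter.

    ``truth`` records per variant its effect, germline flag, number of
    detecting sets, and whether it passes the ≥3-of-4 missense consensus —
    the quantity recovery tests compare against.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    bases = np.array(list("ACGT"))

    chrom = np.array([f"chr{c}" for c in rng.integers(1, 20, size=n)])
    pos = rng.choice(np.arange(1, 50_000_000), size=n, replace=False)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    effects = np.where(
        rng.random(n) < config.missense_fraction,
        "missense",
        rng.choice(["synonymous", "stop_gained", "intron"], size=n),
    )
    gene_pool = [f"Gene{i:04d}" for i in range(max(10, n // 2))]
    genes = rng.choice(gene_pool, size=n)
    germline = rng.random(n) < config.germline_fraction

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos.astype(int),
            "ref": bases[ref_idx],
            "alt": bases[alt_idx],
            "effect": effects,
            "gene": genes,
            "germline": germline,
        }
    )

    detected = np.column_stack(
        [rng.random(n) < p for p in config.detection_probs]
    )
    sets = [
        VariantCallSet(name=SET_NAMES[k], variants=variants.loc[detected[:, k]].reset_index(drop=True))
        for k in range(4)
    ]

    n_sets = detected.sum(axis=1)
    truth = variants.assign(
        n_sets=n_sets,
        consensus=(n_sets >= 3) & (variants["effect"] == "missense") & ~germline,
    )

    # predictor tables: one 9-mer candidate per missense variant, reported by
    # each predictor independently (guaranteed by at least one)
    missense = truth[truth["effect"] == "missense"].reset_index(drop=True)
    m = len(missense)
    peptides = np.array(
        ["".join(rng.choice(list(AA), size=9)) for _ in range(m)]
    )
    base_aff = rng.lognormal(config.affinity_log_mean, config.affinity_log_sigma, size=m)
    agre = rng.lognormal(0.0, config.agretopicity_log_sigma, size=m)
    foreign = rng.random(m)
    reported = np.column_stack(
        [rng.random(m) < config.predictor_report_prob for _ in range(2)]
    )
    reported[~reported.any(axis=1), 0] = True

    tables = []
    for k in range(2):
        noise = rng.lognormal(0.0, 0.2, size=m)
        tab = pd.DataFrame(
            {
                "peptide": peptides,
                "allele": "H2-Kb",
                "affinity_nM": base_aff * noise,
                "agretopicity": agre,
                "foreignness": foreign,
                "gene": missense["gene"].to_numpy(),
                "chrom": missense["chrom"].to_numpy(),
                "pos": missense["pos"].to_numpy(),
                "ref": missense["ref"].to_numpy(),
                "alt": missense["alt"].to_numpy(),
            }
        ).loc[reported[:, k]].reset_index(drop=True)
        tables.append(tab)

    expressed = pd.Series(
        rng.lognormal(config.tpm_log_mean, config.tpm_log_sigma, size=len(gene_pool)),
        index=gene_pool,
        name="tpm",
    )
    # ~10% of genes are silent
    silent = rng.random(len(gene_pool)) < 0.1
    expressed[silent] = 0.0

    return SimulatedVariants(
        sets=sets, predictor_tables=tables, expression=expressed, truth=truth
    )
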