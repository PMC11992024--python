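"""Neoantigen candidate selection and chimeric construct assembly.

The selection logic of a tumor-agnostic antigen discovery pipeline:

1. **Consensus filter** — somatic missense variants must be called in at
   least 3 of 4 datasets (WES and RNA, each from in vivo and in vitro
   samples); variants present in the matched germline reference are excluded
   first.
2. **Score integration** — epitope predictions from two external pipelines
   (consumed as tables, never executed here) are merged with gene expression
   (TPM); duplicates by (peptide, allele) keep the stronger (lower nM)
   predicted binder.
3. **Ranking** — hard filters on the four criteria (MHC-I affinity,
   expression, agretopicity, foreignness), then a configurable stable sort,
   ascending affinity first.
4. **Top-N selection** — default 33 peptides.
5. **Construct assembly** — the selected peptides are concatenated with
   linkers into a single chimeric protein (fused downstream of a CD74 moiety,
   tracked as metadata). Peptide order is chosen greedily to avoid creating
   strong MHC-I binders at the junctions: each junction is scored by its
   strongest (lowest-nM) junction-spanning 8–11-mer, and the assembly
   maximizes the weakest junction.

The external predictors' own scoring is out of scope; a deterministic
hash-based mock junction scorer is bundled for tests and examples.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]
VARIANT_COLUMNS = VARIANT_KEY + ["effect", "gene"]
PREDICTOR_COLUMNS = ["peptide", "allele", "affinity_nM", "agretopicity", "foreignness", "gene"]


@dataclass
class VariantCallSet:
    """One of the four variant call sets (WES/RNA × in vivo/in vitro).

    ``variants`` rows are unique per (chrom, pos, ref, alt); an optional
    boolean ``germline`` column marks variants also present in the matched
    control sample.
    """

    name: str
    variants: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant set {self.name!r} missing columns: {missing}")
        if self.variants.duplicated(subset=VARIANT_KEY).any():
            raise ValueError(f"duplicate variant records in set {self.name!r}")
        if "germline" not in self.variants.columns:
            self.variants = self.variants.assign(germline=False)


def consensus_filter(sets: Sequence[VariantCallSet], min_sets: int = 3) -> pd.DataFrame:
    """Missense variants called in ≥ ``min_sets`` of exactly 4 datasets.

    Germline-flagged variants (in any set) are removed before counting.
    Returns one row per surviving variant with its gene and an ``n_sets``
    occupancy column.
    """
    if len(sets) != 4:
        raise ValueError(f"expected exactly 4 variant call sets, got {len(sets)}")
    frames = []
    germline_keys = set()
    for s in sets:
        v = s.variants
        germline_keys |= set(map(tuple, v.loc[v["germline"], VARIANT_KEY].to_numpy()))
        frames.append(v.assign(_set=s.name))
    merged = pd.concat(frames, ignore_index=True)
    if germline_keys:
        keys = list(map(tuple, merged[VARIANT_KEY].to_numpy()))
        merged = merged.loc[[k not in germline_keys for k in keys]]
    missense = merged[merged["effect"] == "missense"]
    occupancy = missense.groupby(VARIANT_KEY)["_set"].nunique()
    keep = occupancy[occupancy >= min_sets]
    out = (
        missense.drop_duplicates(subset=VARIANT_KEY)
        .set_index(VARIANT_KEY)
        .loc[keep.index]
        .reset_index()[VARIANT_COLUMNS]
    )
    out["n_sets"] = keep.to_numpy()
    return out.sort_values(VARIANT_KEY, ignore_index=True)


def integrate_scores(
    variants: pd.DataFrame,
    predictor_tables: Sequence[pd.DataFrame],
    expression: Mapping[str, float],
    predictor_names: Sequence[str] = ("predictor_1", "predictor_2"),
) -> pd.DataFrame:
    """Merge the two predictors' candidate tables with expression.

    Candidates are restricted to genes of the consensus-filtered variants,
    deduplicated by (peptide, allele) keeping the lower predicted affinity,
    and annotated with TPM (0 when the gene is absent from the expression
    table). Malformed rows raise with their table and row number.
    """
    if len(predictor_tables) != 2:
        raise ValueError(f"expected 2 predictor tables, got {len(predictor_tables)}")
    genes = set(variants["gene"])
    frames = []
    for name, tab in zip(predictor_names, predictor_tables):
        missing = [c for c in PREDICTOR_COLUMNS if c not in tab.columns]
        if missing:
            raise ValueError(f"predictor table {name!r} missing columns: {missing}")
        tab = tab.copy()
        for col in ("affinity_nM", "agretopicity", "foreignness"):
            vals = pd.to_numeric(tab[col], errors="coerce")
            bad = ~np.isfinite(vals)
            bad |= (vals <= 0) if col in ("affinity_nM", "agretopicity") else (vals < 0)
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValueError(
                    f"malformed {col} in predictor table {name!r} at row {row}: "
                    f"{tab[col].iloc[row]!r}"
                )
            tab[col] = vals
        tab["provenance"] = name
        frames.append(tab[tab["gene"].isin(genes)])
    merged = pd.concat(frames, ignore_index=True)
    if len(merged) == 0:
        return merged.reindex(columns=PREDICTOR_COLUMNS + ["provenance", "tpm"])
    merged = (
        merged.sort_values(["peptide", "allele", "affinity_nM"], kind="stable")
        .drop_duplicates(subset=["peptide", "allele"], keep="first")
        .reset_index(drop=True)
    )
    merged["tpm"] = merged["gene"].map(lambda g: float(expression.get(g, 0.0)))
    return merged


@dataclass(frozen=True)
class RankConfig:
    """Thresholds and sort policy for candidate ranking.

    The four criteria are hard filters: predicted affinity at most
    ``affinity_max`` nM, expression strictly above ``tpm_min``, agretopicity
    (mutant/wild-type affinity ratio) at least ``agre_min``, foreignness at
    least ``foreign_min``. ``sort_keys`` is a list of (column, ascending)
    applied as a stable sort.
    """

    affinity_max: float = 500.0
    tpm_min: float = 0.0
    agre_min: float = 1.0
    foreign_min: float = 0.0
    sort_keys: tuple = (
        ("affinity_nM", True),
        ("tpm", False),
        ("foreignness", False),
        ("peptide", True),
    )

    def __post_init__(self):
        if self.affinity_max <= 0 or not math.isfinite(self.affinity_max):
            raise ValueError(f"affinity_max must be positive, got {self.affinity_max}")
        if self.tpm_min < 0 or self.agre_min < 0 or self.foreign_min < 0:
            raise ValueError("thresholds must be non-negative")
        if not self.sort_keys:
            raise ValueError("sort_keys must be non-empty")


def rank_candidates(candidates: pd.DataFrame, config: RankConfig = RankConfig()) -> pd.DataFrame:
    """Filter on the four criteria, then stable-sort (ascending affinity first)."""
    if len(candidates) == 0:
        return candidates.copy()
    keep = (
        (candidates["affinity_nM"] <= config.affinity_max)
        & (candidates["tpm"] > config.tpm_min)
        & (candidates["agretopicity"] >= config.agre_min)
        & (candidates["foreignness"] >= config.foreign_min)
    )
    cols = [k for k, _ in config.sort_keys]
    asc = [a for _, a in config.sort_keys]
    return (
        candidates.loc[keep]
        .sort_values(cols, ascending=asc, kind="stable")
        .reset_index(drop=True)
    )


def select_top(ranked: pd.DataFrame, n: int = 33) -> list[str]:
    """First min(n, available) peptides of a ranked candidate table."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return ranked["peptide"].head(n).tolist()


# --- chimeric construct assembly -------------------------------------------


def mock_junction_scorer(kmer: str) -> float:
    """Deterministic stand-in for an MHC-I binding predictor (nM in [1, 50000]).

    Hash-based so it is stable across processes and platforms; bundled for
    tests and examples only.
    """
    h = int(hashlib.md5(kmer.encode("ascii")).hexdigest()[:8], 16)
    return 1.0 + (h % 50000)


def junction_kmers(left: str, right: str, linker: str, kmin: int = 8, kmax: int = 11):
    """All k-mers (kmin..kmax) spanning the junction of ``left+linker+right``.

    A window spans the junction if it is not fully contained in either
    flanking peptide, i.e. it includes linker residues and/or crosses from
    one peptide into the other.
    """
    s = left + linker + right
    a, b = len(left), len(left) + len(linker)
    out = []
    for k in range(kmin, kmax + 1):
        for start in range(0, len(s) - k + 1):
            end = start + k
            if end > a and start < b:
                out.append(s[start:end])
    return out


def junction_score(
    left: str, right: str, linker: str, scorer: Callable[[str], float]
) -> float:
    """Strongest (lowest-nM) predicted binder among junction-spanning k-mers.

    Higher is better (the junction's best binder is weak); +inf when no
    window fits (very short total sequence).
    """
    kmers = junction_kmers(left, right, linker)
    if not kmers:
        return math.inf
    return min(scorer(k) for k in kmers)


def construct_objective(
    order: Sequence[str], linker: str, scorer: Callable[[str], float]
) -> float:
    """Ordering objective: the weakest junction's score, to be maximized.

    +inf for a single peptide (no junctions).
    """
    if len(order) < 2:
        return math.inf
    return min(
        junction_score(order[i], order[i + 1], linker, scorer)
        for i in range(len(order) - 1)
    )


@dataclass
class ChimericConstruct:
    """Assembled polyepitope: ordered peptides joined by linkers.

    ``leader`` names the fusion moiety (CD74), metadata only unless a
    ``leader_sequence`` is supplied, in which case it is prepended (with a
    linker) to the amino-acid sequence. The junction report enumerates every
    junction-spanning 8–11-mer with its predicted affinity.
    """

    peptides: list[str]
    linker: str
    leader: str = "CD74"
    leader_sequence: str = ""
    junctions: list[dict] = field(default_factory=list)
    objective: float = math.inf

    @property
    def sequence(self) -> str:
        parts = ([self.leader_sequence] if self.leader_sequence else []) + list(self.peptides)
        return self.linker.join(parts)


def assemble_construct(
    peptides: Sequence[str],
    linker: str = "GGSGG",
    scorer: Callable[[str], float] = mock_junction_scorer,
    leader: str = "CD74",
    leader_sequence: str = "",
) -> ChimericConstruct:
    """Order peptides to minimize junction immunogenicity and assemble.

    Maximin objective: maximize the weakest junction's score (each junction
    scored by its strongest spanning binder). Up to 6 peptides the search is
    exhaustive over all orders (junction scores are cached per ordered pair,
    so this is cheap) and returns the true optimum; beyond that a greedy
    heuristic starts from the ordered pair whose junction's strongest binder
    is weakest and repeatedly extends the chain at either end with the
    remaining peptide whose new junction score is highest. Ties break on
    lexicographic order (greedy: lexicographic peptide, append before
    prepend).
    """
    peptides = [str(p) for p in peptides]
    if not peptides:
        raise ValueError("need at least one peptide")
    if len(set(peptides)) != len(peptides):
        raise ValueError("peptides must be unique")

    if len(peptides) == 1:
        chain = list(peptides)
    else:
        import itertools

        J = {
            (p, q): junction_score(p, q, linker, scorer)
            for p in peptides
            for q in peptides
            if p != q
        }
        if len(peptides) <= 6:
            chain = list(
                max(
                    itertools.permutations(sorted(peptides)),
                    key=lambda order: (
                        min(J[(order[i], order[i + 1])] for i in range(len(order) - 1)),
                        tuple(-ord(c) for p in order for c in p),  # ties: lexicographic
                    ),
                )
            )
        else:
            best = max(J.values())
            chain = list(min(pq for pq, s in J.items() if s == best))
            remaining = [p for p in peptides if p not in chain]
            while remaining:
                options = []
                for r in remaining:
                    options.append((-J[(chain[-1], r)], r, 0))  # append
                    options.append((-J[(r, chain[0])], r, 1))  # prepend
                neg_score, r, end = min(options)
                if end == 0:
                    chain.append(r)
                else:
                    chain.insert(0, r)
                remaining.remove(r)

    junctions = []
    for i in range(len(chain) - 1):
        left, right = chain[i], chain[i + 1]
        kmers = junction_kmers(left, right, linker)
        junctions.append(
            {
                "left": left,
                "right": right,
                "kmers": [(k, scorer(k)) for k in kmers],
                "min_affinity_nM": min((scorer(k) for k in kmers), default=math.inf),
            }
        )
    return ChimericConstruct(
        peptides=chain,
        linker=linker,
        leader=leader,
        leader_sequence=leader_sequence,
        junctions=junctions,
        objective=construct_objective(chain, linker, scorer),
    )


def construct_to_fasta(construct: ChimericConstruct, path, name: str = "chimeric_construct") -> None:
    """Write the construct's amino-acid sequence as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(
        Seq(construct.sequence),
        id=name,
        description=f"leader={construct.leader} linker={construct.linker} "
        f"n_peptides={len(construct.peptides)}",
    )
    seqio_write([rec], str(path), "fasta")


# --- minimal VCF I/O --------------------------------------------------------


def write_vcf(variants: pd.DataFrame, path, source: str = "livmet") -> None:
    """Write a variant table as a minimal uncompressed VCF 4.2.

    INFO carries GENE, EFF (effect class) and the GERMLINE flag; positions
    are 1-based as in VCF.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##source={source}",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=EFF,Number=1,Type=String,Description="Effect class">',
        '##INFO=<ID=GERMLINE,Number=0,Type=Flag,Description="Present in germline reference">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for _, row in variants.iterrows():
        info = f"GENE={row['gene']};EFF={row['effect']}"
        if bool(row.get("germline", False)):
            info += ";GERMLINE"
        lines.append(
            f"{row['chrom']}\t{int(row['pos'])}\t.\t{row['ref']}\t{row['alt']}\t.\t.\t{info}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a minimal VCF into the variant-table schema (via cyvcf2)."""
    from cyvcf2 import VCF

    rows = []
    for rec in VCF(str(path)):
        rows.append(
            {
                "chrom": rec.CHROM,
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "effect": rec.INFO.get("EFF", "unknown"),
                "gene": rec.INFO.get("GENE", ""),
                "germline": bool(rec.INFO.get("GERMLINE", False)),
            }
        )
    return pd.DataFrame(
        rows, columns=VARIANT_COLUMNS + ["germline"]
    )
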