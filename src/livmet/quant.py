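"""Closed-form quantifications and gene-signature survival stratification.

* Lentiviral vector copy number per diploid genome from droplet digital PCR:
  ``2 * concentration(HIV amplicon) / concentration(normalizer amplicon)``.
* Caliper tumor volume from two orthogonal diameters (x >= y, mm):
  ``x**2 * y / 2``.
* IIT (IFN/IL12-induced T cell) signature scoring: per-sample sum of
  log2-transformed expression over the signature genes, with samples split
  into high/low strata at the 50th percentile of the score.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DdpcrMeasurement:
    """Paired ddPCR concentrations (copies/µL) for vector copy-number calls."""

    concentration_hiv: float
    concentration_normalizer: float

    def __post_init__(self):
        if self.concentration_hiv < 0 or self.concentration_normalizer < 0:
            raise ValueError("ddPCR concentrations must be non-negative")


def lv_copies_per_genome(concentration_hiv: float, concentration_normalizer: float) -> float:
    """Integrated vector copies per diploid genome.

    The normalizer amplicon targets a two-copy genomic locus, hence the
    factor 2. A zero normalizer concentration means the measurement is
    undefined (no amplifiable genomes) and raises.
    """
    m = DdpcrMeasurement(concentration_hiv, concentration_normalizer)
    if m.concentration_normalizer == 0:
        raise ValueError(
            "normalizer concentration is 0: copies per genome undefined"
        )
    return 2.0 * m.concentration_hiv / m.concentration_normalizer


def tumor_volume(diameter_x: float, diameter_y: float) -> float:
    """Caliper tumor volume in mm³ from larger (x) and smaller (y) diameters."""
    if diameter_y < 0:
        raise ValueError("diameters must be non-negative")
    if diameter_y > diameter_x:
        raise ValueError(
            f"diameter_x must be the larger diameter (got x={diameter_x}, y={diameter_y})"
        )
    return diameter_x**2 * diameter_y / 2.0


# --- IIT signature ----------------------------------------------------------

#: Signature members named in the study's text; the full 22-gene list ships as
#: a user-editable file (see :meth:`SignaturePanel.default`).
IIT_CORE_GENES = ("GZMA", "GZMB", "KLRG1", "CD7", "P2RX7", "CCR5")


@dataclass(frozen=True)
class SignaturePanel:
    """Gene list for signature scoring, plus the log2 pseudo-offset for zeros."""

    genes: tuple
    log_offset: float = 1.0

    def __post_init__(self):
        if not self.genes:
            raise ValueError("signature panel is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature panel contains duplicate genes")
        if self.log_offset < 0:
            raise ValueError("log offset must be non-negative")

    @classmethod
    def from_file(cls, path, log_offset: float = 1.0) -> "SignaturePanel":
        """One gene per line; blank lines and ``#`` comments ignored."""
        genes = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.strip().startswith("#")
        ]
        return cls(tuple(genes), log_offset)

    @classmethod
    def default(cls) -> "SignaturePanel":
        """The bundled IIT panel file (core members printed in the study text)."""
        with resources.as_file(
            resources.files("livmet.data").joinpath("iit_genes.txt")
        ) as p:
            return cls.from_file(p)


@dataclass
class ScoreVector:
    """Per-sample signature scores with high/low strata.

    ``strata`` is 'high' when the score is strictly above the 50th percentile
    of all scores, else 'low' (median ties go low). ``missing_genes`` lists
    panel members absent from the expression matrix.
    """

    scores: pd.Series
    strata: pd.Series
    cut: float
    missing_genes: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample": self.scores.index, "score": self.scores.to_numpy(),
             "stratum": self.strata.to_numpy()}
        )


def iit_score(expr: pd.DataFrame, panel: Optional[SignaturePanel] = None) -> ScoreVector:
    """Signature score per sample: sum of log2(expression + offset) over panel genes.

    ``expr`` is samples × genes (samples in the index). Panel genes missing
    from the matrix are reported but tolerated; no panel gene present is an
    error. The high/low split is at the 50th percentile (strictly greater →
    high), so any strictly monotone global rescaling of the expression matrix
    leaves the strata unchanged.
    """
    if panel is None:
        panel = SignaturePanel.default()
    present = [g for g in panel.genes if g in expr.columns]
    missing = [g for g in panel.genes if g not in expr.columns]
    if not present:
        raise ValueError("no signature panel gene present in the expression matrix")
    if missing:
        log.warning("%d signature genes absent from matrix: %s", len(missing), missing)
    sub = expr[present].astype(float)
    if (sub.to_numpy() + panel.log_offset <= 0).any():
        raise ValueError(
            "expression + offset must be positive for log2 scoring "
            f"(offset={panel.log_offset})"
        )
    scores = np.log2(sub + panel.log_offset).sum(axis=1).rename("score")
    cut = float(np.percentile(scores.to_numpy(), 50))
    strata = pd.Series(
        np.where(scores.to_numpy() > cut, "high", "low"), index=scores.index, name="stratum"
    )
    return ScoreVector(scores=scores, strata=strata, cut=cut, missing_genes=missing)


def export_strata(scores: ScoreVector, survival: pd.DataFrame) -> pd.DataFrame:
    """Join scores/strata with a survival table, ready for an external KM/Cox fit.

    ``survival`` needs columns (sample, time, event); the fit itself is
    delegated to standard survival packages. Sample sets must match exactly
    and be free of duplicates.
    """
    for col in ("sample", "time", "event"):
        if col not in survival.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if len(survival) == 0:
        raise ValueError("survival table is empty")
    if survival["sample"].duplicated().any():
        dupes = survival.loc[survival["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicated sample ids in survival table: {dupes}")
    if scores.scores.index.duplicated().any():
        raise ValueError("duplicated sample ids in score vector")
    score_samples = set(scores.scores.index)
    surv_samples = set(survival["sample"])
    if score_samples != surv_samples:
        raise ValueError(
            "sample mismatch between scores and survival table; "
            f"only in scores: {sorted(score_samples - surv_samples)[:5]}, "
            f"only in survival: {sorted(surv_samples - score_samples)[:5]}"
        )
    out = scores.to_frame().merge(survival[["sample", "time", "event"]], on="sample")
    return out
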