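"""Shared domain types.

Coordinates are 0-based, half-open throughout the package; file readers and
writers convert other conventions (GTF) exactly once, at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Promoter biotypes recognised by the annotation model.
BIOTYPES = ("coding", "lncRNA", "pseudogene", "antisense", "divergent")

#: The ten genes reported to be up-regulated in every analysed PBMC cell type
#: by every tested type I IFN subtype ("core ISGs").  Shipped as a constant:
#: the list derives from donor data and is not recomputable from simulations.
CORE_ISGS = (
    "IFI44L", "ISG15", "IFIT3", "XAF1", "MX1",
    "IFI6", "IFIT1", "TRIM22", "MX2", "RSAD2",
)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript group: one quantified transcription unit.

    ``high_confidence`` houses the GENCODE-style flag (MANE Select or
    transcript support level 1/2) that defines the reference set for motif
    score standardisation.  ``tss`` is the first transcribed base (start on
    the + strand, end-1 on the - strand).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str
    high_confidence: bool = False
    group_id: str = ""

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: invalid strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"transcript {self.transcript_id}: invalid interval "
                f"[{self.start}, {self.end})")
        if self.biotype not in BIOTYPES:
            raise ValidationError(
                f"transcript {self.transcript_id}: unknown biotype {self.biotype!r}")
        if not self.group_id:
            object.__setattr__(self, "group_id", self.transcript_id)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def is_coding(self) -> bool:
        return self.biotype == "coding"


@dataclass(frozen=True)
class RegulatoryElement:
    """A promoter-like element (ENCODE cCRE PLS class), 0-based half-open."""

    element_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"element {self.element_id}: invalid interval "
                f"[{self.start}, {self.end})")


@dataclass(frozen=True)
class PromoterRegion:
    """A fixed-length promoter interval serving one or more transcripts.

    ``source`` records whether the region was matched to a regulatory
    element near a TSS or imputed around a TSS.  Identical intervals from
    the same source are merged, so ``transcript_ids`` and ``element_ids``
    may hold several entries.
    """

    chrom: str
    start: int
    end: int
    source: str  # "matched" | "imputed"
    transcript_ids: tuple[str, ...]
    element_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if self.source not in ("matched", "imputed"):
            raise ValidationError(f"invalid promoter source {self.source!r}")
        if not self.transcript_ids:
            raise ValidationError("promoter region with no transcripts")

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.source}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MotifLibrary:
    """PWM count matrices plus a partition of PWMs into motif clusters.

    ``pwms`` maps pwm_id to a 4 x W count matrix over A, C, G, T (rows in
    that order).  ``clusters`` maps cluster_id to the member pwm_ids; every
    PWM belongs to exactly one cluster.
    """

    pwms: dict[str, np.ndarray]
    clusters: dict[str, tuple[str, ...]]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for cid, members in self.clusters.items():
            if not members:
                raise ValidationError(f"cluster {cid} is empty")
            for pid in members:
                if pid not in self.pwms:
                    raise ValidationError(
                        f"cluster {cid} references unknown PWM {pid}")
                if pid in seen:
                    raise ValidationError(
                        f"PWM {pid} in clusters {seen[pid]} and {cid}")
                seen[pid] = cid
        missing = set(self.pwms) - set(seen)
        if missing:
            raise ValidationError(
                f"PWMs not assigned to any cluster: {sorted(missing)}")
        for pid, counts in self.pwms.items():
            counts = np.asarray(counts, dtype=float)
            if counts.ndim != 2 or counts.shape[0] != 4 or counts.shape[1] < 1:
                raise ValidationError(f"PWM {pid}: counts must be 4 x W")
            if (counts < 0).any():
                raise ValidationError(f"PWM {pid}: negative counts")
            if (counts.sum(axis=0) == 0).any():
                raise ValidationError(f"PWM {pid}: all-zero column")
            self.pwms[pid] = counts

    @property
    def pwm_ids(self) -> list[str]:
        return list(self.pwms)

    def cluster_of(self, pwm_id: str) -> str:
        for cid, members in self.clusters.items():
            if pwm_id in members:
                return cid
        raise KeyError(pwm_id)


@dataclass
class GroundTruth:
    """Planted truth for a simulation run.

    true_log2fc is transcripts x treatments (already scaled by potency);
    base_log2fc is the per-transcript effect at potency 1.  programs maps
    cell type -> gene ids induced in that type; core_isgs is the shared
    (all-type) program.  pairs has columns ncrna_id, coding_id, orientation
    (divergent|antisense), regulation (co|anti|none).
    """

    isg_ids: tuple[str, ...]
    core_isgs: tuple[str, ...]
    programs: dict[str, tuple[str, ...]]
    heterogeneous: tuple[str, ...]
    base_log2fc: "pd.Series"
    true_log2fc: "pd.DataFrame"
    pairs: "pd.DataFrame"
    motif_planted: dict[str, bool] = field(default_factory=dict)

    def planted_promoters(self) -> set[str]:
        return {rid for rid, flag in self.motif_planted.items() if flag}


@dataclass(frozen=True)
class DetSet:
    """Differentially expressed features for one contrast and direction."""

    contrast: str
    direction: str  # "up" | "down"
    feature_ids: frozenset[str]
    padj_max: float
    min_abs_log2fc: float

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValidationError(f"invalid direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.feature_ids)


@dataclass(frozen=True)
class GenePair:
    """A non-coding transcript paired with a protein-coding neighbour."""

    ncrna_id: str
    coding_id: str
    orientation: str  # "divergent" | "antisense"

    def __post_init__(self):
        if self.orientation not in ("divergent", "antisense"):
            raise ValidationError(f"invalid orientation {self.orientation!r}")


def transcripts_frame(transcripts) -> pd.DataFrame:
    """Tabulate TranscriptModel records (index = transcript_id)."""
    rows = [
        {
            "transcript_id": t.transcript_id,
            "gene_id": t.gene_id,
            "group_id": t.group_id,
            "chrom": t.chrom,
            "start": t.start,
            "end": t.end,
            "strand": t.strand,
            "tss": t.tss,
            "biotype": t.biotype,
            "high_confidence": t.high_confidence,
        }
        for t in transcripts
    ]
    df = pd.DataFrame(rows)
    return df.set_index("transcript_id", drop=False)
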