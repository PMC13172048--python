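"""Non-coding / coding neighbour pairing and co-regulation classification.

Divergent pairing: a non-coding transcript is paired with the nearest
protein-coding transcript on the opposite strand whose TSS lies within
``max_tss_gap`` bp in head-to-head (diverging) orientation.  Antisense
pairing: opposite-strand transcripts overlapping by at least one base, the
largest overlap winning ties.  For a differentially expressed ncRNA the pair
is classified by the signs of the two members' significant fold changes:
same sign -> co-regulated, opposite -> anticorrelated, partner not a DET ->
unmatched.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .models import DetSet, GenePair, TranscriptModel

MAX_TSS_GAP = 1000

CO = "co-regulated"
ANTI = "anticorrelated"
UNMATCHED = "unmatched-coding-not-DE"


def _diverging(nc: TranscriptModel, coding: TranscriptModel) -> bool:
    """True when the two TSSs point away from each other."""
    if nc.strand == coding.strand:
        return False
    plus, minus = (nc, coding) if nc.strand == "+" else (coding, nc)
    # The + partner transcribes rightward, the - partner leftward: they
    # diverge iff the + TSS does not lie left of the - TSS.
    return plus.tss >= minus.tss


def pair_divergent(
    transcripts: Sequence[TranscriptModel],
    max_tss_gap: int = MAX_TSS_GAP,
) -> list[GenePair]:
    """Pair each non-coding transcript with its nearest head-to-head coding
    neighbour within ``max_tss_gap`` bp (opposite strands only)."""
    coding = [t for t in transcripts if t.is_coding]
    pairs = []
    for nc in transcripts:
        if nc.is_coding:
            continue
        best = None
        best_d = None
        for c in coding:
            if c.chrom != nc.chrom or not _diverging(nc, c):
                continue
            d = abs(c.tss - nc.tss)
            if d <= max_tss_gap and (best_d is None or d < best_d):
                best, best_d = c, d
        if best is not None:
            pairs.append(GenePair(nc.transcript_id, best.transcript_id,
                                  "divergent"))
    return pairs


def pair_antisense(transcripts: Sequence[TranscriptModel]) -> list[GenePair]:
    """Pair non-coding transcripts with opposite-strand overlapping coding
    transcripts; the largest overlap wins."""
    coding = [t for t in transcripts if t.is_coding]
    pairs = []
    for nc in transcripts:
        if nc.is_coding:
            continue
        best = None
        best_ov = 0
        for c in coding:
            if c.chrom != nc.chrom or c.strand == nc.strand:
                continue
            ov = min(nc.end, c.end) - max(nc.start, c.start)
            if ov > best_ov:
                best, best_ov = c, ov
        if best is not None:
            pairs.append(GenePair(nc.transcript_id, best.transcript_id,
                                  "antisense"))
    return pairs


def classify_pairs(
    pairs: Sequence[GenePair],
    de_table: pd.DataFrame,
    up: DetSet,
    down: DetSet,
) -> pd.DataFrame:
    """Classify each pair whose ncRNA is a DET, for one contrast.

    Returns one row per DET ncRNA pair with the two fold changes and the
    classification; pairs whose ncRNA is not differentially expressed are
    omitted (classification is defined only for DET ncRNAs).
    """
    det_nc = up.feature_ids | down.feature_ids
    fc = de_table.set_index("transcript_id")["log2fc"]
    rows = []
    for pair in pairs:
        for fid in (pair.ncrna_id, pair.coding_id):
            if fid not in fc.index:
                raise ValidationError(f"pair references unknown feature {fid!r}")
        if pair.ncrna_id not in det_nc:
            continue
        nc_up = pair.ncrna_id in up.feature_ids
        coding_det = pair.coding_id in det_nc
        if not coding_det:
            cls = UNMATCHED
        else:
            coding_up = pair.coding_id in up.feature_ids
            cls = CO if nc_up == coding_up else ANTI
        rows.append({
            "ncrna_id": pair.ncrna_id,
            "coding_id": pair.coding_id,
            "orientation": pair.orientation,
            "ncrna_log2fc": float(fc[pair.ncrna_id]),
            "coding_log2fc": float(fc[pair.coding_id]),
            "classification": cls,
        })
    return pd.DataFrame(
        rows, columns=["ncrna_id", "coding_id", "orientation",
                       "ncrna_log2fc", "coding_log2fc", "classification"])


def classify_pairs_any_contrast(
    pairs: Sequence[GenePair],
    de_tables: pd.DataFrame,
    det_sets: Mapping[str, tuple[DetSet, DetSet]],
) -> pd.DataFrame:
    """Summarise classifications across contrasts ("regulated by >= 1 IFN").

    A pair enters the summary if its ncRNA is a DET for at least one
    contrast; the classification is taken from the contrast with the largest
    absolute ncRNA fold change among those where the ncRNA is a DET.
    """
    frames = []
    for contrast, (up, down) in det_sets.items():
        table = de_tables[de_tables["contrast"] == contrast]
        cls = classify_pairs(pairs, table, up, down)
        if len(cls):
            cls = cls.assign(contrast=contrast)
            frames.append(cls)
    if not frames:
        return pd.DataFrame(columns=[
            "ncrna_id", "coding_id", "orientation", "ncrna_log2fc",
            "coding_log2fc", "classification", "contrast"])
    allc = pd.concat(frames, ignore_index=True)
    allc["abs_fc"] = allc["ncrna_log2fc"].abs()
    best = allc.sort_values(["abs_fc"], ascending=False) \
        .drop_duplicates(subset=["ncrna_id"], keep="first") \
        .drop(columns="abs_fc") \
        .sort_values("ncrna_id") \
        .reset_index(drop=True)
    return best
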