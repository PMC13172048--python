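"""Promoter assignment.

Each transcript group receives at least one fixed-length (350 bp) promoter
region: regulatory elements (ENCODE PLS class) lying within ``max_gap`` bp of
the TSS are matched — all qualifying elements are retained — and uniformly
extended to the target length around their midpoint; transcripts with no
nearby element get a single promoter imputed symmetrically around the TSS.
Promoter geometry ignores strand, and regions overrunning a chromosome edge
are shifted inward so every region keeps the exact target length.
"""
from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .models import PromoterRegion, RegulatoryElement, TranscriptModel

PROMOTER_LENGTH = 350
MAX_GAP = 500


def tss_element_gap(tss: int, element: RegulatoryElement) -> int:
    """Distance in bp from a TSS to the nearest base of an element.

    Zero when the TSS lies inside the (half-open) element interval.
    """
    if tss < element.start:
        return element.start - tss
    if tss >= element.end:
        return tss - (element.end - 1)
    return 0


def match_pls(
    transcripts: Sequence[TranscriptModel],
    elements: Sequence[RegulatoryElement],
    max_gap: int = MAX_GAP,
) -> list[tuple[str, str]]:
    """Match transcripts to promoter-like elements near their TSS.

    Returns (transcript_id, element_id) pairs for every element whose nearest
    base lies within ``max_gap`` bp of the TSS (boundary inclusive).  The
    relation is many-to-many: a TSS may match several elements and an element
    several TSSs.
    """
    chroms = {t.chrom for t in transcripts}
    by_chrom: dict[str, list[RegulatoryElement]] = defaultdict(list)
    for e in elements:
        by_chrom[e.chrom].append(e)
    unknown = set(by_chrom) - chroms if transcripts else set()
    # Elements on chromosomes absent from the annotation are legal only if the
    # annotation is empty; flag the mismatch early.
    if transcripts and unknown:
        first = next(e for e in elements if e.chrom in unknown)
        raise ValidationError(
            f"element {first.element_id} on unknown chromosome {first.chrom!r}")
    for lst in by_chrom.values():
        lst.sort(key=lambda e: e.start)

    pairs: list[tuple[str, str]] = []
    for t in transcripts:
        for e in by_chrom.get(t.chrom, ()):
            if tss_element_gap(t.tss, e) <= max_gap:
                pairs.append((t.transcript_id, e.element_id))
    return pairs


def extend_region(
    start: int,
    end: int,
    chrom_len: int,
    target_len: int = PROMOTER_LENGTH,
) -> tuple[int, int]:
    """Resize an interval to exactly ``target_len`` around its midpoint.

    Midpoint and half-width use floor division so results are bit-stable;
    intervals overrunning a chromosome edge are shifted inward, preserving
    length.
    """
    if target_len > chrom_len:
        raise ValidationError(
            f"target length {target_len} exceeds chromosome length {chrom_len}")
    if not 0 <= start < end:
        raise ValidationError(f"invalid interval [{start}, {end})")
    midpoint = (start + end) // 2
    new_start = midpoint - target_len // 2
    new_end = new_start + target_len
    if new_start < 0:
        new_start, new_end = 0, target_len
    elif new_end > chrom_len:
        new_start, new_end = chrom_len - target_len, chrom_len
    return new_start, new_end


def impute_promoter(
    transcript: TranscriptModel,
    chrom_len: int,
    target_len: int = PROMOTER_LENGTH,
) -> PromoterRegion:
    """Impute a promoter centred on the TSS (strand-agnostic)."""
    start, end = extend_region(
        transcript.tss, transcript.tss + 1, chrom_len, target_len)
    return PromoterRegion(
        chrom=transcript.chrom,
        start=start,
        end=end,
        source="imputed",
        transcript_ids=(transcript.transcript_id,),
    )


def assign_promoters(
    transcripts: Sequence[TranscriptModel],
    elements: Sequence[RegulatoryElement],
    chrom_lengths: Mapping[str, int],
    max_gap: int = MAX_GAP,
    target_len: int = PROMOTER_LENGTH,
) -> list[PromoterRegion]:
    """Assign every transcript at least one promoter region.

    Matched regions carry all qualifying element ids; a transcript with no
    match within ``max_gap`` gets exactly one imputed region.  Identical
    intervals of the same source are merged, pooling transcript and element
    ids.
    """
    for t in transcripts:
        if t.chrom not in chrom_lengths:
            raise ValidationError(
                f"transcript {t.transcript_id} on unknown chromosome {t.chrom!r}")
    by_id = {e.element_id: e for e in elements}
    matches = match_pls(transcripts, elements, max_gap=max_gap)
    matched_t: dict[str, list[str]] = defaultdict(list)
    for tid, eid in matches:
        matched_t[tid].append(eid)

    # key -> (set of transcript ids, set of element ids)
    merged: dict[tuple[str, int, int, str], tuple[set, set]] = {}

    def add(chrom, start, end, source, tid, eid=None):
        key = (chrom, start, end, source)
        tids, eids = merged.setdefault(key, (set(), set()))
        tids.add(tid)
        if eid is not None:
            eids.add(eid)

    for t in transcripts:
        clen = chrom_lengths[t.chrom]
        eids = matched_t.get(t.transcript_id)
        if eids:
            for eid in eids:
                e = by_id[eid]
                start, end = extend_region(e.start, e.end, clen, target_len)
                add(t.chrom, start, end, "matched", t.transcript_id, eid)
        else:
            r = impute_promoter(t, clen, target_len)
            add(r.chrom, r.start, r.end, "imputed", t.transcript_id)

    regions = [
        PromoterRegion(
            chrom=chrom, start=start, end=end, source=source,
            transcript_ids=tuple(sorted(tids)),
            element_ids=tuple(sorted(eids)),
        )
        for (chrom, start, end, source), (tids, eids) in sorted(merged.items())
    ]
    return regions


def promoters_by_transcript(
    regions: Iterable[PromoterRegion],
) -> dict[str, list[PromoterRegion]]:
    out: dict[str, list[PromoterRegion]] = defaultdict(list)
    for r in regions:
        for tid in r.transcript_ids:
            out[tid].append(r)
    return dict(out)
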