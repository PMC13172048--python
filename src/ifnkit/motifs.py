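"""PWM promoter scanning and motif-cluster scoring.

Every promoter is scored against every PWM by the maximum log-odds score over
all windows on the forward and reverse-complement strand.  Raw scores are
Z-normalised per PWM against a reference set of promoters matched to
high-confidence transcripts; normalised scores are summed within motif
clusters and the sums Z-scored again against the same reference, giving a
per-promoter cluster score.  Each transcript group receives the maximum
cluster score over all of its promoters.

Log-odds use log base 2, a uniform background and a pseudocount of 0.01 per
cell by default; none of these are dictated by the procedure itself and all
are exposed as arguments.  Ambiguous bases (N) contribute the
background-expected log-odds (zero under a uniform background).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import MotifLibrary

ALPHABET = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGTN (case-insensitive) as integer codes 0-4."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _CODE[raw]
    return codes


def reverse_complement(seq: str) -> str:
    table = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(table)[::-1]


def pwm_log_odds(
    counts: np.ndarray,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.01,
) -> np.ndarray:
    """Log2 odds matrix from a 4 x W count matrix.

    entry(b, j) = log2(((counts[b, j] + pc) / (colsum_j + 4 pc)) / bg[b]).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValidationError("PWM counts must be a 4 x W matrix")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    if pseudocount == 0 and (counts.sum(axis=0) == 0).any():
        raise ValidationError("zero column requires a positive pseudocount")
    if pseudocount == 0 and (counts == 0).any():
        # zero cells give -inf log-odds; permitted, but columns must not be empty
        pass
    colsum = counts.sum(axis=0) + 4 * pseudocount
    with np.errstate(divide="ignore"):
        probs = (counts + pseudocount) / colsum
        lo = np.log2(probs / background[:, None])
    return lo


def information_content(counts: np.ndarray, pseudocount: float = 0.01) -> float:
    """Total information content (bits) of a PWM against a uniform background."""
    counts = np.asarray(counts, dtype=float)
    probs = (counts + pseudocount) / (counts.sum(axis=0) + 4 * pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(probs > 0, probs * np.log2(probs), 0.0).sum(axis=0)
    return float((2.0 - h).sum())


def _window_scores(codes: np.ndarray, lo5: np.ndarray) -> np.ndarray:
    w = lo5.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return lo5[windows, np.arange(w)].sum(axis=1)


def scan_max_score(seq: str, log_odds: np.ndarray) -> tuple[float, int, str]:
    """Best log-odds score over all windows on both strands.

    Returns (score, position, strand); the position refers to the window
    start on the given (forward) sequence.  Ties prefer the forward strand,
    then the smallest position.
    """
    log_odds = np.asarray(log_odds, dtype=float)
    w = log_odds.shape[1]
    n = len(seq)
    if n < w:
        raise ValidationError(f"sequence length {n} shorter than motif width {w}")
    # N contributes the background expectation: log-odds 0 under uniform bg.
    lo5 = np.vstack([log_odds, np.zeros((1, w))])
    codes = encode_sequence(seq)
    fwd = _window_scores(codes, lo5)
    rc = _COMPLEMENT[codes][::-1]
    rev = _window_scores(rc, lo5)
    i_f = int(np.argmax(fwd))
    i_r = int(np.argmax(rev))
    if rev[i_r] > fwd[i_f]:
        # map the reverse-complement window start back to forward coordinates
        return float(rev[i_r]), n - w - i_r, "-"
    return float(fwd[i_f]), i_f, "+"


def scan_library(
    sequences: Mapping[str, str],
    library: MotifLibrary,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.01,
) -> pd.DataFrame:
    """Raw max log-odds scores, promoters x PWMs."""
    los = {
        pid: pwm_log_odds(counts, background=background, pseudocount=pseudocount)
        for pid, counts in library.pwms.items()
    }
    data = {
        pid: [scan_max_score(seq, lo)[0] for seq in sequences.values()]
        for pid, lo in los.items()
    }
    return pd.DataFrame(data, index=list(sequences))


def reference_standardise(
    raw: pd.DataFrame,
    reference_ids: Iterable[str],
    ddof: int = 1,
) -> pd.DataFrame:
    """Z-score each column against the reference promoters.

    The reference is the promoter set matched to high-confidence transcripts;
    the sample SD (denominator n - 1) is the default.
    """
    ref = list(reference_ids)
    if len(ref) < 2:
        raise ValidationError("reference set must contain at least 2 promoters")
    missing = [r for r in ref if r not in raw.index]
    if missing:
        raise ValidationError(f"reference promoters missing from scores: {missing[:5]}")
    sub = raw.loc[ref]
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=ddof)
    bad = sd[sd == 0]
    if len(bad):
        raise ValidationError(
            f"zero reference variance for: {', '.join(map(str, bad.index[:5]))}")
    return (raw - mean) / sd


@dataclass
class PromoterScoreTable:
    """Raw, per-PWM z, and per-cluster z scores for every promoter."""

    raw: pd.DataFrame
    z: pd.DataFrame
    cluster_z: pd.DataFrame
    reference_ids: tuple[str, ...]


def cluster_scores(
    z: pd.DataFrame,
    clusters: Mapping[str, Sequence[str]],
    reference_ids: Iterable[str],
    ddof: int = 1,
) -> pd.DataFrame:
    """Sum member PWM z-scores per cluster, then re-standardise the sums."""
    sums = {}
    for cid, members in clusters.items():
        members = list(members)
        if not members:
            raise ValidationError(f"cluster {cid} is empty")
        missing = [m for m in members if m not in z.columns]
        if missing:
            raise ValidationError(f"cluster {cid} references unscored PWMs {missing}")
        sums[cid] = z[members].sum(axis=1)
    return reference_standardise(pd.DataFrame(sums), reference_ids, ddof=ddof)


def transcript_cluster_scores(
    cluster_z: pd.DataFrame,
    promoter_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Per transcript group, the max cluster score over its promoters.

    ``promoter_map`` maps transcript_id -> promoter region ids.
    """
    rows = {}
    for tid, rids in promoter_map.items():
        if not rids:
            raise ValidationError(f"transcript {tid} has no promoter")
        missing = [r for r in rids if r not in cluster_z.index]
        if missing:
            raise ValidationError(
                f"transcript {tid}: unscored promoters {missing[:3]}")
        rows[tid] = cluster_z.loc[list(rids)].max(axis=0)
    return pd.DataFrame(rows).T


def score_promoters(
    sequences: Mapping[str, str],
    library: MotifLibrary,
    reference_ids: Iterable[str],
    background: Sequence[float] | None = None,
    pseudocount: float = 0.01,
    ddof: int = 1,
) -> PromoterScoreTable:
    """Full scoring stage: scan, standardise, aggregate into cluster scores."""
    reference_ids = tuple(reference_ids)
    raw = scan_library(sequences, library,
                       background=background, pseudocount=pseudocount)
    z = reference_standardise(raw, reference_ids, ddof=ddof)
    cz = cluster_scores(z, library.clusters, reference_ids, ddof=ddof)
    return PromoterScoreTable(raw=raw, z=z, cluster_z=cz,
                              reference_ids=reference_ids)
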