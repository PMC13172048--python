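"""File formats.

One internal coordinate convention (0-based, half-open) everywhere; GTF
(1-based, closed) is converted exactly once, here.  TSV dialects are
tab-separated with a mandatory header row, UTF-8, "NA" for missing values.
Readers reject malformed input with the offending line in the message rather
than silently coercing.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .models import (MotifLibrary, PromoterRegion, RegulatoryElement,
                     TranscriptModel)

_GTF_BIOTYPE = {
    "coding": "protein_coding",
    "lncRNA": "lncRNA",
    "pseudogene": "pseudogene",
    "antisense": "antisense",
    "divergent": "divergent",
}
_GTF_BIOTYPE_BACK = {v: k for k, v in _GTF_BIOTYPE.items()}

ANNOTATION_TSV_COLUMNS = [
    "transcript_id", "gene_id", "group_id", "chrom", "start", "end",
    "strand", "biotype", "high_confidence",
]


# ------------------------------------------------------------------- FASTA

def write_fasta(path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    """Load FASTA into a dict; alphabet normalised to upper-case ACGTN."""
    from Bio import SeqIO

    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise FormatError(
                f"{path}: sequence {rec.id} contains invalid characters "
                f"{sorted(bad)}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"{path}: no FASTA records")
    return out


def extract_sequences(
    genome: Mapping[str, str],
    regions: Sequence[PromoterRegion],
) -> dict[str, str]:
    out = {}
    for r in regions:
        if r.chrom not in genome:
            raise FormatError(f"region {r.region_id}: unknown chromosome")
        out[r.region_id] = genome[r.chrom][r.start:r.end]
    return out


# -------------------------------------------------------------- annotation

def write_annotation_gtf(path, transcripts: Sequence[TranscriptModel]) -> None:
    """GTF (1-based, closed): one transcript and one exon line per group."""
    with open(path, "w") as fh:
        for t in transcripts:
            tsl = "1" if t.high_confidence else "5"
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'group_id "{t.group_id}"; '
                f'gene_biotype "{_GTF_BIOTYPE[t.biotype]}"; '
                f'transcript_support_level "{tsl}";'
            )
            if t.high_confidence:
                attrs += ' tag "MANE_Select";'
            for feature in ("transcript", "exon"):
                fh.write("\t".join([
                    t.chrom, "ifnkit", feature, str(t.start + 1), str(t.end),
                    ".", t.strand, ".", attrs]) + "\n")


def _parse_gtf_attributes(raw: str, lineno: int, path) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise FormatError(f"{path}:{lineno}: malformed attribute {chunk!r}")
        key, value = chunk.split(" ", 1)
        value = value.strip().strip('"')
        if key == "tag":
            attrs.setdefault("tags", []).append(value)  # type: ignore[arg-type]
        else:
            attrs[key] = value
    return attrs


def read_annotation_gtf(path) -> list[TranscriptModel]:
    """Parse transcripts from GTF; TSS from exon extent, strand-aware.

    High confidence is a MANE_Select tag or transcript support level 1/2.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}")
            chrom, _src, feature, start, end, _score, strand, _frame, raw = fields
            if feature not in ("transcript", "exon"):
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            attrs = _parse_gtf_attributes(raw, lineno, path)
            tid = attrs.get("transcript_id")
            if not tid:
                raise FormatError(f"{path}:{lineno}: missing transcript_id")
            biotype = attrs.get("gene_biotype", "protein_coding")
            if biotype not in _GTF_BIOTYPE_BACK:
                raise FormatError(
                    f"{path}:{lineno}: unknown gene_biotype {biotype!r}")
            tsl = attrs.get("transcript_support_level", "NA")
            hc = ("MANE_Select" in attrs.get("tags", [])) or tsl in ("1", "2")
            meta.setdefault(tid, {
                "gene_id": attrs.get("gene_id", tid),
                "group_id": attrs.get("group_id", tid),
                "chrom": chrom, "strand": strand,
                "biotype": _GTF_BIOTYPE_BACK[biotype],
                "high_confidence": hc,
                "span": (start0, end0),
            })
            if feature == "exon":
                exons.setdefault(tid, []).append((start0, end0))
    out = []
    for tid, m in meta.items():
        spans = exons.get(tid, [m["span"]])
        start = min(s for s, _ in spans)
        end = max(e for _, e in spans)
        out.append(TranscriptModel(
            transcript_id=tid, gene_id=m["gene_id"], group_id=m["group_id"],
            chrom=m["chrom"], start=start, end=end, strand=m["strand"],
            biotype=m["biotype"], high_confidence=m["high_confidence"]))
    return out


def write_annotation_tsv(path, transcripts: Sequence[TranscriptModel]) -> None:
    rows = [{
        "transcript_id": t.transcript_id, "gene_id": t.gene_id,
        "group_id": t.group_id, "chrom": t.chrom, "start": t.start,
        "end": t.end, "strand": t.strand, "biotype": t.biotype,
        "high_confidence": str(t.high_confidence),
    } for t in transcripts]
    pd.DataFrame(rows, columns=ANNOTATION_TSV_COLUMNS).to_csv(
        path, sep="\t", index=False)


def read_annotation_tsv(path) -> list[TranscriptModel]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(ANNOTATION_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(TranscriptModel(
                transcript_id=row["transcript_id"], gene_id=row["gene_id"],
                group_id=row["group_id"], chrom=row["chrom"],
                start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"], biotype=row["biotype"],
                high_confidence=row["high_confidence"] == "True"))
        except (ValueError, Exception) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    dupes = df["transcript_id"].duplicated()
    if dupes.any():
        raise FormatError(
            f"{path}: duplicate transcript ids "
            f"{df.loc[dupes, 'transcript_id'].tolist()[:5]}")
    return out


def read_annotation(path, dialect: str | None = None) -> list[TranscriptModel]:
    path = Path(path)
    if dialect is None:
        dialect = "gtf" if path.suffix.lower() in (".gtf", ".gff") else "tsv"
    if dialect == "gtf":
        return read_annotation_gtf(path)
    if dialect == "tsv":
        return read_annotation_tsv(path)
    raise FormatError(f"unknown annotation dialect {dialect!r}")


# --------------------------------------------------------------------- BED

def write_bed(path, elements: Sequence[RegulatoryElement]) -> None:
    with open(path, "w") as fh:
        for e in elements:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.element_id}\n")


def read_bed(path) -> list[RegulatoryElement]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED fields")
            chrom, start, end = fields[:3]
            name = fields[3] if len(fields) > 3 else f"element{lineno}"
            try:
                s, e = int(start), int(end)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if s >= e:
                raise FormatError(f"{path}:{lineno}: start >= end")
            out.append(RegulatoryElement(element_id=name, chrom=chrom,
                                         start=s, end=e))
    return out


def write_promoters_bed(path, regions: Sequence[PromoterRegion]) -> None:
    """BED6: name = comma-joined transcript ids + source, score 0, strand '.'."""
    with open(path, "w") as fh:
        for r in regions:
            name = ",".join(r.transcript_ids) + f"|{r.source}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t.\n")


def read_promoters_bed(path) -> list[PromoterRegion]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected BED6 promoters")
            chrom, start, end, name = fields[:4]
            if "|" not in name:
                raise FormatError(f"{path}:{lineno}: promoter name lacks source")
            tids, source = name.rsplit("|", 1)
            out.append(PromoterRegion(
                chrom=chrom, start=int(start), end=int(end), source=source,
                transcript_ids=tuple(tids.split(","))))
    return out


# ---------------------------------------------------------------- PWM files

def write_jaspar_pfm(path, library: MotifLibrary) -> None:
    """JASPAR PFM text: '>ID name' then four bracketed count rows."""
    with open(path, "w") as fh:
        for pid, counts in library.pwms.items():
            name = library.names.get(pid, pid)
            fh.write(f">{pid} {name}\n")
            for b, row in zip("ACGT", counts):
                cells = " ".join(f"{v:10.2f}" for v in row)
                fh.write(f"{b} [ {cells} ]\n")


def read_jaspar_pfm(path) -> tuple[dict[str, np.ndarray], dict[str, str]]:
    """Parse JASPAR PFM text via Bio.motifs; returns (counts, names)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "jaspar")
            records = list(records)
        except Exception as exc:
            raise FormatError(f"{path}: not valid JASPAR PFM text: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no motifs found")
    pwms, names = {}, {}
    for m in records:
        pid = m.matrix_id or m.name
        if pid in pwms:
            raise FormatError(f"{path}: duplicate PWM id {pid!r}")
        pwms[pid] = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        names[pid] = m.name or pid
    return pwms, names


def write_cluster_map(path, library: MotifLibrary) -> None:
    rows = [{"pwm_id": pid, "cluster_id": cid}
            for cid, members in library.clusters.items() for pid in members]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cluster_map(path) -> dict[str, tuple[str, ...]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pwm_id", "cluster_id"} <= set(df.columns):
        raise FormatError(f"{path}: cluster map needs pwm_id and cluster_id")
    if df["pwm_id"].duplicated().any():
        raise FormatError(f"{path}: PWM assigned to multiple clusters")
    return {cid: tuple(sub["pwm_id"])
            for cid, sub in df.groupby("cluster_id", sort=True)}


def read_motif_library(pfm_path, cluster_path) -> MotifLibrary:
    pwms, names = read_jaspar_pfm(pfm_path)
    clusters = read_cluster_map(cluster_path)
    return MotifLibrary(pwms=pwms, clusters=clusters, names=names)


# -------------------------------------------------------------- TSV tables

def write_matrix_tsv(path, df: pd.DataFrame, index_name: str = "transcript_id") -> None:
    df = df.copy()
    df.index.name = index_name
    df.to_csv(path, sep="\t", na_rep="NA")


def read_matrix_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicate row ids")
    return df


DE_COLUMNS = ["transcript_id", "log2fc", "pvalue", "padj", "contrast",
              "feature_class"]


def write_de_tables(path, de: pd.DataFrame) -> None:
    cols = [c for c in DE_COLUMNS if c in de.columns]
    de[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_de_tables(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"transcript_id", "log2fc", "padj", "contrast"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: DE table missing columns {sorted(missing)}")
    if df.duplicated(subset=["transcript_id", "contrast"]).any():
        raise FormatError(f"{path}: duplicate (transcript, contrast) rows")
    return df


# --------------------------------------------------------------------- MTX

def write_mtx_bundle(outdir, adata) -> None:
    """matrix.mtx (genes x cells) + features/barcodes/cells TSVs."""
    from scipy import io as sio, sparse

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X
    if not sparse.issparse(X):
        X = sparse.csr_matrix(X)
    sio.mmwrite(str(outdir / "matrix.mtx"), X.T.astype(np.int64).tocoo())
    (outdir / "features.tsv").write_text(
        "".join(f"{g}\n" for g in adata.var_names))
    (outdir / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in adata.obs_names))
    cells = adata.obs.reset_index().rename(columns={"index": "barcode"})
    if "barcode" not in cells.columns:
        cells.insert(0, "barcode", adata.obs_names)
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def read_mtx_bundle(indir):
    """Read the MTX bundle back into an AnnData (cells x genes)."""
    import anndata as ad
    from scipy import io as sio, sparse

    indir = Path(indir)
    X = sio.mmread(str(indir / "matrix.mtx"))
    features = (indir / "features.tsv").read_text().split()
    barcodes = (indir / "barcodes.tsv").read_text().split()
    X = sparse.csr_matrix(X.T)
    if X.shape != (len(barcodes), len(features)):
        raise FormatError(
            f"{indir}: matrix shape {X.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features")
    cells = pd.read_csv(indir / "cells.tsv", sep="\t", dtype=str)
    if "barcode" not in cells.columns:
        raise FormatError(f"{indir}/cells.tsv: missing barcode column")
    cells = cells.set_index("barcode")
    if set(cells.index) != set(barcodes):
        raise FormatError(f"{indir}: cells.tsv barcodes do not match barcodes.tsv")
    obs = cells.loc[barcodes]
    var = pd.DataFrame(index=pd.Index(features, name="transcript_id"))
    return ad.AnnData(X=X, obs=obs, var=var)


# -------------------------------------------------------------------- truth

def write_truth_json(path, truth) -> None:
    payload = {
        "isg_ids": list(truth.isg_ids),
        "core_isgs": list(truth.core_isgs),
        "programs": {k: list(v) for k, v in truth.programs.items()},
        "heterogeneous": list(truth.heterogeneous),
        "base_log2fc": truth.base_log2fc.round(6).to_dict(),
        "pairs": truth.pairs.to_dict(orient="records"),
        "motif_planted": truth.motif_planted,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
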