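"""Differential-expression set algebra and single-cell ISG procedures.

Bulk side: robust-expression filtering (every sample of at least one
condition has >= 20 assigned reads), DET thresholds (adjusted p <= 0.05 and
|log2FC| >= 0.585, i.e. 1.5-fold), and the universal / subtype-specific set
algebra across treatments.

Single-cell side: log-normalisation (counts per 10k, natural log1p),
Wilcoxon rank-sum differential expression with Seurat-style detection and
fold-change pre-filters, cell-type eligibility (average > 50 cells per
sample), the core-ISG intersection over every eligible cell type x
treatment, lineage Venn partitions, and the per-cell ISG score (sum of
log-normalised expression over a gene set).
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .association import mann_whitney_u, bh_adjust
from .errors import ValidationError
from .models import DetSet

PADJ_MAX = 0.05
MIN_ABS_LOG2FC = 0.585  # log2(1.5), rounded as in common usage
MIN_READS = 20
MIN_PCT = 0.10
LOGFC_THRESHOLD = 0.25
MIN_AVG_CELLS = 50.0
SC_SCALE = 1e4


# ---------------------------------------------------------------- bulk sets

def filter_robust_bulk(
    counts: pd.DataFrame,
    conditions: Mapping[str, str] | pd.Series,
    min_reads: int = MIN_READS,
) -> list[str]:
    """Features where all samples of >= 1 condition have >= min_reads counts."""
    conditions = pd.Series(conditions)
    unlabelled = [c for c in counts.columns if c not in conditions.index]
    if unlabelled:
        raise ValidationError(f"unlabelled samples: {unlabelled[:5]}")
    keep = np.zeros(len(counts), dtype=bool)
    for cond in conditions.unique():
        cols = conditions.index[conditions == cond]
        cols = [c for c in cols if c in counts.columns]
        if cols:
            keep |= (counts[cols] >= min_reads).all(axis=1).to_numpy()
    return counts.index[keep].tolist()


def det_filter(
    table: pd.DataFrame,
    contrast: str | None = None,
    padj_max: float = PADJ_MAX,
    min_abs_log2fc: float = MIN_ABS_LOG2FC,
) -> tuple[DetSet, DetSet]:
    """Split a differential table into up- and down-regulated DET sets.

    Boundaries are inclusive (padj <= padj_max, |log2FC| >= min_abs_log2fc).
    Rows with missing padj are excluded and reported via a warning.
    """
    required = {"transcript_id", "log2fc", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"differential table missing columns {sorted(missing)}")
    df = table
    if contrast is not None:
        df = df[df["contrast"] == contrast]
    elif "contrast" in df.columns:
        labels = df["contrast"].unique()
        if len(labels) > 1:
            raise ValidationError(
                "table holds several contrasts; pass the contrast to filter")
        contrast = labels[0] if len(labels) else ""
    na = df["padj"].isna()
    if na.any():
        warnings.warn(f"{int(na.sum())} features dropped for missing padj")
        df = df[~na]
    sig = df["padj"] <= padj_max
    up = frozenset(df.loc[sig & (df["log2fc"] >= min_abs_log2fc), "transcript_id"])
    down = frozenset(df.loc[sig & (df["log2fc"] <= -min_abs_log2fc), "transcript_id"])
    mk = lambda direction, ids: DetSet(
        contrast=contrast or "", direction=direction, feature_ids=ids,
        padj_max=padj_max, min_abs_log2fc=min_abs_log2fc)
    return mk("up", up), mk("down", down)


def universal_sets(det_sets: Sequence[DetSet]) -> frozenset[str]:
    """Features significant in the same direction for every treatment."""
    if not det_sets:
        raise ValidationError("need at least one DET set")
    directions = {s.direction for s in det_sets}
    if len(directions) > 1:
        raise ValidationError("DET sets mix directions")
    out = frozenset(det_sets[0].feature_ids)
    for s in det_sets[1:]:
        out &= s.feature_ids
    return out


def subtype_specific_sets(det_sets: Sequence[DetSet]) -> dict[str, frozenset[str]]:
    """Features significant for exactly one treatment (per direction)."""
    if not det_sets:
        raise ValidationError("need at least one DET set")
    out = {}
    for s in det_sets:
        others = frozenset().union(
            *(o.feature_ids for o in det_sets if o is not s)) if len(det_sets) > 1 \
            else frozenset()
        out[s.contrast] = frozenset(s.feature_ids) - others
    return out


# --------------------------------------------------------------- single cell

def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def sc_log_normalise(counts, barcodes: Sequence[str] | None = None) -> np.ndarray:
    """ln(1 + 1e4 * count / cell_total), cells x genes."""
    X = _dense(counts).astype(float)
    totals = X.sum(axis=1)
    zero = totals == 0
    if zero.any():
        which = (list(np.asarray(barcodes)[zero][:5]) if barcodes is not None
                 else np.nonzero(zero)[0][:5].tolist())
        raise ValidationError(f"all-zero cells: {which}")
    return np.log1p(SC_SCALE * X / totals[:, None])


def sc_fold_change(
    norm_a: np.ndarray,
    norm_b: np.ndarray,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """log2 ratio of mean back-transformed expression (+pseudocount), a vs b."""
    mean_a = np.expm1(norm_a).mean(axis=0)
    mean_b = np.expm1(norm_b).mean(axis=0)
    return np.log2((mean_a + pseudocount) / (mean_b + pseudocount))


def sc_wilcoxon_de(
    normalised: np.ndarray,
    genes: Sequence[str],
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    counts=None,
    min_pct: float = MIN_PCT,
    logfc_threshold: float = LOGFC_THRESHOLD,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Wilcoxon rank-sum DE between two cell groups (group a vs group b).

    A gene is tested iff it is detected (count > 0) in >= min_pct of the
    cells of at least one group and its |log2FC| (ratio of mean
    back-transformed expression) is >= logfc_threshold.  P-values come from
    the same rank-sum routine used for bulk association; adjustment is
    Bonferroni over the tested genes by default (BH by flag).
    """
    normalised = np.asarray(normalised)
    cells_a = np.asarray(cells_a)
    cells_b = np.asarray(cells_b)
    if cells_a.size == 0 or cells_b.size == 0:
        raise ValidationError("both cell groups must be non-empty")
    if correction not in ("bonferroni", "bh"):
        raise ValidationError(f"unknown correction {correction!r}")
    det_source = _dense(counts) if counts is not None else normalised
    xa, xb = normalised[cells_a], normalised[cells_b]
    pct_a = (det_source[cells_a] > 0).mean(axis=0)
    pct_b = (det_source[cells_b] > 0).mean(axis=0)
    fc = sc_fold_change(xa, xb)
    testable = ((pct_a >= min_pct) | (pct_b >= min_pct)) & \
        (np.abs(fc) >= logfc_threshold)
    idx = np.nonzero(testable)[0]
    if idx.size:
        if min(xa.shape[0], xb.shape[0]) <= 8:
            pvals = np.array([
                mann_whitney_u(xa[:, j], xb[:, j])[1] for j in idx])
        else:
            res = stats.mannwhitneyu(
                xa[:, idx], xb[:, idx], alternative="two-sided",
                method="asymptotic", axis=0)
            pvals = np.minimum(np.atleast_1d(res.pvalue), 1.0)
        if correction == "bonferroni":
            padj = np.minimum(pvals * idx.size, 1.0)
        else:
            padj = bh_adjust(pvals)
    else:
        pvals = padj = np.array([])
    genes = np.asarray(genes)
    return pd.DataFrame({
        "transcript_id": genes[idx],
        "log2fc": fc[idx],
        "pct_a": pct_a[idx],
        "pct_b": pct_b[idx],
        "pvalue": pvals,
        "padj": padj,
    }).reset_index(drop=True)


def eligible_cell_types(
    cell_meta: pd.DataFrame,
    min_avg: float = MIN_AVG_CELLS,
    sample_col: str = "treatment",
    type_col: str = "cell_type",
) -> list[str]:
    """Cell types averaging strictly more than min_avg cells per sample.

    The denominator is the number of samples in the experiment, including
    samples where the type was not captured.
    """
    for col in (sample_col, type_col):
        if col not in cell_meta.columns:
            raise ValidationError(f"cell metadata missing column {col!r}")
        if cell_meta[col].isna().any():
            raise ValidationError(f"cells with missing {col!r}")
    n_samples = cell_meta[sample_col].nunique()
    totals = cell_meta.groupby(type_col, observed=True).size()
    return sorted(totals.index[(totals / n_samples) > min_avg].tolist())


def core_isg_set(
    de_tables: Mapping[tuple[str, str], pd.DataFrame],
    padj_max: float = PADJ_MAX,
    min_fold: float = 1.5,
) -> frozenset[str]:
    """Genes up-regulated in every (cell type, treatment) table.

    Significance is strict (padj < padj_max) and the induction threshold is
    applied on the log2 scale (log2fc >= log2(min_fold)).
    """
    if not de_tables:
        raise ValidationError("no DE tables supplied")
    min_l2 = np.log2(min_fold)
    core: frozenset[str] | None = None
    for key, table in de_tables.items():
        if table is None:
            raise ValidationError(f"missing DE table for {key}")
        up = frozenset(table.loc[
            (table["padj"] < padj_max) & (table["log2fc"] >= min_l2),
            "transcript_id"])
        core = up if core is None else core & up
    return core


def lineage_venn(
    set_a: Iterable[str],
    set_b: Iterable[str],
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """Two-set Venn partition: (only_a, both, only_b)."""
    a, b = frozenset(set_a), frozenset(set_b)
    return a - b, a & b, b - a


def isg_score(
    normalised: np.ndarray,
    genes: Sequence[str],
    gene_set: Iterable[str],
) -> pd.Series:
    """Per-cell ISG score: sum of log-normalised expression over a gene set.

    Genes absent from the matrix are reported via a warning and skipped; an
    empty effective set is an error.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValidationError("empty gene set")
    index = {g: j for j, g in enumerate(genes)}
    present = [g for g in gene_set if g in index]
    missing = [g for g in gene_set if g not in index]
    if missing:
        warnings.warn(f"{len(missing)} gene(s) missing from matrix: {missing[:5]}")
    if not present:
        raise ValidationError("no gene of the set is present in the matrix")
    cols = [index[g] for g in present]
    values = np.asarray(normalised)[:, cols].sum(axis=1)
    return pd.Series(values, name="isg_score")
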