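"""Motif-cluster / fold-change association testing.

For each motif cluster and each IFN-vs-mock contrast, transcripts with a high
cluster score ("likely regulated", z >= 2) are compared against transcripts
with a low score ("likely unregulated", z <= -1) on their observed log2 fold
changes with a Mann-Whitney U test, restricted to robustly expressed
transcripts (median TPM >= 10 in either arm of the contrast).  P-values are
Benjamini-Hochberg adjusted over the full cluster x treatment grid by
default (a per-treatment pool is available).
"""
from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, ValidationError

HI_Z = 2.0
LO_Z = -1.0
MIN_TPM = 10.0


def partition_transcripts(
    scores: pd.Series,
    hi: float = HI_Z,
    lo: float = LO_Z,
) -> tuple[list[str], list[str]]:
    """Split transcripts into likely-regulated (z >= hi) and likely-unregulated
    (z <= lo) sets; both boundaries are inclusive and the band between them
    belongs to neither set."""
    if hi <= lo:
        raise ConfigError(f"hi ({hi}) must exceed lo ({lo})")
    values = pd.Series(scores, dtype=float)
    if not np.isfinite(values.to_numpy()).all():
        raise ValidationError("non-finite motif scores in partition")
    regulated = values.index[values >= hi].tolist()
    unregulated = values.index[values <= lo].tolist()
    return regulated, unregulated


def filter_expressed(
    tpm: pd.DataFrame,
    treated_samples: Sequence[str],
    mock_samples: Sequence[str],
    threshold: float = MIN_TPM,
) -> list[str]:
    """Transcripts with median TPM >= threshold in mock or treated samples."""
    if len(treated_samples) == 0 or len(mock_samples) == 0:
        raise ValidationError("both sample arms must be non-empty")
    for col in list(treated_samples) + list(mock_samples):
        if col not in tpm.columns:
            raise ValidationError(f"sample {col!r} missing from TPM matrix")
    med_mock = tpm[list(mock_samples)].median(axis=1)
    med_trt = tpm[list(treated_samples)].median(axis=1)
    keep = (med_mock >= threshold) | (med_trt >= threshold)
    return tpm.index[keep].tolist()


def mann_whitney_u(
    values_a: Sequence[float],
    values_b: Sequence[float],
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test (U for the first sample, p-value).

    Exact enumeration when both samples have <= 8 observations and no ties;
    otherwise a normal approximation with tie and continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("Mann-Whitney samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def samples_by_treatment(columns: Iterable[str]) -> dict[str, list[str]]:
    """Group 'donor{i}_{treatment}' sample ids by treatment."""
    groups: dict[str, list[str]] = {}
    for col in columns:
        if "_" not in col:
            raise ValidationError(
                f"sample id {col!r} not of the form 'donor_treatment'")
        treatment = col.split("_", 1)[1]
        groups.setdefault(treatment, []).append(col)
    return groups


def run_motif_association(
    de_tables: pd.DataFrame,
    tpm: pd.DataFrame,
    transcript_scores: pd.DataFrame,
    hi: float = HI_Z,
    lo: float = LO_Z,
    min_tpm: float = MIN_TPM,
    bh_pool: str = "global",
    mock_label: str = "mock",
) -> pd.DataFrame:
    """Associate every motif cluster with fold changes in every contrast.

    ``de_tables`` is a long table with columns transcript_id, log2fc, padj,
    contrast (the treatment label); ``transcript_scores`` is transcripts x
    clusters.  Tests with an empty arm are emitted with NA statistics and are
    not counted in the BH pool.
    """
    if bh_pool not in ("global", "per-treatment"):
        raise ConfigError(f"unknown BH pool {bh_pool!r}")
    groups = samples_by_treatment(tpm.columns)
    if mock_label not in groups:
        raise ValidationError(f"no {mock_label!r} samples in TPM matrix")
    treatments = [c for c in de_tables["contrast"].unique() if c != mock_label]

    rows = []
    for treatment in treatments:
        if treatment not in groups:
            raise ValidationError(f"no TPM samples for treatment {treatment!r}")
        expressed = filter_expressed(
            tpm, groups[treatment], groups[mock_label], threshold=min_tpm)
        de = de_tables[de_tables["contrast"] == treatment].set_index("transcript_id")
        ids = [i for i in expressed if i in de.index and i in transcript_scores.index]
        if not ids:
            warnings.warn(
                f"no transcripts pass the expression filter for {treatment}")
            continue
        fc = de.loc[ids, "log2fc"].astype(float)
        for cluster in transcript_scores.columns:
            reg, unreg = partition_transcripts(
                transcript_scores.loc[ids, cluster], hi=hi, lo=lo)
            row = {
                "cluster_id": cluster,
                "treatment": treatment,
                "n_regulated": len(reg),
                "n_unregulated": len(unreg),
                "U": np.nan,
                "p": np.nan,
                "padj": np.nan,
                "median_fc_regulated": np.nan,
                "median_fc_unregulated": np.nan,
            }
            if reg and unreg:
                u, p = mann_whitney_u(fc.loc[reg], fc.loc[unreg])
                row.update(
                    U=u, p=p,
                    median_fc_regulated=float(fc.loc[reg].median()),
                    median_fc_unregulated=float(fc.loc[unreg].median()),
                )
            rows.append(row)

    result = pd.DataFrame(rows)
    if result.empty:
        return result
    if bh_pool == "global":
        valid = result["p"].notna()
        if valid.any():
            result.loc[valid, "padj"] = bh_adjust(result.loc[valid, "p"])
    else:
        for treatment in result["treatment"].unique():
            mask = (result["treatment"] == treatment) & result["p"].notna()
            if mask.any():
                result.loc[mask, "padj"] = bh_adjust(result.loc[mask, "p"])
    return result
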