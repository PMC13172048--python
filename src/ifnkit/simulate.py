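"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a type I IFN stimulation study of
PBMCs: five IFN treatments plus mock across three donors with a fixed
potency ordering (IFN-beta strongest), an interferon-stimulated gene
programme whose promoters carry a planted ISRE-like motif, several cell
types sharing a small universal ("core") programme plus type-specific
genes, bimodally induced heterogeneous genes, and divergent/antisense
non-coding transcripts co- or anti-regulated with coding neighbours.

All randomness flows from ``config.seed`` through named sub-streams, one per
artifact, so identical configs give byte-identical outputs.

The generator emits observed differential-expression tables directly (a
normal model around the true log2 fold change with known noise SD) rather
than fitting a count model: the fitting stage of the emulated workflow is
upstream of this package's scope.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import CapacityError, ValidationError
from .models import (GroundTruth, MotifLibrary, PromoterRegion,
                     RegulatoryElement, TranscriptModel)
from .motifs import scan_max_score, pwm_log_odds
from .promoters import assign_promoters, promoters_by_transcript
from .association import bh_adjust

# Planted ISRE-like consensus: a tandem T/C-rich direct repeat (TTTC x2 with
# a 2-bp spacer), width 13.  Only its recoverability matters; the informative
# columns carry probability 0.85 for the consensus base.
ISRE_CONSENSUS = "AGTTTCNNTTTCC"
ISRE_PWM_ID = "PWM_ISRE"
ISRE_CLUSTER_ID = "ISRE"

_BASES = "ACGT"

# rng sub-stream tags (spawned as default_rng([seed, tag]))
_STREAM_ANNOTATION = 0
_STREAM_LIBRARY = 1
_STREAM_PLANT = 2
_STREAM_BULK = 3
_STREAM_CELLS = 4


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream])


def decode_genome(codes: np.ndarray) -> str:
    return codes.tobytes().decode("ascii")


@dataclass
class AnnotationBundle:
    """Genome plus annotation as produced by generate_annotation."""

    genome: np.ndarray               # uint8 ASCII codes, mutable for planting
    transcripts: list[TranscriptModel]
    elements: list[RegulatoryElement]
    pairs: pd.DataFrame              # ncrna_id, coding_id, orientation
    chrom_name: str
    chrom_length: int

    def sequence(self, start: int, end: int) -> str:
        return self.genome[start:end].tobytes().decode("ascii")


def generate_annotation(config: SimulationConfig) -> AnnotationBundle:
    """Random genome, gene loci, PLS elements and designed ncRNA pairs.

    Gene bodies do not overlap except for the designed divergent
    (head-to-head TSSs within 1 kb on opposite strands) and antisense
    (opposite-strand overlapping) pairs.  A ``pls_frac`` fraction of
    transcripts gets a promoter-like element within 500 bp of its TSS; the
    rest get none, forcing promoter imputation downstream.
    """
    rng = _rng(config, _STREAM_ANNOTATION)
    n_c, n_nc = config.n_coding_genes, config.n_noncoding_genes
    n_div = round(config.frac_divergent_pairs * n_nc)
    n_as = round(config.frac_antisense_pairs * n_nc)
    if n_div + n_as > n_c:
        raise CapacityError("more paired ncRNAs requested than coding genes")
    if config.required_length() > config.chrom_length:
        raise CapacityError(
            f"chrom_length {config.chrom_length} too small; need at least "
            f"{config.required_length()}")

    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = base_codes[rng.integers(0, 4, size=config.chrom_length)].copy()

    partners = rng.permutation(n_c)
    div_host = set(partners[:n_div].tolist())
    as_host = set(partners[n_div:n_div + n_as].tolist())
    div_iter = iter(sorted(div_host))

    transcripts: list[TranscriptModel] = []
    pair_rows: list[dict] = []
    cursor = 1000
    L, Lnc = config.gene_length, config.nc_gene_length
    nc_counter = 0

    def add(tid_prefix, idx, start, end, strand, biotype):
        gid = f"{tid_prefix}{idx:04d}"
        transcripts.append(TranscriptModel(
            transcript_id=f"{gid}.1", gene_id=gid, chrom=config.chrom_name,
            start=int(start), end=int(end), strand=strand, biotype=biotype,
            high_confidence=bool(rng.random() < config.high_conf_frac)))
        return transcripts[-1]

    for i in range(n_c):
        strand = "+" if rng.random() < 0.5 else "-"
        if i in div_host:
            d = int(rng.integers(200, 801))
            if strand == "+":
                nc = add("NC", nc_counter, cursor, cursor + Lnc, "-", "divergent")
                c_start = cursor + Lnc - 1 + d
                c = add("CG", i, c_start, c_start + L, "+", "coding")
            else:
                c = add("CG", i, cursor, cursor + L, "-", "coding")
                nc_start = cursor + L - 1 + d
                nc = add("NC", nc_counter, nc_start, nc_start + Lnc, "+",
                         "divergent")
            nc_counter += 1
            pair_rows.append({"ncrna_id": nc.transcript_id,
                              "coding_id": c.transcript_id,
                              "orientation": "divergent"})
            cursor = max(c.end, nc.end) + config.gene_spacing
        elif i in as_host:
            c = add("CG", i, cursor, cursor + L, strand, "coding")
            nc_start = cursor + (L - Lnc) // 2
            nc = add("NC", nc_counter, nc_start, nc_start + Lnc,
                     "-" if strand == "+" else "+", "antisense")
            nc_counter += 1
            pair_rows.append({"ncrna_id": nc.transcript_id,
                              "coding_id": c.transcript_id,
                              "orientation": "antisense"})
            cursor = c.end + config.gene_spacing
        else:
            c = add("CG", i, cursor, cursor + L, strand, "coding")
            cursor = c.end + config.gene_spacing

    for _ in range(n_nc - n_div - n_as):
        strand = "+" if rng.random() < 0.5 else "-"
        add("NC", nc_counter, cursor, cursor + Lnc, strand, "lncRNA")
        nc_counter += 1
        cursor += Lnc + config.gene_spacing

    if cursor + 1000 > config.chrom_length:
        raise CapacityError(
            f"gene layout overran the chromosome ({cursor} > "
            f"{config.chrom_length - 1000})")

    elements: list[RegulatoryElement] = []
    for t in transcripts:
        if rng.random() < config.pls_frac:
            offset = int(rng.integers(-300, 301))
            width = int(rng.integers(150, 351))
            start = max(0, t.tss + offset - width // 2)
            end = min(config.chrom_length, start + width)
            elements.append(RegulatoryElement(
                element_id=f"PLS{len(elements):05d}",
                chrom=config.chrom_name, start=start, end=end))

    pairs = pd.DataFrame(pair_rows,
                         columns=["ncrna_id", "coding_id", "orientation"])
    return AnnotationBundle(genome=genome, transcripts=transcripts,
                            elements=elements, pairs=pairs,
                            chrom_name=config.chrom_name,
                            chrom_length=config.chrom_length)


# ------------------------------------------------------------- motif library

def _consensus_counts(consensus: str, p_major: float, scale: int = 100) -> np.ndarray:
    w = len(consensus)
    counts = np.zeros((4, w))
    for j, base in enumerate(consensus):
        if base == "N":
            counts[:, j] = scale / 4
        else:
            minor = (1 - p_major) / 3
            counts[:, j] = minor * scale
            counts[_BASES.index(base), j] = p_major * scale
    return counts


def generate_motif_library(config: SimulationConfig) -> MotifLibrary:
    """One strongly informative ISRE-like PWM plus weaker random decoys.

    The ISRE-like PWM sits in its own cluster; decoys are grouped into
    clusters of 1-3 members.
    """
    rng = _rng(config, _STREAM_LIBRARY)
    pwms = {ISRE_PWM_ID: _consensus_counts(ISRE_CONSENSUS, 0.85)}
    names = {ISRE_PWM_ID: "ISRE-like"}
    for k in range(config.n_decoy_pwms):
        width = int(rng.integers(8, 12))
        consensus = "".join(_BASES[i] for i in rng.integers(0, 4, size=width))
        pwms[f"PWM_DECOY{k:02d}"] = _consensus_counts(consensus, 0.70)
        names[f"PWM_DECOY{k:02d}"] = f"decoy-{consensus}"

    clusters: dict[str, tuple[str, ...]] = {ISRE_CLUSTER_ID: (ISRE_PWM_ID,)}
    decoy_ids = [p for p in pwms if p != ISRE_PWM_ID]
    sizes = [2, 1, 3]
    i = ci = 0
    while i < len(decoy_ids):
        take = sizes[ci % len(sizes)]
        clusters[f"CLU{ci:02d}"] = tuple(decoy_ids[i:i + take])
        i += take
        ci += 1
    return MotifLibrary(pwms=pwms, clusters=clusters, names=names)


# -------------------------------------------------------------- ground truth

def generate_truth(
    config: SimulationConfig,
    bundle: AnnotationBundle,
) -> GroundTruth:
    """Select ISGs, cell-type programmes and pair regulation modes."""
    rng = _rng(config, _STREAM_ANNOTATION + 10)
    coding_ids = [t.transcript_id for t in bundle.transcripts if t.is_coding]
    all_ids = [t.transcript_id for t in bundle.transcripts]
    n_isg = round(config.frac_isg * len(coding_ids))
    isg = sorted(rng.choice(coding_ids, size=n_isg, replace=False).tolist())

    n_core = max(1, round(config.frac_core * n_isg)) if n_isg else 0
    core = sorted(rng.choice(isg, size=n_core, replace=False).tolist()) \
        if n_core else []
    specific = [g for g in isg if g not in core]
    assignment = rng.integers(0, len(config.cell_types), size=len(specific))
    programs = {
        ct: tuple(sorted(core + [g for g, a in zip(specific, assignment)
                                 if a == j]))
        for j, ct in enumerate(config.cell_types)
    }
    n_het = round(config.frac_heterogeneous * len(specific))
    het = sorted(rng.choice(specific, size=n_het, replace=False).tolist()) \
        if n_het else []

    base = pd.Series(0.0, index=all_ids)
    # per-gene effect sizes vary moderately around the configured mean
    base.loc[isg] = config.effect_log2fc * rng.uniform(0.8, 1.2, size=len(isg))

    pairs = bundle.pairs.copy()
    regs = []
    for _, row in pairs.iterrows():
        if base[row["coding_id"]] > 0:
            reg = "anti" if rng.random() < config.frac_anticorrelated else "co"
        else:
            reg = "none"
        regs.append(reg)
        if reg == "co":
            base[row["ncrna_id"]] = base[row["coding_id"]]
        elif reg == "anti":
            base[row["ncrna_id"]] = -base[row["coding_id"]]
    pairs["regulation"] = regs if len(pairs) else pd.Series(dtype=object)

    true_fc = pd.DataFrame(
        {t: base * config.potency[t] for t in config.treatments},
        index=all_ids)
    return GroundTruth(
        isg_ids=tuple(sorted(base.index[base > 0])),
        core_isgs=tuple(core),
        programs=programs,
        heterogeneous=tuple(het),
        base_log2fc=base,
        true_log2fc=true_fc,
        pairs=pairs,
    )


# ------------------------------------------------------------ motif planting

def sample_pwm_sequence(counts: np.ndarray, rng: np.random.Generator) -> str:
    probs = counts / counts.sum(axis=0)
    return "".join(
        _BASES[rng.choice(4, p=probs[:, j])] for j in range(counts.shape[1]))


def plant_motifs(
    sequences: Mapping[str, str],
    target_ids: Sequence[str],
    library: MotifLibrary,
    rng: np.random.Generator,
    pwm_id: str = ISRE_PWM_ID,
) -> tuple[dict[str, str], dict[str, int]]:
    """Insert one sampled ISRE-like site into each targeted sequence.

    Returns the updated sequences plus the planted window start per target.
    Sequences not listed in ``target_ids`` are returned unchanged.
    """
    counts = library.pwms[pwm_id]
    w = counts.shape[1]
    out = dict(sequences)
    positions: dict[str, int] = {}
    for sid in target_ids:
        seq = out[sid]
        if len(seq) < w:
            raise ValidationError(
                f"promoter {sid} shorter ({len(seq)}) than motif width {w}")
        pos = int(rng.integers(0, len(seq) - w + 1))
        site = sample_pwm_sequence(counts, rng)
        out[sid] = seq[:pos] + site + seq[pos + w:]
        positions[sid] = pos
    return out, positions


# ---------------------------------------------------------------- bulk data

def generate_bulk_tables(
    config: SimulationConfig,
    truth: GroundTruth,
    transcripts: Sequence[TranscriptModel],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TPM matrix, count matrix and per-treatment DE tables.

    Baseline abundance is log-normal per transcript; counts are negative
    binomial (gamma-Poisson) around TPM-implied means with donor-specific
    library sizes.  The observed log2FC is the truth scaled by potency plus
    Gaussian noise of known SD; p-values follow from that normal model, and
    BH adjustment is applied separately to coding and non-coding groups.
    """
    rng = _rng(config, _STREAM_BULK)
    ids = [t.transcript_id for t in transcripts]
    classes = pd.Series(
        ["coding" if t.is_coding else "noncoding" for t in transcripts],
        index=ids)
    n = len(ids)

    baseline = np.exp(rng.normal(np.log(config.baseline_tpm_median),
                                 config.baseline_tpm_sigma, size=n))
    samples = list(config.samples)
    tpm = pd.DataFrame(index=ids, columns=samples, dtype=float)
    counts = pd.DataFrame(index=ids, columns=samples, dtype=int)
    for t in config.treatments:
        fold = np.power(2.0, truth.true_log2fc[t].to_numpy())
        for d in range(1, config.n_donors + 1):
            col = f"donor{d}_{t}"
            noise = np.exp(rng.normal(0.0, config.tpm_noise_sigma, size=n))
            tpm[col] = baseline * fold * noise
            lib = config.library_size * np.exp(
                rng.normal(0.0, config.library_size_sigma))
            mean = tpm[col].to_numpy() / 1e6 * lib
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mean * config.nb_dispersion)
            counts[col] = rng.poisson(lam)

    de_rows = []
    from scipy import stats as _st
    for t in config.non_mock_treatments:
        obs = truth.true_log2fc[t].to_numpy() + \
            rng.normal(0.0, config.de_noise_sd, size=n)
        z = obs / config.de_noise_sd
        p = 2.0 * _st.norm.sf(np.abs(z))
        padj = np.empty(n)
        for cls in ("coding", "noncoding"):
            mask = (classes == cls).to_numpy()
            padj[mask] = bh_adjust(p[mask])
        de_rows.append(pd.DataFrame({
            "transcript_id": ids,
            "log2fc": obs,
            "pvalue": p,
            "padj": padj,
            "contrast": t,
            "feature_class": classes.to_numpy(),
        }))
    de = pd.concat(de_rows, ignore_index=True) if de_rows else pd.DataFrame(
        columns=["transcript_id", "log2fc", "pvalue", "padj", "contrast",
                 "feature_class"])
    return tpm, counts, de


# --------------------------------------------------------------- single cell

def generate_single_cell(
    config: SimulationConfig,
    truth: GroundTruth,
    transcripts: Sequence[TranscriptModel],
):
    """Cells x genes Poisson counts with per-cell rates, as an AnnData.

    Each cell gets a type, a treatment and a library size; a gene's rate is
    library x gene weight, multiplied by 2^(true log2FC) when the gene
    belongs to the cell type's programme.  Heterogeneous genes are induced
    only in a Bernoulli(het_responder_frac) subset of treated cells.
    """
    import anndata as ad
    from scipy import sparse

    rng = _rng(config, _STREAM_CELLS)
    ids = [t.transcript_id for t in transcripts]
    n_genes = len(ids)
    col = {g: j for j, g in enumerate(ids)}

    in_program = set().union(*truth.programs.values()) if truth.programs else set()
    weights = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    prog_idx = np.array([col[g] for g in sorted(in_program)], dtype=int)
    if prog_idx.size:
        weights[prog_idx] = np.exp(rng.normal(
            np.log(config.isg_weight_boost), 0.3, size=prog_idx.size))
    weights /= weights.sum()

    het = set(truth.heterogeneous)
    type_names = list(config.cell_types)

    blocks, barcodes, types, treatments = [], [], [], []
    for t in config.treatments:
        n_cells = config.n_cells_per_sample
        ct_idx = rng.integers(0, len(type_names), size=n_cells)
        libs = np.exp(rng.normal(np.log(config.sc_library_size),
                                 config.sc_library_sigma, size=n_cells))
        rate = libs[:, None] * weights[None, :]
        if t != "mock":
            for j, ct in enumerate(type_names):
                cells = np.nonzero(ct_idx == j)[0]
                if cells.size == 0:
                    continue
                for g in truth.programs[ct]:
                    factor = 2.0 ** truth.true_log2fc.at[g, t]
                    gj = col[g]
                    if g in het:
                        resp = rng.random(cells.size) < config.het_responder_frac
                        rate[cells[resp], gj] *= factor
                    else:
                        rate[cells, gj] *= factor
        blocks.append(rng.poisson(rate))
        barcodes.extend(f"{t}_c{i:04d}" for i in range(n_cells))
        types.extend(type_names[j] for j in ct_idx)
        treatments.extend([t] * n_cells)

    X = sparse.csr_matrix(np.vstack(blocks).astype(np.int64))
    obs = pd.DataFrame({
        "cell_type": pd.Categorical(types),
        "treatment": pd.Categorical(treatments, categories=config.treatments),
    }, index=pd.Index(barcodes, name="barcode"))
    var = pd.DataFrame(index=pd.Index(ids, name="transcript_id"))
    return ad.AnnData(X=X, obs=obs, var=var)


# -------------------------------------------------------------- orchestrator

@dataclass
class SimulationResult:
    """Everything one simulation run produces, in memory."""

    config: SimulationConfig
    bundle: AnnotationBundle
    library: MotifLibrary
    truth: GroundTruth
    promoters: list[PromoterRegion]
    promoter_sequences: dict[str, str]
    tpm: pd.DataFrame
    counts: pd.DataFrame
    de_tables: pd.DataFrame
    adata: object = None

    @property
    def transcripts(self) -> list[TranscriptModel]:
        return self.bundle.transcripts


def simulate(config: SimulationConfig, single_cell: bool = True) -> SimulationResult:
    """Run the full generator: annotation, library, truth, planted promoter
    motifs, bulk tables and (optionally) single-cell counts."""
    bundle = generate_annotation(config)
    library = generate_motif_library(config)
    truth = generate_truth(config, bundle)

    chrom_lengths = {config.chrom_name: config.chrom_length}
    regions = assign_promoters(bundle.transcripts, bundle.elements,
                               chrom_lengths)
    by_tx = promoters_by_transcript(regions)

    sequences = {r.region_id: bundle.sequence(r.start, r.end) for r in regions}
    induced = [tid for tid in truth.base_log2fc.index
               if truth.base_log2fc[tid] > 0]
    target_regions = sorted({r.region_id for tid in induced
                             for r in by_tx[tid]})
    rng = _rng(config, _STREAM_PLANT)
    planted_seqs, positions = plant_motifs(
        sequences, target_regions, library, rng)
    truth.motif_planted = {rid: rid in positions for rid in sequences}

    # patch the genome so FASTA extraction reproduces the planted sequences
    region_by_id = {r.region_id: r for r in regions}
    for rid in target_regions:
        r = region_by_id[rid]
        seq = planted_seqs[rid]
        bundle.genome[r.start:r.end] = np.frombuffer(
            seq.encode("ascii"), dtype=np.uint8)

    tpm, counts, de = generate_bulk_tables(config, truth, bundle.transcripts)
    adata = generate_single_cell(config, truth, bundle.transcripts) \
        if single_cell else None
    return SimulationResult(
        config=config, bundle=bundle, library=library, truth=truth,
        promoters=regions, promoter_sequences=planted_seqs,
        tpm=tpm, counts=counts, de_tables=de, adata=adata)
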