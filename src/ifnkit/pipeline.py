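"""End-to-end orchestration: simulate -> promoters -> motif scores ->
association -> DE sets -> core ISGs -> ISG scores -> ncRNA pairs.

``run_all`` writes every artifact under one output directory and a manifest
JSON (versions, seed, thresholds, per-output SHA-256 digests) sufficient to
reproduce the run.  Logs go to standard error; machine outputs never
interleave with logs.
"""
from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as kio
from .association import run_motif_association
from .config import SimulationConfig, Thresholds
from .errors import IfnkitError
from .expression import (core_isg_set, det_filter, eligible_cell_types,
                         isg_score, sc_log_normalise, sc_wilcoxon_de,
                         subtype_specific_sets, universal_sets)
from .models import transcripts_frame
from .motifs import score_promoters, transcript_cluster_scores
from .pairs import classify_pairs_any_contrast, pair_antisense, pair_divergent
from .promoters import assign_promoters, promoters_by_transcript
from .simulate import simulate

logger = logging.getLogger("ifnkit")


def setup_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass
class PipelineConfig:
    """Paths, thresholds and the seed for a full run."""

    outdir: str = "ifnkit_out"
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulation: SimulationConfig | None = None
    verbose: bool = False

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def reference_promoter_ids(regions, transcripts) -> list[str]:
    """Promoters whose transcript set contains >= 1 high-confidence transcript."""
    hc = {t.transcript_id for t in transcripts if t.high_confidence}
    return [r.region_id for r in regions if hc.intersection(r.transcript_ids)]


def sc_de_by_type(adata, eligible, treatments, thresholds: Thresholds,
                  mock_label: str = "mock"):
    """Per (cell type, treatment) Wilcoxon DE tables, treated vs mock."""
    norm = sc_log_normalise(adata.X, barcodes=list(adata.obs_names))
    counts = adata.X.toarray() if hasattr(adata.X, "toarray") else adata.X
    genes = list(adata.var_names)
    obs = adata.obs
    tables = {}
    for ct in eligible:
        in_type = (obs["cell_type"] == ct).to_numpy()
        mock_cells = np.nonzero(in_type & (obs["treatment"] == mock_label).to_numpy())[0]
        for t in treatments:
            if t == mock_label:
                continue
            treated = np.nonzero(in_type & (obs["treatment"] == t).to_numpy())[0]
            tables[(ct, t)] = sc_wilcoxon_de(
                norm, genes, treated, mock_cells, counts=counts,
                min_pct=thresholds.min_pct,
                logfc_threshold=thresholds.logfc_threshold)
    return tables, norm


def analyse(sim, thresholds: Thresholds | None = None):
    """Run every downstream stage on an in-memory simulation result.

    Returns a dict with the intermediate products of each stage.
    """
    th = thresholds or Thresholds()
    cfg = sim.config
    out: dict = {"sim": sim, "thresholds": th}

    by_tx = promoters_by_transcript(sim.promoters)
    ref_ids = reference_promoter_ids(sim.promoters, sim.transcripts)
    scores = score_promoters(sim.promoter_sequences, sim.library, ref_ids)
    tx_scores = transcript_cluster_scores(
        scores.cluster_z, {tid: [r.region_id for r in regs]
                           for tid, regs in by_tx.items()})
    out["promoter_scores"] = scores
    out["transcript_scores"] = tx_scores

    assoc = run_motif_association(
        sim.de_tables, sim.tpm, tx_scores,
        hi=th.hi, lo=th.lo, min_tpm=th.min_tpm)
    out["association"] = assoc

    det_sets = {
        t: det_filter(sim.de_tables, contrast=t, padj_max=th.padj_max,
                      min_abs_log2fc=th.min_abs_log2fc)
        for t in cfg.non_mock_treatments
    }
    out["det_sets"] = det_sets
    out["universal_up"] = universal_sets([up for up, _ in det_sets.values()])
    out["universal_down"] = universal_sets([dn for _, dn in det_sets.values()])
    out["specific_up"] = subtype_specific_sets([up for up, _ in det_sets.values()])

    pairs = pair_divergent(sim.transcripts) + pair_antisense(sim.transcripts)
    out["pairs"] = pairs
    out["pair_classes"] = classify_pairs_any_contrast(
        pairs, sim.de_tables, det_sets)

    if sim.adata is not None:
        eligible = eligible_cell_types(sim.adata.obs,
                                       min_avg=th.min_avg_cells)
        out["eligible_cell_types"] = eligible
        if not eligible:
            logger.warning("no cell type reaches %s cells/sample on average; "
                           "skipping single-cell DE", th.min_avg_cells)
            out["sc_de_tables"] = {}
            out["core_isgs"] = frozenset()
            return out
        sc_tables, norm = sc_de_by_type(
            sim.adata, eligible, cfg.treatments, th)
        out["sc_de_tables"] = sc_tables
        out["core_isgs"] = core_isg_set(
            sc_tables, padj_max=th.padj_max, min_fold=th.sc_min_fold)
        if out["core_isgs"]:
            out["core_isg_scores"] = pd.Series(
                isg_score(norm, list(sim.adata.var_names),
                          sorted(out["core_isgs"])).to_numpy(),
                index=sim.adata.obs_names, name="core_isg_score")
    return out


STAGES = ("simulate", "promoters", "motif-score", "motif-assoc", "de-sets",
          "core-isgs", "isg-score", "ncrna-pairs")


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline, writing artifacts and a manifest."""
    setup_logging(config.verbose)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "ifnkit_version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        "simulation": {k: v for k, v in asdict(config.simulation).items()},
        "stages": [],
        "outputs": {},
    }
    completed = []
    stage = "simulate"
    try:
        sim = simulate(config.simulation)
        logger.info("simulate: %d transcripts, %d elements, %d cells",
                    len(sim.transcripts), len(sim.bundle.elements),
                    0 if sim.adata is None else sim.adata.n_obs)
        kio.write_fasta(outdir / "genome.fa",
                        {sim.bundle.chrom_name:
                         sim.bundle.genome.tobytes().decode("ascii")})
        kio.write_annotation_gtf(outdir / "annotation.gtf", sim.transcripts)
        kio.write_annotation_tsv(outdir / "annotation.tsv", sim.transcripts)
        kio.write_bed(outdir / "pls.bed", sim.bundle.elements)
        kio.write_jaspar_pfm(outdir / "pwms.jaspar", sim.library)
        kio.write_cluster_map(outdir / "clusters.tsv", sim.library)
        kio.write_matrix_tsv(outdir / "tpm.tsv", sim.tpm)
        kio.write_matrix_tsv(outdir / "counts.tsv", sim.counts)
        kio.write_de_tables(outdir / "de_tables.tsv", sim.de_tables)
        kio.write_truth_json(outdir / "truth.json", sim.truth)
        if sim.adata is not None:
            kio.write_mtx_bundle(outdir / "sc", sim.adata)
        completed.append(stage)

        stage = "promoters"
        results = analyse(sim, config.thresholds)
        kio.write_promoters_bed(outdir / "promoters.bed", sim.promoters)
        logger.info("promoters: %d regions (%d matched, %d imputed)",
                    len(sim.promoters),
                    sum(r.source == "matched" for r in sim.promoters),
                    sum(r.source == "imputed" for r in sim.promoters))
        completed.append(stage)

        stage = "motif-score"
        scores = results["promoter_scores"]
        long = scores.cluster_z.stack().rename("z").reset_index()
        long.columns = ["promoter_id", "cluster_id", "z"]
        long.to_csv(outdir / "cluster_scores.tsv", sep="\t", index=False)
        kio.write_matrix_tsv(outdir / "transcript_scores.tsv",
                             results["transcript_scores"])
        logger.info("motif-score: %d promoters x %d PWMs",
                    *scores.raw.shape)
        completed.append(stage)

        stage = "motif-assoc"
        results["association"].to_csv(outdir / "association.tsv", sep="\t",
                                      index=False, na_rep="NA")
        logger.info("motif-assoc: %d tests", len(results["association"]))
        completed.append(stage)

        stage = "de-sets"
        rows = []
        for t, (up, dn) in results["det_sets"].items():
            for s in (up, dn):
                rows += [{"contrast": t, "direction": s.direction,
                          "transcript_id": fid} for fid in sorted(s.feature_ids)]
        pd.DataFrame(rows).to_csv(outdir / "det_sets.tsv", sep="\t", index=False)
        with open(outdir / "universal_sets.json", "w") as fh:
            json.dump({"up": sorted(results["universal_up"]),
                       "down": sorted(results["universal_down"]),
                       "specific_up": {k: sorted(v) for k, v in
                                       results["specific_up"].items()}},
                      fh, indent=1)
        logger.info("de-sets: %d universal up, %d universal down",
                    len(results["universal_up"]), len(results["universal_down"]))
        completed.append(stage)

        stage = "core-isgs"
        core = sorted(results.get("core_isgs", ()))
        with open(outdir / "core_isgs.json", "w") as fh:
            json.dump({"core_isgs": core,
                       "eligible_cell_types":
                       results.get("eligible_cell_types", [])}, fh, indent=1)
        logger.info("core-isgs: %d genes", len(core))
        completed.append(stage)

        stage = "isg-score"
        if "core_isg_scores" in results:
            results["core_isg_scores"].rename_axis("barcode").reset_index() \
                .to_csv(outdir / "isg_scores.tsv", sep="\t", index=False)
        completed.append(stage)

        stage = "ncrna-pairs"
        results["pair_classes"].to_csv(outdir / "ncrna_pairs.tsv", sep="\t",
                                       index=False)
        logger.info("ncrna-pairs: %d classified", len(results["pair_classes"]))
        completed.append(stage)
    except IfnkitError as exc:
        manifest["stages"] = completed
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise IfnkitError(f"[{stage}] {exc}") from exc

    manifest["stages"] = completed
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(outdir))] = _digest(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
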