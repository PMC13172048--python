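# ifnkit

Downstream analysis toolkit for type I interferon (IFN) transcriptomics:
given bulk and single-cell RNA-seq derivatives of IFN-stimulated PBMCs, it
answers four questions that recur in interferon-stimulated gene (ISG)
studies —

1. **Which transcription-factor motifs explain the induction?** Promoters
   are assigned to every transcript group (matched ENCODE promoter-like
   elements within 500 bp of the TSS, uniformly extended to 350 bp, or
   imputed around the TSS), scanned against a PWM library on both strands,
   Z-standardised against high-confidence transcripts, aggregated into
   motif-cluster scores, and each cluster is tested per treatment with a
   Mann–Whitney U test comparing fold changes of high-scoring (z ≥ 2)
   versus low-scoring (z ≤ −1) transcripts, with Benjamini–Hochberg
   correction across the cluster × treatment grid.
2. **Which genes respond universally?** DET sets (padj ≤ 0.05,
   |log2FC| ≥ 0.585) are intersected across treatments, and in single-cell
   data the "core ISG" set is the intersection of up-regulated genes over
   every eligible cell type (> 50 cells/sample on average) and every IFN
   subtype (Wilcoxon rank-sum, 10 % detection, 0.25 log2FC pre-filter,
   padj < 0.05, ≥ 1.5-fold).
3. **How uniform is the response across cells?** A per-cell ISG score sums
   log-normalised expression over a gene set (e.g. the ten published core
   ISGs, shipped as `ifnkit.CORE_ISGS`).
4. **Are non-coding neighbours co-regulated?** Divergent (head-to-head,
   ≤ 1 kb) and antisense (opposite-strand overlap) lncRNAs are paired with
   coding neighbours and classified as co-regulated, anticorrelated or
   unmatched from their DET signs.

Because the donor data behind such studies are rarely at hand, the package
includes a first-class synthetic cohort generator
(`ifnkit.simulate`) that plants all of the above structure — an ISRE-like
motif in ISG promoters, treatment potency ordering, shared and cell
type-specific programmes, heterogeneous genes, co-/anti-regulated ncRNA
pairs — with full ground truth, so every stage is testable end to end.

## Worked example

```python
from ifnkit import SimulationConfig, simulate
from ifnkit.pipeline import analyse

sim = simulate(SimulationConfig(seed=1))   # 1000 transcripts, 2400 cells
res = analyse(sim)
print(res["association"].sort_values("padj").head(5))
```

The association table ranks the planted ISRE-like cluster first for every
IFN subtype (decoy clusters stay at null p-values):

```
cluster_id treatment  n_regulated  n_unregulated            p         padj
      ISRE    ifna2a           38            296 4.276513e-22 3.563761e-21
      ISRE      ifnb           38            298 2.560612e-22 3.563761e-21
      ISRE      ifno           38            298 3.501200e-22 3.563761e-21
      ISRE    ifna10           38            296 7.992309e-22 4.995193e-21
      ISRE     ifna1           36            298 3.900948e-21 1.950474e-20
```

`n_regulated`/`n_unregulated` are the partition sizes after the robust
expression filter; `padj` is BH-adjusted over all cluster × treatment
tests. The same run recovers the planted universal programme
(`len(res["universal_up"]) == 208` of 211 induced transcripts), returns
exactly the 10 planted core ISGs from the single-cell arm, classifies the
planted ncRNA pairs (11 co-regulated, 3 anticorrelated at the IFN-β
contrast), and the mean core-ISG score per cell rises with treatment
potency (mock 25.1 → IFN-α1 33.4 → IFN-β 40.6).

The same stages run from files via the CLI:

```bash
ifnkit simulate --seed 1 --out sim/
ifnkit promoters --annotation sim/annotation.tsv --pls sim/pls.bed \
       --genome sim/genome.fa --out promoters.bed
ifnkit motif-score --promoters promoters.bed --genome sim/genome.fa \
       --pwms sim/pwms.jaspar --clusters sim/clusters.tsv \
       --annotation sim/annotation.tsv --out scores.tsv
ifnkit motif-assoc --de sim/de_tables.tsv --tpm sim/tpm.tsv \
       --scores scores.tsv --out association.tsv
ifnkit run-all --seed 1 --out run/        # everything, plus manifest.json
```

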