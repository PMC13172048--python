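# Methods

`ifnkit` re-implements, as a tested reusable pipeline, the downstream
analyses used to characterise transcriptional responses of PBMCs to type I
interferons: promoter-based transcription-factor motif association, bulk
differential-expression set algebra, single-cell core-ISG identification and
per-cell ISG scoring, and classification of non-coding/coding neighbour
co-regulation. Every stage is exercised end-to-end on a synthetic cohort
generator with known ground truth, so the statistical machinery can be
validated without access to donor data.

## Promoter assignment

Each transcript group receives at least one fixed-length promoter region.
Promoter-like elements (the ENCODE cCRE PLS class, supplied as BED) are
matched to a transcript when the element's nearest base lies within
`max_gap` = 500 bp of the TSS (boundary inclusive; distance 0 when the TSS
falls inside the element). All qualifying elements are retained, so the
transcript–element relation is many-to-many. Matched intervals are resized
to exactly 350 bp around their midpoint; transcripts with no nearby element
get one region imputed symmetrically around the TSS.

Decisions where the procedure leaves room:

- **Gap anchor.** The 500 bp gap is measured TSS-to-nearest-element-edge —
  the most permissive reading; a centre-based metric is a one-line change in
  `tss_element_gap`.
- **Centring parity.** Midpoint and half-width use floor division, so
  results are bit-stable across platforms.
- **Edges.** Regions overrunning a chromosome end are shifted inward,
  preserving the 350 bp length (keeps motif scores comparable across
  promoters).
- **Strand.** Promoter geometry ignores strand.
- Identical intervals from the same source are merged, pooling transcript
  and element ids.

## Motif scoring

PWM count matrices are converted to log2-odds with a uniform background and
a pseudocount of 0.01 per cell (none of these is dictated by the procedure;
all are arguments). Each promoter × PWM score is the maximum log-odds over
all windows on the forward and reverse-complement strands; ties prefer the
forward strand, then the leftmost window. Ambiguous bases (`N`) contribute
the background-expected log-odds, i.e. zero under a uniform background, so
windows containing `N` are scored rather than discarded.

Raw scores are Z-normalised per PWM against the **reference set**: promoters
whose transcript set contains at least one high-confidence transcript (the
GENCODE-style MANE Select / TSL 1–2 flag). Normalised scores are summed
within motif clusters and the sums Z-scored again against the same
reference, giving the per-promoter cluster score; each transcript group
takes the maximum cluster score over its promoters. Standard deviations use
the n−1 denominator (a flag switches to n). The mean-0/SD-1 contract over
the reference set holds to 1e-9 at both stages and is asserted in tests.

## Motif–fold-change association

For each motif cluster and each IFN-vs-mock contrast, transcripts are
partitioned into "likely regulated" (cluster z ≥ 2) and "likely
unregulated" (z ≤ −1), restricted to robustly expressed transcripts
(median TPM ≥ 10 in mock or treated samples, boundary inclusive). Observed
log2 fold changes of the two sets are compared with a two-sided
Mann–Whitney U test (exact enumeration when both arms have ≤ 8 values and
no ties; otherwise the normal approximation with tie and continuity
corrections). P-values are Benjamini–Hochberg adjusted over the full
cluster × treatment grid by default; a per-treatment pool is available
(`bh_pool="per-treatment"`). Tests with an empty arm are reported as NA and
excluded from the BH pool. The fold-change source is whatever the DE table
carries (shrunken estimates upstream, the known-noise simulated values
here).

## Bulk DET set algebra

Differentially expressed transcript groups (DETs) are rows with adjusted
p ≤ 0.05 and |log2FC| ≥ 0.585 (1.5-fold), both boundaries inclusive.
Robust expression for bulk counts requires every sample of at least one
condition to have ≥ 20 assigned reads. Universal sets are intersections of
per-treatment DET sets (per direction); subtype-specific sets contain
features significant for exactly one treatment.

## Single-cell procedures

- **Normalisation**: counts per 10,000 then natural `log1p` — the "log
  normalise" convention of the tooling this stage emulates.
- **Differential expression**: Wilcoxon rank-sum per gene between a
  treated and the unstimulated sample within one cell type. A gene is
  tested iff detected (count > 0) in ≥ 10 % of cells of at least one group
  and |log2FC| ≥ 0.25, where the fold change is the log2 ratio of mean
  back-transformed expression with a +1 pseudocount. Adjustment is
  Bonferroni over tested genes (BH by flag). Reported DEGs use strict
  padj < 0.05.
- **Eligibility**: a cell type enters the analysis when it averages
  strictly more than 50 cells per sample; the denominator is the number of
  samples in the experiment, including samples where the type is absent.
- **Core ISGs**: the intersection, over every eligible cell type ×
  treatment, of genes with padj < 0.05 and log2FC ≥ log2(1.5). The
  ten-gene core list reported from donor data (IFI44L, ISG15, IFIT3, XAF1,
  MX1, IFI6, IFIT1, TRIM22, MX2, RSAD2) ships as the constant
  `ifnkit.CORE_ISGS`; it derives from real data and is not recomputed.
- **ISG score**: per cell, the sum of log-normalised expression over a
  gene set; genes missing from the matrix are warned about and skipped.

## ncRNA/coding pairing

Matching is geometric (a name-suffix convention would not exist for
arbitrary annotations): divergent = opposite strands, head-to-head TSSs
within 1 kb (nearest coding TSS wins); antisense = opposite-strand overlap
of ≥ 1 bp (largest overlap wins). For a DET ncRNA, classification compares
DET signs: same sign → co-regulated, opposite → anticorrelated, partner not
a DET → unmatched. Sign-based classification (rather than expression
correlation across samples) matches how "anticorrelated" counts are usually
derived from DE tables; a correlation-based variant would need per-sample
abundances and is out of scope. An "any contrast" summary keeps, per ncRNA,
the contrast with the largest absolute fold change among those where the
ncRNA is a DET.

## The synthetic cohort

The generator defines the study conditions; all randomness derives from one
seed through named sub-streams, so identical configs give byte-identical
artifacts.

- **Design**: 6 treatments (mock + 5 IFN subtypes) × 3 donors; potency
  multipliers mock 0 < ifna1 0.5 < ifna2a 0.6 < ifna10 0.7 < ifno 0.85 <
  ifnb 1.0, encoding the observed ordering (IFN-β strongest, IFN-α1
  weakest).
- **Genome/annotation**: 800 coding + 200 non-coding genes on one 8 Mb
  chromosome, gene bodies spaced 2 kb apart so only designed pairs
  interact. 15 % of non-coding genes are placed divergent (head-to-head,
  TSS gap 200–800 bp) and 15 % antisense (nested opposite-strand) to coding
  partners. 70 % of transcripts get a PLS within 500 bp of the TSS (the
  rest force imputation); 60 % are flagged high-confidence (the reference
  set).
- **ISG programme**: 25 % of coding genes (200 ISGs vs 800 non-ISGs, the
  sizes used for the recovery analyses) with per-gene effect
  2.5 × U(0.8, 1.2) log2 units at potency 1 — strong but within the range
  of interferon inductions, and large enough that the weakest subtype still
  clears the 1.5-fold reporting threshold at single-cell depth.
- **Promoter motifs**: one ISRE-like PWM (consensus `AGTTTCAGTTTCC`-type
  tandem TTTC repeat with a 2-bp spacer, 0.85 per consensus base; constant
  `ISRE_CONSENSUS`) in its own cluster, plus 8 weaker random decoy PWMs in
  clusters of 1–3. One site sampled from the ISRE PWM is planted at a
  uniform position in every promoter of every induced transcript.
- **Bulk tables**: baseline TPM log-normal (median 30, σ 1); counts
  gamma-Poisson (dispersion 0.05) around TPM-implied means with donor
  library sizes ~2×10⁷. Observed log2FC = truth × potency + N(0, 0.25);
  p-values come from that known-SD normal model, BH-adjusted separately for
  coding and non-coding groups. Emitting DE tables directly reflects the
  scope cut: count-model fitting happens upstream of this package.
- **Single cell**: 5 cell types, 400 cells per sample (6 samples),
  library sizes log-normal around 3,000 counts, genes weighted log-normally
  with ISGs drawn from a higher baseline (boost 2.5) so induced genes are
  detectable at this depth. Counts are Poisson given per-cell rates;
  overdispersion enters through library-size and gene-weight variability.
  Each type's programme = a shared core (5 % of ISGs → 10 genes) plus
  type-specific genes; 10 % of non-core ISGs are "heterogeneous", induced
  only in a Bernoulli(0.5) subset of treated cells.
- **Pair regulation**: ncRNAs paired to an induced coding partner are
  anti-regulated with probability 0.33, otherwise co-regulated (truth fold
  change mirrored or negated); pairs with non-ISG partners are unregulated.

What the generator does **not** emulate: UMI chemistry, ambient RNA,
batch/donor single-cell effects, dropout beyond Poisson sampling, realistic
dispersion or library-size distributions (unreported for the real data;
values above are conventional), isoform-level grouping, or read-level data.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not performance on real
sequencing artefacts.

## Numerical and testing notes

- Coordinates are 0-based half-open internally; GTF is converted once, at
  the reader. TSVs are tab-separated, headered, `NA` for missing.
- Rank tests go through `scipy.stats.mannwhitneyu`; BH through
  `statsmodels`. Tests cross-check both against independent permutation /
  step-up oracles rather than the same libraries.
- Recovery analyses run at the default sizes above over 20 fixed seeds and
  require ≥ 19 successes; the null-calibration check is a per-seed
  level-0.05 event, so one hit among 20 null seeds is within expectation.
- Permutation-oracle agreement for the rank test is checked on samples with
  scattered ties (rounded continuous values). For coarse categorical data
  the normal approximation's error is intrinsically larger than the
  tolerance used here; such data should use exact or permutation methods
  directly.
- The full default pipeline (seed 0) runs in under ten seconds on one CPU;
  the complete test suite, including the 20-seed recovery experiments, in
  about two and a half minutes.
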