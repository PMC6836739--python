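# Methods

## Signal model and coordinate conventions

All genomic arithmetic is 0-based, half-open. GTF input (1-based,
inclusive) is converted on read; BED/bedGraph are written 0-based.
Every assay is reduced to read 5′ ends: the leftmost aligned base on
the + strand, the rightmost on the −. Optional signed offsets
(e.g. +75 nt for ChIP-seq to approximate the nucleosome dyad, +35 nt
for DNase fragments) are applied along the direction of transcription.
Counts are stored sparsely (sorted position/count arrays per
chromosome and strand); behaviour is that of a dense per-base vector.

Windows written [a, +b] relative to a TSS are inclusive of both
endpoints in transcription-direction coordinates: [−100, +500] spans
601 bp, lying right of a + strand TSS and left of a − strand TSS.
Windows reaching past a chromosome edge are clipped at quantification
time; the missing part contributes nothing.

Normalization is "reads per 10⁷ uniquely aligned reads":
norm = raw × 10⁷ / library_size, with the library size counted over
the whole library (not per chromosome), so depths are comparable
across samples. Log-ratios add a pseudocount of one read per 10⁷ to
numerator and denominator.

## Cluster calling

A TSS cluster is a fixed-width window (`cluster_size`, default 150 bp)
on one strand. Candidate anchors are the observed 5′-end positions:
any window can be shifted right until its left edge meets its leftmost
contained read without losing reads, so read-anchored windows are an
exhaustive candidate set and the reported cluster start always
coincides with a read. Selection is greedy: deepest window first, ties
to the lower coordinate, suppressing any later candidate whose anchor
lies within `min_dist` (default 150 bp) of an emitted one on the same
strand. With `min_dist >= cluster_size` emitted windows never overlap
and no read is counted twice.

Two filters follow, with the boundary semantics taken literally from
their wording:

* depth floor — normalized depth ≥ 7 reads per 10⁷ (inclusive);
* local background — per-bp density strictly > `local_fold` (default
  2) times the same-strand density of the surrounding `local_span`
  (default 10 kb), excluding the cluster's own span. An empty
  background receives a pseudocount of 0.5 reads — enough to avoid
  infinite folds, never enough to rescue a failing cluster. At
  chromosome edges the density denominator is the actually surveyed
  (clipped) width, so edge clusters are not penalised for
  out-of-genome bp. The background deliberately uses the cluster's own
  strand: the failure mode being targeted (exonic degradation
  carry-over, read-through) is strand-coherent.

The primary TSS is the deepest position in the cluster; ties break to
the 5′-most position in the direction of transcription. Whether a
neighbouring called cluster should be excluded from the background was
left open; we exclude only the cluster under test, which is
conservative (neighbours make the background harder to beat, never
easier).

## Input calibration

Each cluster's enrichment ratio is (csRNA_norm + 1)/(input_norm + 1)
over its own 150-bp window, same strand; total RNA-seq can stand in
for the input library (identical arithmetic) via
`--use-rnaseq-as-input`.

Presumptive labels: TP = primary TSS within ±`promoter_window`
(default 500 bp, the same constant as the promoter-distal rule — the
one promoter-distance constant the method defines) of an annotated
gene TSS on the same strand; FP = primary TSS inside a *non-first*
exon of a same-strand gene and farther than the promoter window from
every gene TSS. First exons are excluded from the FP rule because a
cluster there may be a genuine TSS of a long first exon. Everything
else is unlabeled and does not influence the threshold.

The threshold is the smallest grid point (grid = sorted union of
observed ratios) maximizing D(t) = F_FP(t) − F_TP(t) with ≤-type
empirical CDFs — the location of the signed Kolmogorov–Smirnov
statistic. D is invariant under monotone transforms of the ratios, so
raw vs log ratios change nothing but the grid labels. Clusters with
ratio strictly above the threshold survive. The smallest-maximizer
tie-break makes the choice deterministic; note that on perfectly
separated classes it places the threshold at the largest FP ratio
(the most permissive value achieving full separation), not midway
between the classes.

When calibration is impossible — no annotation, or an empty TP or FP
class — a fallback threshold of 2.0 applies (the pervasive twofold
convention), or the run aborts if the fallback is disabled. When no
input library is given at all, no ratio exists and the enrichment
filter is skipped entirely; the manifest records which path ran.

## Annotation

* Stability: sense-strand RNA-seq 5′ ends in [−100, +500] ≥ 2 per 10⁷
  (inclusive); NA without an RNA-seq library. Counting 5′ ends rather
  than full-read overlap keeps the single global convention; with
  gene-body-scale coverage the two differ negligibly.
* Bidirectionality: opposite-strand csRNA (the same library used for
  calling, not just called antisense clusters) in [−500, +100]
  ≥ 2 per 10⁷ (inclusive).
* Distal: strictly > 500 bp from the nearest annotated gene TSS, any
  strand — an antisense cluster 100 bp upstream of a promoter (a
  PROMPT) is promoter-proximal. Feature precedence:
  promoter > exon > intron > intergenic; the reported signed distance
  is oriented by the nearest gene's strand (positive = downstream).

## Merging and quantification

Cross-sample merging is single-linkage over primary-TSS distance
(≤ 150 bp, same strand) — the single-bp anchors are the method's
currency, so they, rather than span overlap, define redundancy. The
feature span is the union of member spans; the representative TSS
comes from the deepest member. Count matrices are raw same-strand
5′-end counts per feature and sample, exported with a library-size
sidecar for external differential testing; no shrinkage or FDR
machinery is implemented here. Metaprofiles average per-10⁷ signal in
transcription-direction coordinates (− strand anchors mirrored).

## The simulator

`SimConfig` defaults define the study conditions: a 4 × 30 Mb genome;
40 genes (2–5 exons of 300–1500 bp, introns 800–3000 bp) and
15 enhancers placed in distinct 50-kb slots so no two independent loci
interact through any quantification window; 60% of promoters stable;
PROMPTs on 30% of promoters, 150–400 bp upstream antisense;
80% of enhancers bidirectional (divergent partner 110–250 bp away);
per-locus rates lognormal(0, 1) with enhancers ×0.3 and PROMPTs ×0.2;
6 × 10⁶ reads per library. Depth and genome size are scaled together
so the printed per-10⁷ thresholds translate into meaningful raw-read
requirements (the depth floor is ~4 raw reads, the stability and
bidirectionality minima 2 raw reads) while the 1% uniform noise floor
stays well below them — mirroring the depth-to-genome ratio of a real
experiment (~10⁷ reads against ~3 Gb).

Read models:

* csRNA — 5′ ends at planted TSSs plus rounded Gaussian scatter
  (sd 2 bp, respecting single-bp resolution while exercising window
  logic); 1% uniform genomic noise; and a cap-selection leakage term:
  `capture_leak × degradation_level` of reads drawn from the
  degradation distribution below. Cap selection is strong but not
  perfect, and the worse the RNA the more degradation fragments slip
  through; without this term the input library would have nothing to
  correct and the calibration step would be untestable. The default
  (0.005) is sized so that a typical stable gene's exonic carry-over
  clears the depth floor even at the lowest degradation level
  exercised (0.1), keeping the calibration's FP class populated.
* input — (1 − degradation_level) of reads from the csRNA TSS+noise
  model, degradation_level from exon bodies of stable genes
  (rate-weighted per gene, uniform within each gene's merged exons):
  degradation products come from abundant, stable RNAs.
  `degradation_level` is the RNA-quality (RIN) knob.
* RNA-seq — 5′ ends uniform over stable gene bodies, rate-weighted,
  plus the noise floor; enhancers, PROMPTs and unstable promoters are
  RNA-seq dark.

All randomness derives from `SimConfig.seed` through fixed named
streams; outputs are byte-identical across reruns. What the simulator
does **not** model: sequence (reads are positional; alignment is out
of scope), sequencing error and PCR duplicates, empirical TSS shape
(dispersed vs focused initiation), transcript-level isoform structure,
mappability, and chromatin covariates. Tests passing on this generator
therefore validate the pipeline's logic and thresholds, not its
behaviour on artefacts the generator omits.

## Numerical and degenerate-input choices

* Ties everywhere break to the lower coordinate (or 5′-most in
  transcription direction for primary TSSs), making every stage
  deterministic; the pipeline proper uses no randomness at all.
* Empty coverage → empty cluster list with a warning; an empty read
  stream is an error (a library of size zero cannot be normalized).
* Zero-read clusters cannot reach `primary_tss` (caller postcondition);
  reaching it raises.
* Duplicating every read in every library changes no call, flag or
  threshold (everything thresholded is per-10⁷ or a ratio).
* Adapter trimming removes the leftmost read suffix matching an
  adapter prefix with ≥ `min_overlap` (default 4, avoiding spurious
  1–3-base trims) exact bases, repeated to a fixpoint so the
  operation is idempotent.

## Known limitations

* The greedy fixed-width cluster model reports 150-bp windows even
  when initiation occupies a few bp; the primary TSS carries the
  resolution. Dispersed promoters wider than 150 bp fragment into
  multiple clusters 150 bp apart.
* The calibration needs annotated genes with multi-exon structure; on
  a sparse annotation the FP class may be empty and the 2.0 fallback
  is then aggressive when csRNA/input ratios sit near 1 (equal-depth,
  high-quality libraries).
* Strand-blind distal classification deliberately absorbs PROMPTs into
  the promoter class; enhancer counts are therefore conservative.
* Acceptance-scale statements (sensitivity, precision, flag accuracy)
  are properties of the planted-truth generator at its default
  operating point, not of any real library.
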