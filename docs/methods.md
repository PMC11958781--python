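# Methods

## Scope and coordinate conventions

`succer` starts from per-sample peak regions and fragment intervals;
read-level processing (QC, alignment, duplicate filtering, peak calling)
and spike-in calibration are upstream and out of scope. All coordinates are
0-based half-open throughout; GTF input (1-based) is converted on read. The
TSS of a minus-strand gene is `tx_end - 1`, the last covered base, so the
TSS is always a valid coordinate. Book-ended intervals merge at gap 0,
matching the dominant merge semantics of genomic toolkits.

## DER calling

Consensus regions are the union-merge of all samples' peaks; per-region
contributing samples are recorded so stricter filters can be applied later.
Quantification is either fragment-overlap RPKM (`count × 1e9 /
(length × library_size)`, library size = total fragments in the sample) or
the mean of an RPKM-normalized coverage track over the region.

The call rule compares pseudocounted group-mean RPKMs against a fold
threshold τ (default 2). The pseudocount ε (default 0.5 RPKM, configurable)
is added to both means: without it, any region with zero signal in one
group is an infinite-fold call regardless of evidence. Group means are
arithmetic means across replicates. GAIN and LOSS are mutually exclusive by
construction, and swapping group labels swaps the classes exactly.

Feature annotation is summit/midpoint-centric: the region midpoint is
tested with precedence promoter-TSS > TES > exon > intron > intergenic.
The promoter window is [TSS − 1000, TSS + 100) strand-oriented, a common
annotation-tool convention, and configurable; TES means within ±100 bp of
the transcription end site. Signed TSS distance is strand-oriented
(negative = upstream). Meta-profiles use fixed-width 20 bp flank bins with
the gene body linearly rescaled to 100 bins; genes shorter than one base
per body bin are skipped and counted.

## Expression integration

Each DER is assigned to the single gene minimizing |midpoint − TSS|,
kept when that unsigned, strand-agnostic distance is ≤ 100 kb; ties break
on the lexicographically smallest gene id, and genes absent from the
expression table are excluded, never imputed. When several DERs share a
gene, the representative for per-gene statistics is the DER with the
largest |log₂FC| (one point per gene in the fold-change scatter); an
all-pairs mode is available by flag. The fold-change correlation is the
standard product-moment r with a two-sided t-test on n − 2 df. It is
computed over all assigned genes found in the expression table rather than
only DEG-flagged genes: conditioning on |gene log₂FC| > 1 would truncate
the y-variable and bias r.

The Wilcoxon signed-rank test is implemented in-package with the exact
semantics the pipeline needs: zero differences dropped, tied absolute
differences given average ranks, exact null distribution (conditional on
the observed ranks, computed by dynamic programming over doubled rank sums)
for n_eff ≤ 25, and a tie-corrected normal approximation with 0.5
continuity correction beyond. The two-sided exact p is
2·min(P(W ≥ w), P(W ≤ w)) capped at 1. scipy's implementation is used as a
cross-check on tie-free data in the tests, not as the implementation,
because its exact mode refuses ties.

## Motif layer

PWMs are built from count matrices with pseudocount α = 0.01 per cell,
scored as summed log₂-odds against a background base distribution (uniform
by default). Both strands are scanned; a hit requires ≥ 80% of the motif's
maximum attainable score (no score cutoff is standard for "known motif"
searches, so the fraction is configurable); N bases contribute zero
(background) per position; overlapping same-strand hits collapse to the
best-scoring one, ties breaking on position. Scanning the reverse
complement of a sequence yields mirror-image hits with identical scores.

Enrichment compares the fraction of target summit windows (±200 bp) with
≥ 1 hit against background windows — by default the summit windows of
non-DER consensus regions — with a one-sided binomial tail, the background
rate floored at 1/(2·n_bg); a hypergeometric variant is available for small
fixed backgrounds. Raw p < 0.01 is the significance gate, with BH q-values
reported alongside. DETFs intersect motif enrichment with the TF's own
expression: up-DETF = enriched in GAIN windows and significantly
upregulated; down-DETF mirrors with LOSS. TF-name → gene-id mapping is a
two-column input file; nothing is hard-coded.

Occurrence profiles bin hit midpoints in 10 bp bins over ±500 bp around
summits, as density in hits·bp⁻¹·window⁻¹; the conservation identity
Σ density × bin × n_windows = total hits holds exactly. Promoter targets
are DEGs with a hit midpoint inside the half-open gate
[TSS − 2000, TSS + 2000); the scanned window is padded by one motif length
so a hit straddling the gate boundary is still scored, and the gate is
applied to the midpoint.

## Pathway enrichment

Over-representation uses the hypergeometric upper tail, computed per set
over the universe of genes present in both the expression table and the
gene-set collection — the least-assuming reproducible universe choice, and
configurable. The query is filtered to |log₂FC| > 1 before testing,
matching the fold filter applied to DER-linked DEGs upstream. GAIN- and
LOSS-linked queries are tested separately. Raw p < 0.05 is the gate; BH
q-values are reported.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes, not
the sequence biology of any genome:

- **Genome**: i.i.d. bases at a configurable GC content (default 0.45,
  over two 500 kb chromosomes). No repeats, no mappability structure, no
  karyotype.
- **Genes**: non-overlapping, evenly blocked with jitter, alternating
  strands, 2–5 exons each (default 300 genes of 1–3 kb).
- **Regions and signal**: 1000 regions of 400 bp tile the genome in
  non-overlapping slots. Fragment counts are Gamma–Poisson: mean
  `depth · u_r · 2^(β_r·[case])` with u_r ~ LogNormal(0, 0.5) and shared
  dispersion φ = 10 (φ = ∞ recovers Poisson); depth = 200 expected
  fragments per region per sample, 2 replicates per condition. 10% of
  regions are planted GAIN and 10% LOSS with |β| ~ U(log₂ 3, 3); each
  planted region is moved inside its slot to sit next to a distinct gene's
  TSS so the nearest-gene step has recoverable signal. Summits are region
  midpoints; fragments (100 bp) fall uniformly within their region.
- **Background library**: each sample additionally receives an expected
  500 background fragments per region equivalent, placed uniformly in the
  gaps between regions. Real enrichment libraries are dominated by
  unenriched genome-wide background, which keeps library sizes comparable
  between conditions; without it the planted effect mass itself would
  shift the RPKM denominator and distort fold changes at null regions.
- **Expression**: linked genes draw log₂FC = a·β + e with
  e ~ N(0, σ = 1.5) and a set so the population correlation between β and
  log₂FC equals ρ (default 0.7); σ = 1.5 makes linked-gene fold changes
  routinely exceed the DEG filter of |log₂FC| > 1. Unlinked genes draw pure
  noise. Group means are log-normal FPKM-like values consistent with the
  fold change to machine precision.
- **Motifs**: the planted motif is an AP-1-like TGACTCA consensus PFM; an
  instance sampled from the PWM is written into GAIN summit windows with
  probability 0.6 and into null-region windows with probability 0.05, at
  an offset ~ N(0, 50 bp) from the summit, clipped into the window. Decoy
  motifs are random sharp 8-mers never planted anywhere.
- **Gene sets**: 20 sets of 30 genes; the planted set draws 60% of its
  members from realized GAIN-linked upregulated DEGs.

Determinism: one master seed; every stage draws from its own child stream
(numpy `SeedSequence` spawn keys), so identical configs yield
byte-identical files and stages are re-runnable in isolation.

What passing tests on this generator do **not** show: robustness to peak
boundary error, copy-number and mappability artifacts, replicate-specific
batch effects, dispersion varying across regions, distance-dependent
enhancer–gene wiring, or motif occurrence in realistic sequence
composition. The generator validates the pipeline's logic and statistics,
not its behavior on any particular organism's data.

## Problem sizes and numerical choices

Validation runs use desk-scale studies chosen to give the statistics room
to concentrate: the 1 Mb / 1000-region default for the end-to-end
demonstration; 2000 regions (same genome) for fold-rule recovery, where
the rule achieves ≥ 0.90 sensitivity on ≥ 3-fold planted effects with
≤ 5% of null regions called; and 3000 regions / 700 genes over 3 Mb for
correlation recovery, giving ~600 linked gene pairs so the sample r of a
planted ρ = 0.7 concentrates within a few hundredths. Exactness of the
hypergeometric tail is checked against direct summation for every
parameterization with N ≤ 20 (tolerance 1e-12), and the signed-rank exact
p against full 2ⁿ sign enumeration for n ≤ 10.

Degenerate inputs: zero-variance correlation input raises rather than
returning NaN; all-zero paired differences raise ("no information");
windows falling entirely off-chromosome are skipped and counted; regions
beyond 100 kb of any TSS are dropped and counted; empty gene-model sets
annotate as intergenic with an infinite distance sentinel.

## Known limitations

- The fold rule is a thresholded point estimate, not a statistical test:
  no dispersion modeling, no FDR across regions. Its false-call rate under
  the null depends on depth and dispersion; at the default depth it is a
  few percent, and it rises as depth falls.
- RPKM with total-library normalization is composition-sensitive; the
  generator's background keeps this small, but strongly asymmetric global
  shifts in real data would bias calls (spike-in calibration, out of
  scope, is the usual remedy).
- One nearest gene per region ignores multi-gene regulatory domains, and
  the 100 kb gate is hard.
- Motif enrichment treats windows as exchangeable and independent;
  sequence composition differences between target and background windows
  are not modeled (a dinucleotide-shuffled background is the usual control
  and can be supplied as the background set).
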