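# Methods

## Scope and data model

The package analyzes a two-group (control vs case) expression matrix of
positive linear-scale intensities for three RNA classes (mRNA, lncRNA,
circRNA), plus transcript annotations (GFF3), transcript/promoter/miRNA
sequences (FASTA), TF motif count matrices (MEME-minimal text), TF target
tables and term-to-gene tables (TSV). Inputs are post-normalization by
contract; the pipeline performs no normalization of its own. Internal
genomic coordinates are 0-based half-open; GFF3 conversion happens at the
I/O boundary.

## Differential expression

For each probe, the fold change is the ratio of linear-scale group means,
reported as a magnitude ≥ 1 with a direction. The test is a two-tailed
unpaired Student *t* with pooled variance (Welch available by flag), df =
n₁+n₂−2. **Scale:** the *t*-test and all correlations run on
log2-transformed intensities (`log_scale=True`), the microarray convention;
on the raw linear scale a 4-fold shift inflates the case group's variance
16-fold, which both degrades the pooled *t* and bounds attainable negative
correlations well away from −1. Fold change always uses linear means.
`log2_input=True` declares that stored values are already log2.

Multiple testing uses Benjamini–Hochberg, implemented directly as
q₍ᵢ₎ = min₍ⱼ≥ᵢ₎ (p₍ⱼ₎·m/j) capped at 1, so tests can demand exact agreement
with the textbook double loop. BH is applied within each RNA-class stratum
by default (the classes come from separate array designs); `pool_strata`
adjusts jointly. The significance gate is the conjunction FC ≥ 2.0 ∧
p < 0.05 ∧ q < 0.05.

Degenerate probes: zero pooled variance with equal means reports p = 1
(flat probe); zero pooled variance with unequal means is recorded as a
per-probe error and excluded from the BH family, without aborting the run.

## lncRNA positional classification

Per coding gene, strand-aware rules: lncRNA-exon vs gene-exon base overlap →
exon_overlapping (sense) or natural_antisense (antisense); span overlap
without exonic overlap → intron_overlapping / intron_antisense;
no overlap but divergent TSSs within 1,000 bp on opposite strands →
bidirectional (the window is a package definition — the category has no
standard operationalization — and is exposed as `bidir_window_bp`); no label
from any gene → intergenic, which is exclusive. Labels accumulate over all
genes (multi-label); the single "primary" label follows the precedence
exon_overlapping > intron_overlapping > natural_antisense > intron_antisense
> bidirectional > intergenic. Both per-category totals (every label
occurrence) and Venn partition counts (exact label sets) are emitted.

"Exonic" overlap means lncRNA-exon ∩ gene-exon bases; a lncRNA intron
covering a gene exon does not count as exonic contact.

Cis candidates use the nearest-edge gap (overlap ⇒ 0), strictly less than
the 300 kb window, same chromosome, with strand-aware upstream/downstream
annotation. TSS-to-TSS distance was the alternative; nearest-edge is
recorded in the output metadata.

## CNC co-expression network

All (noncoding, coding) pairs are scored by the sample Pearson correlation
across the pooled samples (both groups — one network per comparison), the
t-transform p-value t = r·√((n−2)/(1−r²)) at df = n−2, and BH over the full
pair family. An edge requires |r| ≥ 0.90 ∧ p < 0.01 ∧ q < 0.01; the absolute
value is used because negative correlations are retained and rendered
distinctly (SIF relation `neg_corr`). Constant probes are skipped and
counted. In the pipeline the family is DE noncoding × DE mRNA probes.

## Trans regulation

PFM counts convert to log-odds bits with pseudocount 0.25 against a
user-supplied background (uniform default). Weights are quantized to integer
milli-bits at construction; the scanner, the E-value dynamic program and the
test oracles all compare scores on this integer grid, which makes the
background tail distribution *exactly* reproducible by word enumeration.
Promoters (generator definition: [TSS−2000, TSS+200), 2,200 bp DNA) are
scanned on both strands; reverse-strand hits are reported at their
forward-strand offsets. Ambiguous bases score the background-expected column
contribution.

The E-value of a hit is P(single background position ≥ score) × number of
positions actually scanned for that TF (all promoters, both strands),
computed by exact convolution of the per-column score distributions. Hits
pass at E < 0.01. Default PFM width is 14: with the 2.2 kb promoter and a
typical few-dozen-promoter scan, a planted consensus then has E ≈ 3×10⁻⁴,
whereas a width-10 consensus would sit near E ≈ 0.08 and could never pass
the gate — a property of the stated world, fixed before any test was run.

TF-target enrichment: for each (lncRNA, TF) pair connected by a motif edge,
the overlap between the lncRNA's co-expressed gene set (CNC edges at
|r| ≥ 0.9, FDR ≤ 0.05) and the TF's target set is tested by the
hypergeometric upper tail against the universe of **all measured coding
genes** — not the DE set: in a 3v3 two-group design every DE transcript is
group-correlated with every other, so a DE-only universe would make a DE
lncRNA "co-expressed" with ~90 % of the universe and no overlap could ever
reach significance. Pairs passing p < 0.01 ∧ BH q < 0.01 expand into
(lncRNA, TF, gene) triples over targets ∩ co-expressed genes.

## ceRNA prediction

Canonical seed matching only, no GU wobble: the target is searched for the
reverse complement of miRNA positions 2–7 (6mer core); a matching m8
complement immediately 5′ of the core on the target and/or a target-encoded
A opposite position 1 upgrade the site to 7mer-m8 / 7mer-A1 / 8mer. Each
locus is reported once with its strongest type. circRNA targets are scanned
with (k−1)-base wraparound so back-splice-junction sites are found. A ceRNA
triple (nc, miRNA, mRNA) requires ≥ 1 site on both a DE noncoding transcript
and a DE mRNA for the same miRNA; no context scoring, conservation or
expression-correlation gate is applied by default (an optional
`cerna_require_correlation` flag gates triples on the CNC network).

## Term enrichment

Flat-set over-representation: hypergeometric upper tail (= one-sided
Fisher), or the EASE variant which discounts one overlap gene. The universe
is all measured coding genes (configurable). BH q is reported across all
tested terms, but the display rule filters on raw p (< 0.05), sorts by
ascending p with lexicographic tie-break, and truncates to the 10 smallest
(all shown when fewer qualify). Up- and down-regulated sets are analyzed
separately. GO-DAG decorrelation (topGO elim/weight) is out of scope.

## Synthetic data: the stated world

Defaults: 3 vs 3 samples; 2,000 mRNA, 300 lncRNA, 150 circRNA probes; 10 %
planted DE at ±2 log2 units; log-normal noise, sd 0.25 log2 units; uniform
base composition; 10 miRNAs (22 nt), 8 TFs (width-14 PFMs, 91/3/3/3 counts),
30 terms; 4 chromosomes × 30 Mb.

* **Intensities** are 2^(baseline + group_effect + noise), baseline ~
  U(6, 12) log2 — positive by construction with controllable FC and CV.
* **Co-expressed pairs** share a per-sample latent factor that *replaces*
  most of the independent noise (shared weight √(0.25²−0.05²), residual sd
  0.05) rather than adding variance on top: members keep full DE power at
  n = 3+3 while the pooled pair correlation is ≈ 0.998, above the 0.90 gate
  with margin. Pair members are planted DE (negative pairs pair an
  up-regulated noncoding with a down-regulated mRNA) because the pipeline's
  CNC family is DE-selected and, with n = 6, the q < 0.01 gate is only
  attainable inside a family dominated by truly correlated pairs.
* **Trans-regulation module**: one DE lncRNA plus 20 DE coding genes share a
  latent factor; the module TF's consensus is planted in that lncRNA's
  promoter and its target set is the module genes plus 10 non-DE genes (so
  the planted lncRNA–TF–gene chain is exactly recoverable); all other TF
  target sets are drawn from the full coding universe.
* **ceRNA module**: one miRNA receives an 8mer on one DE lncRNA, a
  7mer-m8 across the back-splice junction of one DE circRNA, and
  8mer/7mer-A1/6mer sites on three DE mRNAs. These five sequences are
  scrubbed of chance seed cores (any simulated miRNA) outside the planted,
  flank-guarded regions and self-checked at generation time, so the planted
  2×3 = 6 triple combinatorics are exact; all other sequences keep their
  chance background sites, which is what real transcriptomes look like.
* **Genome**: the first nine lncRNAs are exemplars — one per positional
  category, a multi-label crossover (sense-exonic in gene A, antisense in
  gene B's intron), and cis pairs at gaps of 295 kb (inside the window) and
  305 kb (outside) — placed in 1.5 Mb guard blocks; everything else tiles at
  20 kb spacing, intergenic by construction.
* **Enrichment**: one term holds 15 DE-up genes plus 5 non-DE genes;
  other terms draw 20–40 genes at random.

Fixing the seed fixes every output byte (all randomness flows through
per-stage `numpy` generators seeded from the one config seed).

What the generator does **not** emulate: probe-level/hybridization effects,
normalization artifacts, heavy-tailed or correlated noise beyond the planted
latent factors, miRNA expression levels, realistic genome annotation density
or sequence composition bias. A green recovery test therefore establishes
that each stage implements its stated statistic and recovers structure that
is present at the stated effect sizes — not that the thresholds are optimal
for real arrays.

Pre-measured operating characteristics on the stated world (measured once,
then frozen into the tests): planted-DE recall 0.96–0.99 with observed FDR
0.0 across seeds; planted CNC-pair detection 10/10 on every one of 50 seeds;
background motif hits with E < 0.01 averaged 0.0 per TF-scan over 100 null
scans (budget 0.01); spurious 8mer counts match (L−7)/4⁸ within Monte-Carlo
error; null raw-p < 0.05 fraction 0.0502 over 50 × 2,000 null tests.

## Numerical choices and degenerate inputs

* BH is hand-implemented with the exact step-up arithmetic (see above);
  p-values, t and hypergeometric tails come from scipy.
* PWM scores: integer milli-bits everywhere; E-value thresholds are rounded
  onto the same grid, so gate comparisons cannot straddle a float ulp.
* |r| is clipped to [−1, 1] before the t-transform; |r| = 1 ⇒ p = 0.
* Constant vectors: correlation raises a domain error at the function level
  and is skipped-and-counted at the network level.
* Ties in enrichment ranking break lexicographically by term id; all edge
  and triple lists are sorted canonically, making outputs order-stable.
* Numeric output tables carry full-precision columns plus display-rounded
  companions.

## Known limitations

* n = 3 per group leaves the t-test underpowered for effects much below
  2 log2 units; the planted world is deliberately strong-effect.
* The E-value model assumes an i.i.d. background; real promoters have
  composition bias the scan does not correct for.
* TRANSFAC-style matrix-similarity scores are not replicated; scoring is
  standard log-odds.
* ceRNA prediction is sequence-only by default; no site accessibility,
  conservation, or expression support unless the correlation flag is set.
* The classification of a lncRNA whose *intron* covers a gene exon follows
  the span-overlap rule (intron category), a boundary case annotation
  databases treat inconsistently.
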