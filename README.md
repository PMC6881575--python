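# cncnet

Post-quantification analysis of two-group expression microarrays that measure
mRNAs, lncRNAs and circRNAs — the workflow used to characterize noncoding-RNA
involvement in a perturbation (e.g. an injury model) when only transcript
intensities, annotations and sequences are available:

1. **Differential expression** — per-probe fold change (linear-mean ratio),
   two-tailed unpaired Student *t*-test, Benjamini–Hochberg FDR, and the joint
   gate *FC ≥ 2.0, p < 0.05, FDR < 0.05*, stratified by RNA class.
2. **lncRNA genomic classification** — six positional categories relative to
   protein-coding genes (exon-overlapping, intron-overlapping, natural
   antisense, intron antisense, bidirectional, intergenic), multi-label with
   Venn partition counts.
3. **Cis candidates** — coding genes within 300 kb of a DE lncRNA on the same
   chromosome (nearest-edge gap).
4. **CNC network** — coding–noncoding co-expression: Pearson correlation on
   log2 intensities across all samples, gated at *|r| ≥ 0.90, p < 0.01,
   FDR < 0.01*; negative edges carry their own relation tag for dashed
   rendering.
5. **Trans regulation** — TF position-frequency matrices are scanned over
   lncRNA promoters (log-odds bits, both strands); hits are kept at
   *E < 0.01*, where E is the exact expected number of background positions
   scoring at least as high over the whole scan. TF–lncRNA edges combine with
   hypergeometric TF-target enrichment (*p < 0.01, FDR < 0.01*) and the CNC
   network (*|r| ≥ 0.9, FDR ≤ 0.05*) into lncRNA–TF–gene triples.
6. **ceRNA network** — canonical TargetScan-style miRNA seed sites (6mer,
   7mer-A1, 7mer-m8, 8mer; no GU wobble; circRNAs scanned across the
   back-splice junction); a (noncoding, miRNA, mRNA) triple is emitted when
   the same miRNA has sites on both a DE noncoding transcript and a DE mRNA.
7. **Term enrichment** — hypergeometric / Fisher / EASE over-representation of
   DE mRNA sets with the top-10 display rule and a pathway–gene bipartite
   network.

Because real array data are not required, the package ships a synthetic-data
generator (`cncnet.simulate`) that emits every pipeline input with *planted,
recorded ground truth* — planted fold changes, co-expressed pairs, genomic
category exemplars, promoter motifs, seed sites and one enriched term — so
every stage is verifiable end to end.

## Worked example

```bash
cncnet all --seed 101 --outdir run
cat run/results/report.txt
```

prints

```
cncnet run report
DE (fold change >= 2.0, p < 0.05, FDR < 0.05):
  mRNA: 98 up-regulated, 97 down-regulated
  lncRNA: 15 up-regulated, 15 down-regulated
  circRNA: 8 up-regulated, 7 down-regulated
The up-regulated lncRNAs-TFs network consisted of 2 TFs and 4 correlated lncRNAs, connected by 4 edges.
The down-regulated lncRNAs-TFs network consisted of 1 TFs and 2 correlated lncRNAs, connected by 2 edges.
The lncRNA-TF-gene network consisted of 1 lncRNAs, 1 TFs, and 20 correlated genes.
ceRNA triples: 1699
```

The generator planted 10% of 2,450 probes as differentially expressed at
±2 log2 units; the DE stage recovers them (98+97 of 100+100 planted mRNAs,
and so on), the TF networks recover exactly the planted promoter motifs, and
the first row of `run/results/enrichment_up.tsv` is the planted term:

```
term_id   k   K   n    N     p            q            fold_enrichment
TERM_000  15  20  98   2000  9.75e-17     2.93e-15     15.3
```

(k of the term's K genes are DE among n DE genes in a universe of N.)
All tables, SIF and GraphML networks land under `run/results/`; the planted
truth is `run/inputs/truth.json`. Stages can be re-run individually
(`cncnet de|classify|cis|cnc|tfnet|ternary|cerna|enrich --outdir run`), and
identical config + seed reproduce byte-identical outputs.

As a library:

```python
from cncnet import SimConfig, simulate_all, run_de, build_cnc

bundle = simulate_all(SimConfig(seed=101))
de = run_de(bundle.matrix)                      # FC >= 2, p < 0.05, q < 0.05
nc = de.passing_ids("lncRNA") + de.passing_ids("circRNA")
cnc = build_cnc(bundle.matrix, nc, de.passing_ids("mRNA"))
print(len(cnc.edges), "CNC edges")
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out results/acceptance.json`
runs the complete simulate-first pipeline at the default stated-world
configuration under the given seed and writes the acceptance summary JSON.

## Layout

- `src/cncnet/simulate.py` — synthetic inputs + planted truth
- `src/cncnet/diffexpr.py` — fold change, t-test, BH, joint gate
- `src/cncnet/genome.py` — positional classification, cis windows
- `src/cncnet/coexpression.py` — CNC network
- `src/cncnet/regulatory.py` — PWM scanning, E-values, TF/ternary networks,
  seed matching, ceRNA
- `src/cncnet/enrichment.py` — term over-representation
- `src/cncnet/io.py`, `pipeline.py`, `cli.py` — formats, stages, CLI

See `docs/methods.md` for the statistical model, parameter defaults and known
limitations.
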