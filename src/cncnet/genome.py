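"""Genomic context of lncRNAs relative to protein-coding genes.

Two questions are answered here, both purely positional:

* Which of the six standard positional categories does a lncRNA fall into
  (exon-overlapping, intron-overlapping, natural antisense, intron antisense,
  bidirectional, intergenic)?  A lncRNA may satisfy several of the first five
  simultaneously (multi-label); "intergenic" is exclusive.
* Which coding genes lie close enough (< 300 kb by default, same chromosome)
  to be candidate cis-regulatory targets of a lncRNA?

All coordinates are 0-based half-open internally; GFF3 conversion happens at
the I/O boundary.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import DomainError

RNA_TYPES = ("mRNA", "lncRNA", "circRNA")

#: Category labels in primary-label precedence order.
CATEGORY_PRECEDENCE = (
    "exon_overlapping",
    "intron_overlapping",
    "natural_antisense",
    "intron_antisense",
    "bidirectional",
    "intergenic",
)


@dataclass(frozen=True)
class TranscriptRecord:
    """A stranded genomic transcript model with an exon chain.

    ``exons`` are 0-based half-open intervals, sorted and pairwise disjoint,
    contained in ``[start, end)``.  An empty exon tuple is normalized to a
    single exon spanning the whole transcript.
    """

    id: str
    gene_id: str
    rna_type: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    is_circular: bool = False

    def __post_init__(self):
        if self.rna_type not in RNA_TYPES:
            raise DomainError(f"{self.id}: unknown rna_type {self.rna_type!r}")
        if not (isinstance(self.start, int) and isinstance(self.end, int)):
            raise DomainError(f"{self.id}: coordinates must be integers")
        if self.start >= self.end:
            raise DomainError(f"{self.id}: start must be < end ({self.start} >= {self.end})")
        if self.strand not in ("+", "-"):
            raise DomainError(f"{self.id}: strand must be '+' or '-'")
        exons = tuple(tuple(e) for e in self.exons) or ((self.start, self.end),)
        prev_end = None
        for (s, e) in exons:
            if s >= e:
                raise DomainError(f"{self.id}: empty exon [{s},{e})")
            if s < self.start or e > self.end:
                raise DomainError(f"{self.id}: exon [{s},{e}) outside [{self.start},{self.end})")
            if prev_end is not None and s < prev_end:
                raise DomainError(f"{self.id}: exons unsorted or overlapping")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def tss(self) -> int:
        """Transcription start coordinate (strand aware; half-open bound on '-')."""
        return self.start if self.strand == "+" else self.end

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class CategoryCall:
    """Positional classification of one lncRNA (possibly multi-label)."""

    lncrna_id: str
    labels: frozenset[str]
    primary: str

    def __post_init__(self):
        if not self.labels:
            raise DomainError(f"{self.lncrna_id}: empty label set")
        if "intergenic" in self.labels and len(self.labels) > 1:
            raise DomainError(f"{self.lncrna_id}: intergenic must be exclusive")
        if self.primary not in self.labels:
            raise DomainError(f"{self.lncrna_id}: primary not in labels")


@dataclass(frozen=True)
class CisPair:
    """A coding gene within the cis window of a lncRNA."""

    lncrna_id: str
    gene_id: str
    distance_bp: int
    relative_position: str  # upstream | downstream | overlapping

    def __post_init__(self):
        if self.distance_bp < 0:
            raise DomainError("distance_bp must be >= 0")


def _spans_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def _exon_chains_overlap(a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]) -> bool:
    """True if any interval of a overlaps any interval of b (both sorted)."""
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i][0] < b[j][1] and b[j][0] < a[i][1]:
            return True
        if a[i][1] <= b[j][0]:
            i += 1
        else:
            j += 1
    return False


def _labels_vs_gene(lnc: TranscriptRecord, gene: TranscriptRecord,
                    bidir_window_bp: int) -> set[str]:
    labels: set[str] = set()
    if gene.chrom != lnc.chrom:
        return labels
    if _spans_overlap(lnc.start, lnc.end, gene.start, gene.end):
        same = gene.strand == lnc.strand
        if _exon_chains_overlap(lnc.exons, gene.exons):
            labels.add("exon_overlapping" if same else "natural_antisense")
        else:
            labels.add("intron_overlapping" if same else "intron_antisense")
    elif gene.strand != lnc.strand:
        # Divergent promoters: the two TSSs face away from each other with a
        # small (or zero) gap and no overlap.
        if lnc.strand == "-" and gene.strand == "+":
            gap = gene.start - lnc.end
        else:  # lnc '+', gene '-': gene must lie to the left
            gap = lnc.start - gene.end
        if 0 <= gap <= bidir_window_bp:
            labels.add("bidirectional")
    return labels


def classify_lncrna(lnc: TranscriptRecord, coding: Iterable[TranscriptRecord],
                    bidir_window_bp: int = 1000) -> CategoryCall:
    """Classify one lncRNA against a collection of protein-coding genes.

    Rules (per gene, strand aware): exonic base overlap -> exon_overlapping
    (sense) / natural_antisense; span overlap confined to introns ->
    intron_overlapping / intron_antisense; no overlap but divergent TSSs
    within ``bidir_window_bp`` -> bidirectional.  No label from any gene ->
    intergenic (exclusive).  "Exonic" means lncRNA-exon vs gene-exon base
    overlap.
    """
    if lnc.rna_type != "lncRNA":
        raise DomainError(f"{lnc.id}: not a lncRNA")
    labels: set[str] = set()
    for gene in coding:
        labels |= _labels_vs_gene(lnc, gene, bidir_window_bp)
    if not labels:
        labels = {"intergenic"}
    primary = next(c for c in CATEGORY_PRECEDENCE if c in labels)
    return CategoryCall(lnc.id, frozenset(labels), primary)


class _GeneIndex:
    """Per-chromosome sorted gene lists for window queries."""

    def __init__(self, genes: Iterable[TranscriptRecord]):
        self.by_chrom: dict[str, list[TranscriptRecord]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        self.starts: dict[str, list[int]] = {}
        self.max_len: dict[str, int] = {}
        for chrom, lst in self.by_chrom.items():
            lst.sort(key=lambda g: (g.start, g.end, g.id))
            self.starts[chrom] = [g.start for g in lst]
            self.max_len[chrom] = max(g.end - g.start for g in lst)

    def window(self, chrom: str, lo: int, hi: int) -> list[TranscriptRecord]:
        """Genes possibly intersecting [lo, hi) on chrom."""
        if chrom not in self.by_chrom:
            return []
        starts = self.starts[chrom]
        left = bisect_left(starts, lo - self.max_len[chrom])
        right = bisect_right(starts, hi)
        return [g for g in self.by_chrom[chrom][left:right] if g.end > lo]


@dataclass
class ClassificationSummary:
    """Per-lncRNA calls plus the aggregate views shown in the field's figures."""

    calls: list[CategoryCall]
    category_counts: Counter = field(default_factory=Counter)
    venn_counts: Counter = field(default_factory=Counter)  # keyed by sorted label tuple
    percentages: dict = field(default_factory=dict)


def classify_all(lncs: Sequence[TranscriptRecord], coding: Sequence[TranscriptRecord],
                 bidir_window_bp: int = 1000) -> ClassificationSummary:
    """Classify every lncRNA; return calls, per-category totals (every label
    occurrence counts), Venn partition counts (by exact label set) and
    percentages over all classified lncRNAs."""
    index = _GeneIndex(coding) if coding else None
    calls: list[CategoryCall] = []
    for lnc in lncs:
        if index is None:
            candidates: list[TranscriptRecord] = []
        else:
            candidates = index.window(lnc.chrom, lnc.start - bidir_window_bp,
                                      lnc.end + bidir_window_bp)
        calls.append(classify_lncrna(lnc, candidates, bidir_window_bp))
    cat = Counter()
    venn = Counter()
    for c in calls:
        for lab in c.labels:
            cat[lab] += 1
        venn[tuple(sorted(c.labels))] += 1
    n = len(calls)
    pct = {lab: (100.0 * cat[lab] / n if n else 0.0) for lab in CATEGORY_PRECEDENCE}
    return ClassificationSummary(calls, cat, venn, pct)


def _gap(lnc: TranscriptRecord, gene: TranscriptRecord) -> int:
    if _spans_overlap(lnc.start, lnc.end, gene.start, gene.end):
        return 0
    if gene.start >= lnc.end:
        return gene.start - lnc.end
    return lnc.start - gene.end


def _relative_position(lnc: TranscriptRecord, gene: TranscriptRecord) -> str:
    if _spans_overlap(lnc.start, lnc.end, gene.start, gene.end):
        return "overlapping"
    right_of_lnc = gene.start >= lnc.end
    if lnc.strand == "+":
        return "downstream" if right_of_lnc else "upstream"
    return "upstream" if right_of_lnc else "downstream"


def cis_neighbors(lnc: TranscriptRecord, coding: Sequence[TranscriptRecord],
                  window_bp: int = 300_000) -> list[CisPair]:
    """Coding genes on the same chromosome with nearest-edge gap < window_bp.

    Overlapping genes count with distance 0.  Sorted by (distance, gene_id).
    """
    pairs = []
    for gene in coding:
        if gene.chrom != lnc.chrom:
            continue
        d = _gap(lnc, gene)
        if d < window_bp:
            pairs.append(CisPair(lnc.id, gene.id, d, _relative_position(lnc, gene)))
    pairs.sort(key=lambda p: (p.distance_bp, p.gene_id))
    return pairs


def cis_neighbors_all(lncs: Sequence[TranscriptRecord], coding: Sequence[TranscriptRecord],
                      window_bp: int = 300_000) -> list[CisPair]:
    """cis_neighbors for many lncRNAs using an interval index."""
    index = _GeneIndex(coding) if coding else None
    out: list[CisPair] = []
    for lnc in lncs:
        cands = index.window(lnc.chrom, lnc.start - window_bp, lnc.end + window_bp) \
            if index else []
        out.extend(cis_neighbors(lnc, cands, window_bp))
    return out
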