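"""Trans-regulation and ceRNA prediction.

Trans arm: transcription-factor position frequency matrices (PFMs) are turned
into log-odds position weight matrices (bits, pseudocount 0.25), lncRNA
promoters are scanned on both strands, and a hit is kept when its E-value —
the expected number of background positions scoring at least as high over the
whole scan — is below a gate (0.01).  TF-lncRNA edges feed a hypergeometric
enrichment of each lncRNA's co-expressed genes against each TF's target set,
and the surviving (lncRNA, TF) pairs expand into lncRNA-TF-gene triples.

ceRNA arm: canonical miRNA seed sites (6mer, 7mer-A1, 7mer-m8, 8mer; no GU
wobble) are located on lncRNA/circRNA/mRNA sequences (circular targets are
scanned across the back-splice junction), and a (noncoding, miRNA, mRNA)
triple is emitted whenever the same miRNA has at least one site on both a DE
noncoding transcript and a DE mRNA.

PWM scores are quantized to integer milli-bits at construction; scanning, the
E-value dynamic program and score comparisons all run on the integer grid, so
tail probabilities are exactly reproducible by word enumeration.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .diffexpr import bh_adjust
from .errors import ConfigurationError, DomainError

DNA = "ACGT"
RNA_BASES = "ACGU"
_DNA_INDEX = {b: i for i, b in enumerate(DNA)}
_DNA_COMP = str.maketrans("ACGT", "TGCA")
_RNA_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: integer quantization of PWM bit scores (milli-bits)
PWM_SCALE = 1000


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Position frequency / weight matrices
# ---------------------------------------------------------------------------

@dataclass
class PFM:
    """Count matrix for a TF motif: 4 rows (A, C, G, T) x width columns."""

    tf_name: str
    counts: np.ndarray
    pseudocount: float = 0.25

    def __post_init__(self):
        self.counts = np.asarray(self.counts, float)
        if self.counts.shape[0] != 4 or self.counts.ndim != 2:
            raise DomainError(f"{self.tf_name}: counts must be 4 x width")
        if self.width < 4:
            raise DomainError(f"{self.tf_name}: width must be >= 4")
        if (self.counts < 0).any():
            raise DomainError(f"{self.tf_name}: negative counts")
        if (self.counts.sum(axis=0) <= 0).any():
            raise DomainError(f"{self.tf_name}: zero column")
        if self.pseudocount < 0:
            raise DomainError(f"{self.tf_name}: negative pseudocount")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(DNA[i] for i in self.counts.argmax(axis=0))


@dataclass
class PWM:
    """Log-odds weight matrix in bits, with an exact integer (milli-bit) view."""

    tf_name: str
    weights: np.ndarray  # float bits, 4 x width
    qweights: np.ndarray  # int milli-bits, 4 x width
    background: np.ndarray  # base frequencies, length 4
    scale: int = PWM_SCALE
    _dist: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.qweights.max(axis=0).sum() / self.scale)

    @property
    def min_score(self) -> float:
        return float(self.qweights.min(axis=0).sum() / self.scale)


def _check_background(background) -> np.ndarray:
    bg = np.asarray(
        [0.25, 0.25, 0.25, 0.25] if background is None else background, float
    )
    if bg.shape != (4,) or (bg <= 0).any() or abs(bg.sum() - 1.0) > 1e-9:
        raise DomainError("background must be 4 positive frequencies summing to 1")
    return bg


def pfm_log_odds(pfm: PFM, background=None) -> PWM:
    """weight[b][i] = log2( (counts[b][i]+pc) / (colsum_i + 4*pc) / bg[b] )."""
    bg = _check_background(background)
    colsum = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pfm.pseudocount) / (colsum + 4 * pfm.pseudocount)
    if (probs <= 0).any():
        raise DomainError(f"{pfm.tf_name}: zero probability cell (pseudocount 0)")
    weights = np.log2(probs / bg[:, None])
    q = np.rint(weights * PWM_SCALE).astype(np.int64)
    return PWM(pfm.tf_name, q / PWM_SCALE, q, bg)


# ---------------------------------------------------------------------------
# Promoter scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoredPosition:
    offset: int  # 0-based, forward-strand coordinates of the window start
    strand: str
    score: float
    ambiguous: bool = False


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    lncrna_id: str
    offset: int
    strand: str
    score: float
    e_value: float


_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(DNA):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _qscores(pwm: PWM, codes: np.ndarray) -> np.ndarray:
    """Integer window scores at every offset; ambiguous bases contribute the
    background-expected column weight."""
    w = pwm.width
    expected = np.rint(pwm.background @ pwm.qweights).astype(np.int64)
    qx = np.vstack([pwm.qweights, expected[None, :]])  # row 4 = ambiguous
    codes = np.where(codes < 0, 4, codes).astype(np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    return qx[windows, np.arange(w)].sum(axis=1)


def scan_promoter(pwm: PWM, promoter_sequence: str,
                  both_strands: bool = True) -> list[ScoredPosition]:
    """Score every window of the promoter; reverse-strand windows are
    reported at their forward-strand start offset.  Ordered by offset."""
    L = len(promoter_sequence)
    if L < pwm.width:
        raise DomainError("promoter shorter than PWM width")
    codes = _encode(promoter_sequence)
    amb = codes < 0
    out = []
    fwd = _qscores(pwm, codes)
    w = pwm.width
    for off in range(fwd.size):
        out.append(ScoredPosition(off, "+", fwd[off] / pwm.scale,
                                  bool(amb[off:off + w].any())))
    if both_strands:
        rc = _qscores(pwm, _encode(revcomp_dna(promoter_sequence)))
        for j in range(rc.size):
            off = L - w - j
            out.append(ScoredPosition(off, "-", rc[j] / pwm.scale,
                                      bool(amb[off:off + w].any())))
    out.sort(key=lambda s: (s.offset, s.strand))
    return out


# ---------------------------------------------------------------------------
# Exact background score distribution and E-values
# ---------------------------------------------------------------------------

def _score_distribution(pwm: PWM) -> tuple[int, np.ndarray]:
    """(min_sum, tail) where tail[i] = P(score_int >= min_sum + i) for a
    single random background position; exact dynamic program over the
    integer column weights."""
    if pwm._dist is not None:
        return pwm._dist
    q = pwm.qweights
    bg = pwm.background
    cur = np.array([1.0])
    cur_min = 0
    for i in range(pwm.width):
        col = q[:, i]
        lo = int(col.min())
        hi = int(col.max())
        new = np.zeros(len(cur) + hi - lo)
        for b in range(4):
            off = int(col[b]) - lo
            new[off:off + len(cur)] += bg[b] * cur
        cur = new
        cur_min += lo
    tail = np.cumsum(cur[::-1])[::-1]
    pwm._dist = (cur_min, tail)
    return pwm._dist


def _tail_probability(pwm: PWM, qthreshold: int) -> float:
    cur_min, tail = _score_distribution(pwm)
    idx = qthreshold - cur_min
    if idx <= 0:
        return 1.0
    if idx >= tail.size:
        return 0.0
    return float(tail[idx])


def site_evalue(score_threshold: float, pwm: PWM, background=None,
                n_positions_scanned: int = 1) -> float:
    """Expected number of background positions scoring >= threshold over the
    scanned positions: E = P(one position >= t) * n."""
    if n_positions_scanned < 1:
        raise DomainError("n_positions_scanned must be >= 1")
    if background is not None:
        bg = _check_background(background)
        if not np.allclose(bg, pwm.background):
            pwm = PWM(pwm.tf_name, pwm.weights, pwm.qweights, bg, pwm.scale)
    qt = int(round(score_threshold * pwm.scale))
    return _tail_probability(pwm, qt) * n_positions_scanned


# ---------------------------------------------------------------------------
# TF-lncRNA network
# ---------------------------------------------------------------------------

@dataclass
class TFNetwork:
    hits: list  # MotifHit, e_value < e_max only
    edges: list  # sorted (tf_name, lncrna_id)
    n_tfs: int
    n_lncrnas: int
    n_edges: int
    n_positions_by_tf: dict

    @property
    def summary(self) -> str:
        return (f"{self.n_tfs} TFs and {self.n_lncrnas} correlated lncRNAs, "
                f"connected by {self.n_edges} edges")


def build_tf_lncrna_network(pfms: Sequence[PFM], promoters: Mapping[str, str],
                            e_max: float = 0.01, background=None,
                            both_strands: bool = True) -> TFNetwork:
    """Scan every promoter with every PFM; an edge (TF, lncRNA) exists when
    at least one hit has E < e_max.  The E-value of a hit counts expected
    background hits at or above its score across all positions scanned for
    that TF (all promoters, both strands)."""
    bg = _check_background(background)
    promoter_ids = sorted(promoters)
    hits: list[MotifHit] = []
    edges: set[tuple[str, str]] = set()
    n_positions_by_tf: dict[str, int] = {}
    strands = 2 if both_strands else 1
    for pfm in pfms:
        pwm = pfm_log_odds(pfm, bg)
        w = pwm.width
        for pid in promoter_ids:
            if len(promoters[pid]) < w:
                raise DomainError(
                    f"promoter {pid!r} shorter than PFM {pfm.tf_name!r}")
        n_positions = sum(strands * (len(promoters[p]) - w + 1)
                          for p in promoter_ids)
        n_positions_by_tf[pfm.tf_name] = n_positions
        cur_min, tail = _score_distribution(pwm)
        # Speed prefilter: minimum integer score that could possibly pass the
        # E gate (with ulp slack; the exact check below decides).
        qmin_pass = cur_min + int(np.searchsorted(
            -tail, -(e_max * (1 + 1e-9) / max(n_positions, 1)), side="right"))
        for pid in promoter_ids:
            for sp in scan_promoter(pwm, promoters[pid], both_strands):
                qs = int(round(sp.score * pwm.scale))
                if qs < qmin_pass:
                    continue
                e = _tail_probability(pwm, qs) * n_positions
                if e < e_max:
                    hits.append(MotifHit(pfm.tf_name, pid, sp.offset, sp.strand,
                                         sp.score, e))
                    edges.add((pfm.tf_name, pid))
    edge_list = sorted(edges)
    return TFNetwork(hits, edge_list,
                     len({t for t, _ in edge_list}),
                     len({l for _, l in edge_list}),
                     len(edge_list), n_positions_by_tf)


# ---------------------------------------------------------------------------
# TF target enrichment and the ternary network
# ---------------------------------------------------------------------------

def tf_target_enrichment(coexpr_genes: Iterable[str], tf_target_genes: Iterable[str],
                         universe_size: int) -> tuple[list[str], float]:
    """Hypergeometric upper-tail p of the overlap between a lncRNA's
    co-expressed gene set and a TF's target set within a common universe.
    Returns (sorted overlap genes, p); the BH q across all tested
    (lncRNA, TF) pairs is computed by build_ternary_network, which owns
    the family."""
    if universe_size <= 0:
        raise DomainError("empty universe")
    a = set(coexpr_genes)
    b = set(tf_target_genes)
    if len(a) > universe_size or len(b) > universe_size:
        raise DomainError("set larger than universe")
    overlap = sorted(a & b)
    p = float(stats.hypergeom.sf(len(overlap) - 1, universe_size, len(b), len(a)))
    return overlap, p


@dataclass
class TernaryNetwork:
    triples: list  # sorted (lncrna, tf, gene)
    enrichment: list  # (lncrna, tf, k, p, q, passes)
    n_lncrnas: int
    n_tfs: int
    n_genes: int

    @property
    def summary(self) -> str:
        return (f"{self.n_lncrnas} lncRNAs, {self.n_tfs} TFs, and "
                f"{self.n_genes} correlated genes")


def build_ternary_network(cnc_edges: Sequence, tf_lnc_edges: Sequence[tuple[str, str]],
                          tf_target_map: Mapping[str, Iterable[str]],
                          universe: Iterable[str], r_min: float = 0.9,
                          q_max: float = 0.05, enrich_p_max: float = 0.01,
                          enrich_q_max: float = 0.01) -> TernaryNetwork:
    """lncRNA-TF-gene triples: TF binds the lncRNA promoter, the gene is
    co-expressed with the lncRNA (|r| >= r_min, FDR <= q_max), the gene is a
    target of the TF, and the (lncRNA, TF) target enrichment passes
    p < enrich_p_max and BH q < enrich_q_max across all tested pairs."""
    universe = set(universe)
    coexpr: dict[str, set[str]] = defaultdict(set)
    for e in cnc_edges:
        if abs(e.r) >= r_min and e.q <= q_max and e.coding_id in universe:
            coexpr[e.nc_id].add(e.coding_id)
    pairs = sorted({(lnc, tf) for tf, lnc in tf_lnc_edges})
    rows = []
    for lnc, tf in pairs:
        targets = set(tf_target_map.get(tf, ())) & universe
        overlap, p = tf_target_enrichment(coexpr.get(lnc, set()), targets,
                                          len(universe)) if universe else ([], 1.0)
        rows.append((lnc, tf, overlap, p))
    qs = bh_adjust([r[3] for r in rows]) if rows else []
    enrichment = []
    triples = []
    for (lnc, tf, overlap, p), q in zip(rows, qs):
        passes = p < enrich_p_max and q < enrich_q_max
        enrichment.append((lnc, tf, len(overlap), float(p), float(q), passes))
        if passes:
            triples.extend((lnc, tf, g) for g in overlap)
    triples.sort()
    return TernaryNetwork(
        triples, enrichment,
        len({t[0] for t in triples}), len({t[1] for t in triples}),
        len({t[2] for t in triples}),
    )


# ---------------------------------------------------------------------------
# miRNA seed matching and the ceRNA network
# ---------------------------------------------------------------------------

SITE_TYPES = ("8mer", "7mer_m8", "7mer_A1", "6mer")  # strongest first


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    target_id: str
    offset: int  # 0-based start of the site on the target (wraps if circular)
    site_type: str


def _check_rna(seq: str, what: str):
    if set(seq) - set(RNA_BASES):
        raise DomainError(f"{what}: non-RNA alphabet")


def seed_site_strings(mirna_sequence: str) -> dict[str, str]:
    """The four canonical site strings (as they read 5'->3' on the target)."""
    m = mirna_sequence
    core = revcomp_rna(m[1:7])  # pairs miRNA positions 2-7
    m8c = _RNA_COMP[m[7]]
    return {
        "6mer": core,
        "7mer_A1": core + "A",
        "7mer_m8": m8c + core,
        "8mer": m8c + core + "A",
    }


def find_seed_sites(mirna_sequence: str, target_sequence: str,
                    circular: bool = False, mirna_id: str = "miRNA",
                    target_id: str = "target") -> list[SeedSite]:
    """Locate canonical seed sites of one miRNA on one target.

    The target is matched against the reverse complement of miRNA positions
    2-7; a matching m8 base upstream and/or a target-encoded A downstream
    upgrade the site (7mer-m8 / 7mer-A1 / 8mer).  Each locus is reported once
    with its strongest type.  Circular targets wrap across the junction.
    """
    _check_rna(mirna_sequence, "miRNA")
    _check_rna(target_sequence, "target")
    if len(mirna_sequence) < 8:
        raise DomainError("miRNA must be >= 8 nt")
    L = len(target_sequence)
    if L < 6:
        return []
    core = revcomp_rna(mirna_sequence[1:7])
    m8c = _RNA_COMP[mirna_sequence[7]]
    ext = target_sequence + (target_sequence[:7] if circular else "")
    sites = []
    pos = ext.find(core)
    while pos != -1:
        if pos >= L:  # wrapped duplicate of an origin-proximal match
            break
        if pos > 0:
            prev = ext[pos - 1]
        elif circular:
            prev = target_sequence[-1]
        else:
            prev = None
        nxt = ext[pos + 6] if pos + 6 < len(ext) else None
        has_m8 = prev == m8c
        has_a1 = nxt == "A"
        if has_m8 and has_a1:
            stype, start = "8mer", pos - 1
        elif has_m8:
            stype, start = "7mer_m8", pos - 1
        elif has_a1:
            stype, start = "7mer_A1", pos
        else:
            stype, start = "6mer", pos
        sites.append(SeedSite(mirna_id, target_id, start % L, stype))
        pos = ext.find(core, pos + 1)
    sites.sort(key=lambda s: (s.offset, s.site_type))
    return sites


@dataclass(frozen=True)
class CeRNATriple:
    nc_id: str
    mirna_id: str
    mrna_id: str


@dataclass
class CeRNAResult:
    triples: list
    edges: list  # (node_a, node_b, relation) for export


def build_cerna(de_nc: Iterable[str], de_mrna: Iterable[str],
                seed_sites: Iterable[SeedSite]) -> CeRNAResult:
    """(nc, miRNA, mRNA) triples where the same miRNA has >= 1 seed site on
    both a DE noncoding transcript and a DE mRNA; exported as nc-miRNA and
    miRNA-mRNA edges."""
    de_nc = set(de_nc)
    de_mrna = set(de_mrna)
    nc_by_mirna: dict[str, set[str]] = defaultdict(set)
    mrna_by_mirna: dict[str, set[str]] = defaultdict(set)
    for s in seed_sites:
        if s.target_id in de_nc:
            nc_by_mirna[s.mirna_id].add(s.target_id)
        if s.target_id in de_mrna:
            mrna_by_mirna[s.mirna_id].add(s.target_id)
    triples = []
    edges = set()
    for mir in sorted(set(nc_by_mirna) & set(mrna_by_mirna)):
        for nc in sorted(nc_by_mirna[mir]):
            for mr in sorted(mrna_by_mirna[mir]):
                triples.append(CeRNATriple(nc, mir, mr))
                edges.add((nc, mir, "mirna_site"))
                edges.add((mir, mr, "mirna_site"))
    triples.sort(key=lambda t: (t.nc_id, t.mirna_id, t.mrna_id))
    return CeRNAResult(triples, sorted(edges))
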