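"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here recomputes a quantity by direct enumeration / textbook
formula, deliberately avoiding the code paths (and, where feasible, the
libraries) used by the implementation.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
from scipy.integrate import quad


# --- Benjamini-Hochberg ----------------------------------------------------

def bh_oracle(pvalues):
    """q_(i) = min_{j>=i}(p_(j) * m / j) by direct double loop."""
    p = list(map(float, pvalues))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_i, idx in enumerate(order, start=1):
        best = math.inf
        for rank_j in range(rank_i, m + 1):
            best = min(best, p[order[rank_j - 1]] * m / rank_j)
        q[idx] = min(best, 1.0)
    return q


# --- Student t -------------------------------------------------------------

def t_sf_oracle(t, df):
    """P(T >= t) by numeric integration of the hand-written t density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def dens(x):
        return c * (1 + x * x / df) ** (-(df + 1) / 2)

    val, _ = quad(dens, t, np.inf)
    return val


def t_two_tailed_oracle(t, df):
    return 2.0 * t_sf_oracle(abs(t), df)


def pooled_t_stat(a, b):
    """Textbook pooled-variance two-sample t statistic (b minus a)."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    return (mb - ma) / math.sqrt(sp2 * (1 / na + 1 / nb))


# --- Pearson ---------------------------------------------------------------

def pearson_oracle(x, y):
    """Textbook covariance / sigma formula."""
    x, y = list(map(float, x)), list(map(float, y))
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def corr_pvalue_oracle(r, n):
    if abs(r) >= 1:
        return 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return t_two_tailed_oracle(t, n - 2)


# --- Hypergeometric --------------------------------------------------------

def hypergeom_tail_enum(k, K, n, N):
    """P(X >= k) by exact summation over the support with math.comb."""
    denom = math.comb(N, n)
    total = 0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(N - K, n - x)
    return total / denom


# --- lncRNA classification -------------------------------------------------

def classify_oracle(lnc, genes, bidir_window_bp=1000):
    """Label set via explicit per-base coordinate sets."""
    lnc_exonic = set()
    for s, e in lnc.exons:
        lnc_exonic |= set(range(s, e))
    labels = set()
    for g in genes:
        if g.chrom != lnc.chrom:
            continue
        g_span = set(range(g.start, g.end))
        l_span = set(range(lnc.start, lnc.end))
        if l_span & g_span:
            g_exonic = set()
            for s, e in g.exons:
                g_exonic |= set(range(s, e))
            same = g.strand == lnc.strand
            if lnc_exonic & g_exonic:
                labels.add("exon_overlapping" if same else "natural_antisense")
            else:
                labels.add("intron_overlapping" if same else "intron_antisense")
        elif g.strand != lnc.strand:
            if lnc.strand == "-" and g.strand == "+":
                gap = g.start - lnc.end
            else:
                gap = lnc.start - g.end
            if 0 <= gap <= bidir_window_bp:
                labels.add("bidirectional")
    return labels or {"intergenic"}


def cis_oracle(lnc, genes, window_bp=300_000):
    """(gene_id, distance) pairs by exhaustive all-pairs distance scan."""
    out = []
    for g in genes:
        if g.chrom != lnc.chrom:
            continue
        if set(range(g.start, g.end)) & set(range(lnc.start, lnc.end)):
            d = 0
        elif g.start >= lnc.end:
            d = g.start - lnc.end
        else:
            d = lnc.start - g.end
        if d < window_bp:
            out.append((g.id, d))
    return sorted(out, key=lambda t: (t[1], t[0]))


# --- PWM scanning ----------------------------------------------------------

_DNA = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))


def scan_scores_oracle(pwm, seq, both_strands=True):
    """{(offset, strand): integer score} by per-position summation."""
    w = pwm.width
    out = {}
    for off in range(len(seq) - w + 1):
        win = seq[off:off + w]
        out[(off, "+")] = sum(int(pwm.qweights[_DNA.index(b), i])
                              for i, b in enumerate(win))
        if both_strands:
            rc = _revcomp(win)
            out[(off, "-")] = sum(int(pwm.qweights[_DNA.index(b), i])
                                  for i, b in enumerate(rc))
    return out


def pwm_tail_enum(pwm, qthreshold):
    """P(score >= threshold) by exhaustive enumeration of all 4^w words."""
    w = pwm.width
    bg = pwm.background
    total = 0.0
    for word in product(range(4), repeat=w):
        score = sum(int(pwm.qweights[b, i]) for i, b in enumerate(word))
        if score >= qthreshold:
            prob = 1.0
            for b in word:
                prob *= bg[b]
            total += prob
    return total


# --- miRNA seed sites ------------------------------------------------------

_RC_RNA = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _revcomp_rna(seq):
    return "".join(_RC_RNA[b] for b in reversed(seq))


def seed_sites_oracle(mirna, target, circular=False):
    """{(offset, type)} by literal comparison of the four site strings at
    every position (strongest type wins at each seed locus)."""
    core = _revcomp_rna(mirna[1:7])
    m8c = _RC_RNA[mirna[7]]
    strings = {
        "8mer": m8c + core + "A",
        "7mer_m8": m8c + core,
        "7mer_A1": core + "A",
        "6mer": core,
    }
    L = len(target)
    ext = target + (target[:8] if circular else "")
    found = {}
    # iterate over every possible core locus (core start position c < L)
    for c in range(L if circular else L - 5):
        if ext[c:c + 6] != core:
            continue
        if circular:
            prev = ext[c - 1] if c > 0 else target[-1]
        else:
            prev = ext[c - 1] if c > 0 else None
        nxt = ext[c + 6] if c + 6 < len(ext) else None
        if prev == m8c and nxt == "A":
            found[c] = ((c - 1) % L, "8mer")
        elif prev == m8c:
            found[c] = ((c - 1) % L, "7mer_m8")
        elif nxt == "A":
            found[c] = (c % L, "7mer_A1")
        else:
            found[c] = (c % L, "6mer")
    return set(found.values())


# --- pathway-gene edges ----------------------------------------------------

def pathway_edges_oracle(term_members, significant_terms, de_genes):
    """Direct set-intersection construction of the bipartite edge list."""
    de = set(de_genes)
    edges = set()
    for t in significant_terms:
        for g in set(term_members[t]) & de:
            edges.add((t, g))
    return sorted(edges)
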