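"""Synthetic inputs with planted, recorded ground truth.

The generator stands in for a two-group (3 control vs 3 case) expression
microarray experiment measuring mRNAs, lncRNAs and circRNAs, together with
the annotation, sequence, motif and term resources the downstream pipeline
consumes.  Everything planted is recorded in a :class:`SyntheticTruth` so
each pipeline stage can be checked for recovery.

What is planted
---------------
* log-normal intensities (Normal in log2, exponentiated) with a +/-2 log2
  group effect on a chosen fraction of probes;
* co-expressed noncoding/coding pairs whose members share a per-sample latent
  factor.  The latent factor *replaces* most of the independent noise
  (residual sd 0.05 of the 0.25 total), so the members keep full DE power at
  n=3+3 while the pooled pair correlation is ~0.998 — comfortably above the
  0.90 network gate.  Negative pairs use opposite DE directions;
* one co-regulated "module": a lncRNA plus a block of coding genes sharing
  one latent factor, wired to a TF (motif in the lncRNA promoter, module
  genes in the TF target set) — the planted trans-regulation chain;
* one ceRNA module: a miRNA with seed sites on one lncRNA, one circRNA and
  three mRNAs (all DE), including a site across the circRNA back-splice
  junction.  These five sequences are scrubbed of chance seed cores so the
  planted combinatorics are exact; all other sequences keep background sites;
* genomic exemplars of all six lncRNA positional categories, one multi-label
  crossover case, and cis pairs at 295 kb (inside the window) and 305 kb
  (outside);
* informative PFMs with their consensus written into selected DE-lncRNA
  promoters; one term whose gene set is over-represented among DE mRNAs.

Fixing the seed fixes every output byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .errors import ConfigurationError
from .genome import TranscriptRecord
from .regulatory import PFM, revcomp_dna, revcomp_rna, seed_site_strings, \
    find_seed_sites

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"


@dataclass
class SimConfig:
    """Stated world of the simulator.  Defaults mirror the study design:
    3 vs 3 samples, fold change 4 (2 log2 units) on 10% of probes, log-normal
    noise with sd 0.25 log2 units."""

    seed: int = 0
    n_per_group: int = 3
    n_mrna: int = 2000
    n_lncrna: int = 300
    n_circrna: int = 150
    frac_de: float = 0.1
    planted_log2fc: float = 2.0
    noise_sd: float = 0.25
    n_coexpr_pairs: int = 10
    n_mirna: int = 10
    n_tf: int = 8
    genome_length_bp: int = 30_000_000  # per chromosome
    n_chromosomes: int = 4
    # sequence / motif geometry
    utr_len: int = 500
    lnc_len: int = 800
    circ_len: int = 400
    mirna_len: int = 22
    promoter_len: int = 2200  # [TSS-2000, TSS+200)
    pfm_width: int = 14
    n_terms: int = 30
    module_size: int = 20
    coexpr_resid_sd: float = 0.05
    base_probs: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be >= 2")
        for name in ("n_mrna", "n_lncrna", "n_circrna", "n_coexpr_pairs",
                     "n_mirna", "n_tf", "n_terms"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigurationError("frac_de must be in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.mirna_len < 8:
            raise ConfigurationError("mirna_len must be >= 8")
        if self.pfm_width > self.promoter_len:
            raise ConfigurationError("PFM wider than promoter")
        if min(self.utr_len, self.lnc_len, self.circ_len) < 16:
            raise ConfigurationError("host sequences too short for seed sites")
        p = np.asarray(self.base_probs, float)
        if p.shape != (4,) or (p <= 0).any() or abs(p.sum() - 1) > 1e-9:
            raise ConfigurationError("base_probs must be 4 positive freqs summing to 1")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - fields
        if unknown:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(unknown)}")
        return cls(**mapping)


@dataclass
class SyntheticTruth:
    """Everything planted, for recovery tests."""

    de_ids_up: set = field(default_factory=set)
    de_ids_down: set = field(default_factory=set)
    coexpr_pairs: set = field(default_factory=set)  # (nc, coding, sign)
    category_by_lncrna: dict = field(default_factory=dict)  # lnc -> set labels
    cis_pairs: set = field(default_factory=set)  # (lnc, gene, distance)
    noncis_pairs: set = field(default_factory=set)  # planted beyond the window
    motif_sites: set = field(default_factory=set)  # (tf, lnc, offset, strand)
    seed_sites: set = field(default_factory=set)  # (mirna, target, offset, type)
    enriched_term: str | None = None
    tf_targets: dict = field(default_factory=dict)  # tf -> set of gene ids
    ternary_chains: set = field(default_factory=set)  # (lnc, tf, gene)
    cerna_module: dict = field(default_factory=dict)
    module_lncrna: str | None = None
    module_genes: list = field(default_factory=list)
    module_tf: str | None = None

    def to_jsonable(self) -> dict:
        return {
            "de_ids_up": sorted(self.de_ids_up),
            "de_ids_down": sorted(self.de_ids_down),
            "coexpr_pairs": sorted(map(list, self.coexpr_pairs)),
            "category_by_lncrna": {k: sorted(v)
                                   for k, v in sorted(self.category_by_lncrna.items())},
            "cis_pairs": sorted(map(list, self.cis_pairs)),
            "noncis_pairs": sorted(map(list, self.noncis_pairs)),
            "motif_sites": sorted(map(list, self.motif_sites)),
            "seed_sites": sorted(map(list, self.seed_sites)),
            "enriched_term": self.enriched_term,
            "tf_targets": {k: sorted(v) for k, v in sorted(self.tf_targets.items())},
            "ternary_chains": sorted(map(list, self.ternary_chains)),
            "cerna_module": self.cerna_module,
            "module_lncrna": self.module_lncrna,
            "module_genes": list(self.module_genes),
            "module_tf": self.module_tf,
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "SyntheticTruth":
        return cls(
            de_ids_up=set(d["de_ids_up"]),
            de_ids_down=set(d["de_ids_down"]),
            coexpr_pairs={tuple(x) for x in d["coexpr_pairs"]},
            category_by_lncrna={k: set(v) for k, v in d["category_by_lncrna"].items()},
            cis_pairs={tuple(x) for x in d["cis_pairs"]},
            noncis_pairs={tuple(x) for x in d["noncis_pairs"]},
            motif_sites={tuple(x) for x in d["motif_sites"]},
            seed_sites={tuple(x) for x in d["seed_sites"]},
            enriched_term=d["enriched_term"],
            tf_targets={k: set(v) for k, v in d["tf_targets"].items()},
            ternary_chains={tuple(x) for x in d["ternary_chains"]},
            cerna_module=d["cerna_module"],
            module_lncrna=d["module_lncrna"],
            module_genes=list(d["module_genes"]),
            module_tf=d["module_tf"],
        )


def mrna_ids(config: SimConfig) -> list[str]:
    return [f"MRNA_{i:04d}" for i in range(1, config.n_mrna + 1)]


def lncrna_ids(config: SimConfig) -> list[str]:
    return [f"LNC_{i:04d}" for i in range(1, config.n_lncrna + 1)]


def circrna_ids(config: SimConfig) -> list[str]:
    return [f"CIRC_{i:04d}" for i in range(1, config.n_circrna + 1)]


def mirna_ids(config: SimConfig) -> list[str]:
    return [f"MIR_{i:03d}" for i in range(1, config.n_mirna + 1)]


def tf_names(config: SimConfig) -> list[str]:
    return [f"TF_{i:02d}" for i in range(1, config.n_tf + 1)]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _split_de(rng: np.random.Generator, ids: Sequence[str], frac: float):
    n_de = int(round(frac * len(ids)))
    chosen = [ids[i] for i in rng.permutation(len(ids))[:n_de]]
    half = (n_de + 1) // 2
    return chosen[:half], chosen[half:]


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression(config: SimConfig,
                        truth: SyntheticTruth | None = None
                        ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Linear intensities 2**(baseline + group_effect + noise) with planted
    DE probes, co-expressed pairs, the trans-regulation module and the ceRNA
    module members chosen among the DE probes."""
    truth = truth or SyntheticTruth()
    rng = _rng(config, 1)
    all_ids = mrna_ids(config) + lncrna_ids(config) + circrna_ids(config)
    types = (["mRNA"] * config.n_mrna + ["lncRNA"] * config.n_lncrna
             + ["circRNA"] * config.n_circrna)
    n_probes = len(all_ids)
    if n_probes == 0:
        raise ConfigurationError("no probes requested")
    n_s = 2 * config.n_per_group
    samples = [f"CTRL_{i+1}:control" for i in range(config.n_per_group)] + \
              [f"CASE_{i+1}:case" for i in range(config.n_per_group)]
    sample_ids = [s.split(":")[0] for s in samples]
    groups = pd.Series([s.split(":")[1] for s in samples], index=sample_ids)

    up_m, down_m = _split_de(rng, mrna_ids(config), config.frac_de)
    up_l, down_l = _split_de(rng, lncrna_ids(config), config.frac_de)
    up_c, down_c = _split_de(rng, circrna_ids(config), config.frac_de)
    truth.de_ids_up = set(up_m) | set(up_l) | set(up_c)
    truth.de_ids_down = set(down_m) | set(down_l) | set(down_c)

    # --- roles among the DE probes --------------------------------------
    up_m_pool = list(up_m)
    down_m_pool = list(down_m)
    up_l_pool = list(up_l)
    up_c_pool = list(up_c)
    up_nc_pool = list(up_l[1:]) + list(up_c[1:])  # keep first of each for modules
    down_nc_pool = list(down_l) + list(down_c)

    module_size = min(config.module_size, max(len(up_m_pool) - 5, 0))
    if up_l_pool and module_size >= 3:
        truth.module_lncrna = up_l_pool[0]
        truth.module_genes = up_m_pool[:module_size]
        up_m_pool = up_m_pool[module_size:]

    if len(up_l_pool) >= 2 and up_c_pool and len(up_m_pool) >= 3:
        truth.cerna_module = {
            "mirna": mirna_ids(config)[0] if config.n_mirna else None,
            "lncrna": up_l_pool[1],
            "circrna": up_c_pool[0],
            "mrnas": up_m_pool[:3],
        }
        up_m_pool = up_m_pool[3:]

    used_nc = {truth.module_lncrna,
               truth.cerna_module.get("lncrna"), truth.cerna_module.get("circrna")}
    up_nc_pool = [i for i in up_nc_pool if i not in used_nc]
    pairs = []
    for i in range(config.n_coexpr_pairs):
        if i % 2 == 0 and up_nc_pool and up_m_pool:
            pairs.append((up_nc_pool.pop(0), up_m_pool.pop(0), "positive"))
        elif i % 2 == 1 and up_nc_pool and down_m_pool:
            pairs.append((up_nc_pool.pop(0), down_m_pool.pop(0), "negative"))
    truth.coexpr_pairs = set(pairs)

    # --- assemble log2 values ------------------------------------------
    idx = {pid: i for i, pid in enumerate(all_ids)}
    base = rng.uniform(6.0, 12.0, n_probes)
    effect = np.zeros(n_probes)
    for pid in truth.de_ids_up:
        effect[idx[pid]] = config.planted_log2fc
    for pid in truth.de_ids_down:
        effect[idx[pid]] = -config.planted_log2fc

    sigma = np.full(n_probes, config.noise_sd)
    resid = min(config.coexpr_resid_sd, config.noise_sd / 2.0)
    w_latent = float(np.sqrt(config.noise_sd ** 2 - resid ** 2))
    latent_weight = np.zeros(n_probes)
    latent_group = np.full(n_probes, -1)

    group_no = 0
    if truth.module_lncrna:
        for pid in [truth.module_lncrna] + list(truth.module_genes):
            latent_group[idx[pid]] = group_no
            latent_weight[idx[pid]] = w_latent
            sigma[idx[pid]] = resid
        group_no += 1
    for nc, coding, sign in sorted(truth.coexpr_pairs):
        latent_group[idx[nc]] = group_no
        latent_weight[idx[nc]] = w_latent
        sigma[idx[nc]] = resid
        latent_group[idx[coding]] = group_no
        latent_weight[idx[coding]] = w_latent * (1 if sign == "positive" else -1)
        sigma[idx[coding]] = resid
        group_no += 1

    case_ind = np.array([0.0] * config.n_per_group + [1.0] * config.n_per_group)
    log2x = base[:, None] + effect[:, None] * case_ind[None, :]
    latents = rng.standard_normal((group_no, n_s)) if group_no else \
        np.zeros((0, n_s))
    has_latent = latent_group >= 0
    if has_latent.any():
        log2x[has_latent] += latent_weight[has_latent, None] * \
            latents[latent_group[has_latent]]
    log2x += rng.standard_normal((n_probes, n_s)) * sigma[:, None]

    values = pd.DataFrame(np.power(2.0, log2x),
                          index=pd.Index(all_ids, name="probe_id"),
                          columns=sample_ids)
    matrix = ExpressionMatrix(values, pd.Series(types, index=all_ids), groups)
    return matrix, truth


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

_BLOCK = 1_500_000  # planted-exemplar block: guards cross-block interactions
_TILE = 20_000      # filler feature tile


class _Allocator:
    def __init__(self, config: SimConfig):
        self.config = config
        self.chrom = 0
        self.pos = 0

    def take(self, size: int) -> tuple[str, int]:
        if self.pos + size > self.config.genome_length_bp:
            self.chrom += 1
            self.pos = 0
        if self.chrom >= self.config.n_chromosomes or \
                size > self.config.genome_length_bp:
            raise ConfigurationError("genome too small to place requested features")
        start = self.pos
        self.pos += size
        return f"chr{self.chrom + 1}", start


def _coding(gid: str, chrom: str, s: int, strand: str) -> TranscriptRecord:
    """Two-exon 20 kb gene: exons [s, s+2k) and [s+18k, s+20k)."""
    return TranscriptRecord(gid, gid, "mRNA", chrom, s, s + 20_000, strand,
                            ((s, s + 2000), (s + 18_000, s + 20_000)))


def _single_exon(tid: str, rna_type: str, chrom: str, s: int, length: int,
                 strand: str, circular: bool = False) -> TranscriptRecord:
    return TranscriptRecord(tid, tid, rna_type, chrom, s, s + length, strand,
                            is_circular=circular)


def simulate_genome(config: SimConfig,
                    truth: SyntheticTruth | None = None
                    ) -> tuple[list[TranscriptRecord], SyntheticTruth]:
    """Deterministic genome layout.

    The first nine lncRNAs (when available) are planted exemplars: one per
    positional category, one multi-label crossover, and cis pairs at 295 kb
    (inside the 300 kb window) and 305 kb (outside).  Remaining features are
    tiled with 20 kb spacing, interleaving coding genes with noncoding
    transcripts, all intergenic by construction.
    """
    truth = truth or SyntheticTruth()
    alloc = _Allocator(config)
    records: list[TranscriptRecord] = []
    lncs = lncrna_ids(config)
    genes = mrna_ids(config)
    circs = circrna_ids(config)
    used_lnc = 0
    used_gene = 0
    L = config.lnc_len

    def plant(n_lnc_needed: int, n_gene_needed: int) -> bool:
        return (used_lnc + n_lnc_needed <= len(lncs)
                and used_gene + n_gene_needed <= len(genes))

    if plant(9, 9):
        # 1. sense exon overlap
        chrom, base = alloc.take(_BLOCK)
        g, l = genes[used_gene], lncs[used_lnc]
        records.append(_coding(g, chrom, base + 10_000, "+"))
        records.append(_single_exon(l, "lncRNA", chrom, base + 11_000, 500, "+"))
        truth.category_by_lncrna[l] = {"exon_overlapping"}
        truth.cis_pairs.add((l, g, 0))
        used_gene += 1
        used_lnc += 1
        # 2. sense intron overlap
        chrom, base = alloc.take(_BLOCK)
        g, l = genes[used_gene], lncs[used_lnc]
        records.append(_coding(g, chrom, base + 10_000, "+"))
        records.append(_single_exon(l, "lncRNA", chrom, base + 15_000, 1000, "+"))
        truth.category_by_lncrna[l] = {"intron_overlapping"}
        truth.cis_pairs.add((l, g, 0))
        used_gene += 1
        used_lnc += 1
        # 3. natural antisense (exonic, opposite strand)
        chrom, base = alloc.take(_BLOCK)
        g, l = genes[used_gene], lncs[used_lnc]
        records.append(_coding(g, chrom, base + 10_000, "+"))
        records.append(_single_exon(l, "lncRNA", chrom, base + 11_000, 500, "-"))
        truth.category_by_lncrna[l] = {"natural_antisense"}
        truth.cis_pairs.add((l, g, 0))
        used_gene += 1
        used_lnc += 1
        # 4. intron antisense
        chrom, base = alloc.take(_BLOCK)
        g, l = genes[used_gene], lncs[used_lnc]
        records.append(_coding(g, chrom, base + 10_000, "+"))
        records.append(_single_exon(l, "lncRNA", chrom, base + 15_000, 1000, "-"))
        truth.category_by_lncrna[l] = {"intron_antisense"}
        truth.cis_pairs.add((l, g, 0))
        used_gene += 1
        used_lnc += 1
        # 5. bidirectional: divergent TSSs 400 bp apart, no overlap
        chrom, base = alloc.take(_BLOCK)
        g, l = genes[used_gene], lncs[used_lnc]
        records.append(_coding(g, chrom, base + 10_000, "+"))
        records.append(_single_exon(l, "lncRNA", chrom, base + 9600 - L, L, "-"))
        truth.category_by_lncrna[l] = {"bidirectional"}
        truth.cis_pairs.add((l, g, 400))
        used_gene += 1
        used_lnc += 1
        # 6. intergenic
        chrom, base = alloc.take(_BLOCK)
        l = lncs[used_lnc]
        records.append(_single_exon(l, "lncRNA", chrom, base + 10_000, L, "+"))
        truth.category_by_lncrna[l] = {"intergenic"}
        used_lnc += 1
        # 7. multi-label crossover: sense exon overlap with gene A AND
        #    antisense within gene B's intron
        chrom, base = alloc.take(_BLOCK)
        ga, gb, l = genes[used_gene], genes[used_gene + 1], lncs[used_lnc]
        records.append(_coding(ga, chrom, base + 10_000, "+"))
        records.append(TranscriptRecord(
            gb, gb, "mRNA", chrom, base + 5000, base + 45_000, "-",
            ((base + 5000, base + 7000), (base + 43_000, base + 45_000))))
        records.append(_single_exon(l, "lncRNA", chrom, base + 11_000, 500, "+"))
        truth.category_by_lncrna[l] = {"exon_overlapping", "intron_antisense"}
        truth.cis_pairs.add((l, ga, 0))
        truth.cis_pairs.add((l, gb, 0))
        used_gene += 2
        used_lnc += 1
        # 8. cis pair at 295 kb (inside the window)
        chrom, base = alloc.take(_BLOCK)
        g, l = genes[used_gene], lncs[used_lnc]
        records.append(_single_exon(l, "lncRNA", chrom, base + 10_000, L, "+"))
        records.append(_coding(g, chrom, base + 10_000 + L + 295_000, "+"))
        truth.category_by_lncrna[l] = {"intergenic"}
        truth.cis_pairs.add((l, g, 295_000))
        used_gene += 1
        used_lnc += 1
        # 9. pair at 305 kb (outside the window)
        chrom, base = alloc.take(_BLOCK)
        g, l = genes[used_gene], lncs[used_lnc]
        records.append(_single_exon(l, "lncRNA", chrom, base + 10_000, L, "+"))
        records.append(_coding(g, chrom, base + 10_000 + L + 305_000, "+"))
        truth.category_by_lncrna[l] = {"intergenic"}
        truth.noncis_pairs.add((l, g, 305_000))
        used_gene += 1
        used_lnc += 1

    # Filler: interleave the remaining features in 20 kb tiles.
    rest: list[tuple[str, str]] = []
    rest += [(g, "mRNA") for g in genes[used_gene:]]
    nc_rest = [(l, "lncRNA") for l in lncs[used_lnc:]] + \
              [(c, "circRNA") for c in circs]
    merged: list[tuple[str, str]] = []
    if nc_rest:
        step = max(len(rest) // len(nc_rest), 1)
        gi = 0
        for k, nc in enumerate(nc_rest):
            take = rest[gi:gi + step]
            merged.extend(take)
            gi += step
            merged.append(nc)
        merged.extend(rest[gi:])
    else:
        merged = rest
    for tid, rtype in merged:
        chrom, base = alloc.take(_TILE)
        if rtype == "mRNA":
            records.append(TranscriptRecord(tid, tid, "mRNA", chrom,
                                            base + 5000, base + 10_000, "+"))
        elif rtype == "lncRNA":
            records.append(_single_exon(tid, "lncRNA", chrom, base + 5000,
                                        config.lnc_len, "+"))
            truth.category_by_lncrna[tid] = {"intergenic"}
        else:
            records.append(_single_exon(tid, "circRNA", chrom, base + 5000,
                                        config.circ_len, "+", circular=True))
    records.sort(key=lambda r: (r.chrom, r.start, r.id))
    return records, truth


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    mrna_utr: dict
    lncrna: dict
    circrna: dict
    mirna: dict


def random_seq(rng: np.random.Generator, length: int, alphabet: str = RNA_BASES,
               base_probs=None) -> str:
    p = np.asarray([0.25] * 4 if base_probs is None else base_probs, float)
    return "".join(rng.choice(list(alphabet), size=length, p=p))


def _scrub(seq: str, cores: Sequence[str], rng: np.random.Generator,
           protected: set | None = None, circular: bool = False,
           alphabet: str = RNA_BASES) -> str:
    """Resample bases until no core occurs outside ``protected`` positions.

    A core occurrence counts as stray if it has at least one non-protected
    base (those bases are resampled; fully protected occurrences are planted
    sites and left alone).  Circular sequences are also checked across the
    junction.
    """
    protected = protected or set()
    L = len(seq)
    for _ in range(300):
        ext = seq + (seq[:5] if circular else "")
        stray = None
        for core in cores:
            p = ext.find(core)
            while p != -1 and p < L:
                span = [(p + j) % L for j in range(6)]
                free = [j for j in span if j not in protected]
                if free:
                    stray = free
                    break
                p = ext.find(core, p + 1)
            if stray:
                break
        if stray is None:
            return seq
        s = list(seq)
        for j in stray:
            s[j] = alphabet[int(rng.integers(4))]
        seq = "".join(s)
    raise ConfigurationError("could not scrub sequence of seed cores")


def _plant_site(seq: str, site: str, offset: int) -> str:
    if offset < 0 or offset + len(site) > len(seq):
        raise ConfigurationError("planted site longer than host sequence")
    return seq[:offset] + site + seq[offset + len(site):]


def _guard_flanks(seq: str, offset: int, length: int, m8c: str) -> str:
    """Prevent accidental upgrade of a planted site: the base before must not
    be the m8 complement and the base after must not be A."""
    s = list(seq)
    if offset - 1 >= 0 and s[offset - 1] == m8c:
        s[offset - 1] = "G" if m8c != "G" else "C"
    j = offset + length
    if j < len(s) and s[j] == "A":
        s[j] = "G"
    return "".join(s)


def simulate_sequences(config: SimConfig,
                       truth: SyntheticTruth | None = None
                       ) -> tuple[SequenceSet, SyntheticTruth]:
    """Random-background RNA sequences with planted miRNA seed sites.

    The ceRNA module (one miRNA vs one lncRNA, one circRNA — with a
    junction-spanning site — and three mRNAs) is planted exactly: its host
    sequences are scrubbed of chance seed cores for every simulated miRNA.
    A couple of extra sites per remaining miRNA are planted on random DE
    transcripts for realism.
    """
    if truth is None:
        _, truth = simulate_expression(config)
    rng = _rng(config, 2)
    seqs = SequenceSet(
        {m: random_seq(rng, config.utr_len, RNA_BASES, config.base_probs)
         for m in mrna_ids(config)},
        {l: random_seq(rng, config.lnc_len, RNA_BASES, config.base_probs)
         for l in lncrna_ids(config)},
        {c: random_seq(rng, config.circ_len, RNA_BASES, config.base_probs)
         for c in circrna_ids(config)},
        {m: random_seq(rng, config.mirna_len, RNA_BASES, config.base_probs)
         for m in mirna_ids(config)},
    )
    all_cores = [seed_site_strings(s)["6mer"] for s in seqs.mirna.values()]

    module = truth.cerna_module
    if module and module.get("mirna"):
        mir = module["mirna"]
        sites = seed_site_strings(seqs.mirna[mir])
        m8c = sites["7mer_m8"][0]

        def host(tid):
            if tid in seqs.lncrna:
                return seqs.lncrna, tid
            if tid in seqs.circrna:
                return seqs.circrna, tid
            return seqs.mrna_utr, tid

        protected: dict[str, set[int]] = {}

        def protect(tid, start, length, L):
            # the site plus its guard flanks
            protected.setdefault(tid, set()).update(
                (start + j) % L for j in range(-1, length + 1))

        # lncRNA: one 8mer at offset 100 (clipped to fit)
        lnc_id = module["lncrna"]
        off = min(100, config.lnc_len - 9)
        seqs.lncrna[lnc_id] = _guard_flanks(
            _plant_site(seqs.lncrna[lnc_id], sites["8mer"], off), off, 8, m8c)
        truth.seed_sites.add((mir, lnc_id, off, "8mer"))
        protect(lnc_id, off, 8, config.lnc_len)

        # circRNA: 7mer-m8 across the back-splice junction (starts 3 nt
        # before the end, wraps to the first 4 nt)
        circ_id = module["circrna"]
        circ = seqs.circrna[circ_id]
        Lc = len(circ)
        site = sites["7mer_m8"]
        circ = circ[:Lc - 3] + site[:3]
        circ = site[3:7] + circ[4:]
        if circ[4] == "A":  # base after the wrapped site: avoid 8mer upgrade
            circ = circ[:4] + "G" + circ[5:]
        if circ[Lc - 4] == m8c:  # base before the site start
            circ = circ[:Lc - 4] + ("G" if m8c != "G" else "C") + circ[Lc - 3:]
        seqs.circrna[circ_id] = circ
        truth.seed_sites.add((mir, circ_id, Lc - 3, "7mer_m8"))
        protect(circ_id, Lc - 3, 7, Lc)

        # mRNAs: 8mer, 7mer-A1, 6mer at staggered offsets
        plans = [("8mer", 50), ("7mer_A1", 120), ("6mer", 200)]
        for tid, (stype, off0) in zip(module["mrnas"], plans):
            off = min(off0, config.utr_len - 9)
            seq = _plant_site(seqs.mrna_utr[tid], sites[stype], off)
            seq = _guard_flanks(seq, off, len(sites[stype]), m8c)
            seqs.mrna_utr[tid] = seq
            truth.seed_sites.add((mir, tid, off, stype))
            protect(tid, off, len(sites[stype]), config.utr_len)

        # Scrub every module host of chance cores (any miRNA) outside the
        # planted regions, then self-check exact recovery.
        members = [lnc_id, circ_id] + list(module["mrnas"])
        for tid in members:
            d, key = host(tid)
            d[key] = _scrub(d[key], all_cores, rng,
                            protected=protected.get(tid, set()),
                            circular=tid in seqs.circrna)
        for tid in members:
            d, key = host(tid)
            circular = tid in seqs.circrna
            for mid, mseq in seqs.mirna.items():
                found = {(s.offset, s.site_type)
                         for s in find_seed_sites(mseq, d[key], circular=circular)}
                planted = {(o, t) for (m, h, o, t) in truth.seed_sites
                           if m == mid and h == tid}
                if found != planted:
                    raise ConfigurationError(
                        f"seed planting self-check failed on {tid}/{mid}: "
                        f"{found} != {planted}")

    # extra plants: 2 sites per remaining miRNA on random DE hosts
    de_all = sorted(truth.de_ids_up | truth.de_ids_down)
    module_members = set(module.get("mrnas", [])) | \
        {module.get("lncrna"), module.get("circrna")} if module else set()
    hosts = [t for t in de_all if t not in module_members]
    stypes = list(seed_site_strings("A" * 22).keys())
    for mir in mirna_ids(config)[1:]:
        if not hosts:
            break
        sites = seed_site_strings(seqs.mirna[mir])
        m8c = sites["7mer_m8"][0]
        for _ in range(2):
            tid = hosts[rng.integers(len(hosts))]
            if tid in seqs.mrna_utr:
                d = seqs.mrna_utr
            elif tid in seqs.lncrna:
                d = seqs.lncrna
            else:
                d = seqs.circrna
            stype = stypes[rng.integers(len(stypes))]
            site = sites[stype]
            off = int(rng.integers(1, len(d[tid]) - len(site) - 1))
            seq = _guard_flanks(_plant_site(d[tid], site, off), off, len(site), m8c)
            if stype in ("6mer", "7mer_m8") and seq[off + len(site)] == "A":
                seq = seq[:off + len(site)] + "G" + seq[off + len(site) + 1:]
            d[tid] = seq
            truth.seed_sites.add((mir, tid, off, stype))
    return seqs, truth


# ---------------------------------------------------------------------------
# Motifs, promoters, TF targets, terms
# ---------------------------------------------------------------------------

def informative_pfm(name: str, consensus: str, dominant: float = 91.0,
                    minor: float = 3.0) -> PFM:
    counts = np.full((4, len(consensus)), minor)
    for i, b in enumerate(consensus):
        counts[DNA_BASES.index(b), i] = dominant
    return PFM(name, counts)


def simulate_motifs_and_terms(config: SimConfig,
                              truth: SyntheticTruth | None = None
                              ) -> tuple[list[PFM], dict, pd.DataFrame,
                                         SyntheticTruth]:
    """Informative PFMs, lncRNA promoter sequences with planted consensus
    sites, TF target gene sets, and a term table with one planted
    over-represented term."""
    if truth is None:
        _, truth = simulate_expression(config)
    rng = _rng(config, 3)
    pfms = [informative_pfm(name, random_seq(rng, config.pfm_width, DNA_BASES,
                                             config.base_probs))
            for name in tf_names(config)]
    promoters = {l: random_seq(rng, config.promoter_len, DNA_BASES,
                               config.base_probs)
                 for l in lncrna_ids(config)}
    by_name = {p.tf_name: p for p in pfms}

    de_up_lnc = sorted(truth.de_ids_up & set(lncrna_ids(config)))
    de_down_lnc = sorted(truth.de_ids_down & set(lncrna_ids(config)))

    def plant_motif(tf: str, lnc: str, offset: int, strand: str):
        cons = by_name[tf].consensus
        ins = cons if strand == "+" else revcomp_dna(cons)
        promoters[lnc] = _plant_site(promoters[lnc], ins, offset)
        truth.motif_sites.add((tf, lnc, offset, strand))

    names = tf_names(config)
    if names and truth.module_lncrna:
        truth.module_tf = names[0]
        plant_motif(names[0], truth.module_lncrna, 100, "+")
    if len(names) >= 2:
        for lnc in de_up_lnc[:3]:
            if (names[0], lnc) not in {(t, l) for t, l, *_ in truth.motif_sites}:
                plant_motif(names[1], lnc,
                            int(rng.integers(0, config.promoter_len
                                             - config.pfm_width)), "+")
    if len(names) >= 3 and de_down_lnc:
        plant_motif(names[2], de_down_lnc[0],
                    int(rng.integers(0, config.promoter_len - config.pfm_width)),
                    "+")
        if len(de_down_lnc) >= 2:
            plant_motif(names[2], de_down_lnc[1],
                        int(rng.integers(0, config.promoter_len
                                         - config.pfm_width)), "-")

    # TF target sets: the module TF owns the module genes (plus non-DE
    # padding so the planted ternary chain is exactly recoverable); the rest
    # draw from the full coding universe.
    genes = mrna_ids(config)
    de_genes = (truth.de_ids_up | truth.de_ids_down) & set(genes)
    non_de = sorted(set(genes) - de_genes)
    for i, tf in enumerate(names):
        if tf == truth.module_tf and truth.module_genes:
            extra = [non_de[j] for j in
                     rng.choice(len(non_de), size=min(10, len(non_de)),
                                replace=False)] if non_de else []
            truth.tf_targets[tf] = set(truth.module_genes) | set(extra)
        else:
            k = min(30, len(genes))
            truth.tf_targets[tf] = {genes[j] for j in
                                    rng.choice(len(genes), size=k, replace=False)}
    if truth.module_tf and truth.module_lncrna:
        truth.ternary_chains = {(truth.module_lncrna, truth.module_tf, g)
                                for g in truth.module_genes}

    # term table: one planted over-represented term among up-regulated mRNAs
    rows = []
    de_up_genes = sorted(truth.de_ids_up & set(genes))
    if config.n_terms and genes:
        n_hit = min(15, len(de_up_genes))
        n_bg = min(5, len(non_de))
        planted = ([de_up_genes[j] for j in
                    rng.choice(len(de_up_genes), size=n_hit, replace=False)]
                   + [non_de[j] for j in
                      rng.choice(len(non_de), size=n_bg, replace=False)])
        truth.enriched_term = "TERM_000"
        rows += [("TERM_000", g) for g in sorted(planted)]
        for t in range(1, config.n_terms):
            size = int(rng.integers(20, 41))
            size = min(size, len(genes))
            members = [genes[j] for j in
                       rng.choice(len(genes), size=size, replace=False)]
            rows += [(f"TERM_{t:03d}", g) for g in sorted(members)]
    term_table = pd.DataFrame(rows, columns=["term_id", "gene_id"])
    return pfms, promoters, term_table, truth


# ---------------------------------------------------------------------------
# One-call bundle
# ---------------------------------------------------------------------------

@dataclass
class SimBundle:
    config: SimConfig
    matrix: ExpressionMatrix
    transcripts: list
    sequences: SequenceSet
    pfms: list
    promoters: dict
    term_table: pd.DataFrame
    truth: SyntheticTruth


def simulate_all(config: SimConfig) -> SimBundle:
    """Generate every pipeline input under one seed (deterministic)."""
    matrix, truth = simulate_expression(config)
    transcripts, truth = simulate_genome(config, truth)
    sequences, truth = simulate_sequences(config, truth)
    pfms, promoters, term_table, truth = simulate_motifs_and_terms(config, truth)
    return SimBundle(config, matrix, transcripts, sequences, pfms, promoters,
                     term_table, truth)
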