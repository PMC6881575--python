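"""End-to-end pipeline driver.

Each stage reads its inputs from files under the run directory and writes its
outputs back, so a late stage re-run from saved intermediates reproduces the
full-run result, and the run report can be recomputed from the emitted files.
Stage order: simulate (optional) -> DE -> classification -> cis -> CNC ->
TF networks -> ternary -> ceRNA -> enrichment -> report.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .coexpression import build_cnc
from .diffexpr import run_de
from .enrichment import enrich_terms, pathway_gene_network
from .errors import ConfigurationError, PipelineError
from .genome import classify_all, cis_neighbors_all
from .regulatory import build_cerna, build_tf_lncrna_network, \
    build_ternary_network, find_seed_sites
from .simulate import SimConfig, simulate_all


@dataclass
class PipelineConfig:
    """All stage thresholds (defaults are the published gates) plus flags."""

    sim: SimConfig = field(default_factory=SimConfig)
    # differential expression
    fc_min: float = 2.0
    de_p_max: float = 0.05
    de_q_max: float = 0.05
    welch: bool = False
    pool_strata: bool = False
    log2_input: bool = False
    # co-expression network
    cnc_r_min: float = 0.90
    cnc_p_max: float = 0.01
    cnc_q_max: float = 0.01
    # genomic context
    cis_window_bp: int = 300_000
    bidir_window_bp: int = 1000
    # trans regulation
    motif_e_max: float = 0.01
    ternary_r_min: float = 0.9
    ternary_q_max: float = 0.05
    tf_enrich_p_max: float = 0.01
    tf_enrich_q_max: float = 0.01
    # ceRNA
    cerna_require_correlation: bool = False
    cerna_r_min: float = 0.9
    # term enrichment
    enrich_method: str = "hypergeom"
    enrich_p_max: float = 0.05
    enrich_top: int = 10

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        mapping = dict(mapping)
        sim = SimConfig.from_mapping(mapping.pop("sim", {}) or {})
        fields = {f.name for f in dataclasses.fields(cls)} - {"sim"}
        unknown = set(mapping) - fields
        if unknown:
            raise ConfigurationError(
                f"unknown PipelineConfig fields: {sorted(unknown)}")
        return cls(sim=sim, **mapping)

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["base_probs"] = list(d["sim"]["base_probs"])
        return d


def _inputs(outdir: Path) -> Path:
    return Path(outdir) / "inputs"


def _results(outdir: Path) -> Path:
    return Path(outdir) / "results"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, outdir: Path) -> None:
    bundle = simulate_all(config.sim)
    inp = _inputs(outdir)
    inp.mkdir(parents=True, exist_ok=True)
    cio.write_expression_tsv(bundle.matrix, inp / "expression.tsv")
    cio.write_gff3(bundle.transcripts, inp / "annotation.gff3")
    cio.write_fasta(bundle.sequences.mrna_utr, inp / "mrna_utr.fa")
    cio.write_fasta(bundle.sequences.lncrna, inp / "lncrna.fa")
    cio.write_fasta(bundle.sequences.circrna, inp / "circrna.fa")
    cio.write_fasta(bundle.sequences.mirna, inp / "mirna.fa")
    cio.write_fasta(bundle.promoters, inp / "promoters.fa")
    cio.write_meme(bundle.pfms, inp / "motifs.meme")
    cio.write_term_table(bundle.term_table, inp / "terms.tsv")
    cio.write_tf_targets(bundle.truth.tf_targets, inp / "tf_targets.tsv")
    cio.write_truth(bundle.truth, inp / "truth.json")


def stage_de(config: PipelineConfig, outdir: Path) -> None:
    matrix = cio.read_expression_tsv(_inputs(outdir) / "expression.tsv")
    de = run_de(matrix, config.fc_min, config.de_p_max, config.de_q_max,
                config.welch, config.pool_strata, config.log2_input)
    res = _results(outdir)
    res.mkdir(parents=True, exist_ok=True)
    table = de.table.copy()
    for col in ("fc", "p", "q"):
        table[f"{col}_display"] = table[col].round(4)
    table.to_csv(res / "de_results.tsv", sep="\t")
    with open(res / "de_errors.tsv", "w") as fh:
        fh.write("probe_id\tmessage\n")
        for pid, msg in de.errors:
            fh.write(f"{pid}\t{msg}\n")


def _read_de(outdir: Path) -> pd.DataFrame:
    return pd.read_csv(_results(outdir) / "de_results.tsv", sep="\t",
                       index_col="probe_id")


def _de_ids(de: pd.DataFrame, rna_type: str, direction: str | None = None
            ) -> list[str]:
    t = de[de["passes"] & (de["rna_type"] == rna_type)]
    if direction is not None:
        t = t[t["direction"] == direction]
    return sorted(t.index)


def stage_classify(config: PipelineConfig, outdir: Path) -> None:
    records = cio.read_gff3(_inputs(outdir) / "annotation.gff3")
    lncs = [r for r in records if r.rna_type == "lncRNA"]
    coding = [r for r in records if r.rna_type == "mRNA"]
    summary = classify_all(lncs, coding, config.bidir_window_bp)
    res = _results(outdir)
    res.mkdir(parents=True, exist_ok=True)
    rows = [(c.lncrna_id, ";".join(sorted(c.labels)), c.primary)
            for c in summary.calls]
    pd.DataFrame(rows, columns=["lncrna_id", "labels", "primary"]).to_csv(
        res / "categories.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(lab, summary.category_counts.get(lab, 0),
          round(summary.percentages.get(lab, 0.0), 4))
         for lab in sorted(summary.percentages)],
        columns=["category", "count", "percent"],
    ).to_csv(res / "category_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted((";".join(k), v) for k, v in summary.venn_counts.items()),
        columns=["label_set", "count"],
    ).to_csv(res / "venn_counts.tsv", sep="\t", index=False)


def stage_cis(config: PipelineConfig, outdir: Path) -> None:
    records = cio.read_gff3(_inputs(outdir) / "annotation.gff3")
    de = _read_de(outdir)
    de_lnc = set(_de_ids(de, "lncRNA"))
    lncs = [r for r in records if r.rna_type == "lncRNA" and r.id in de_lnc]
    coding = [r for r in records if r.rna_type == "mRNA"]
    pairs = cis_neighbors_all(lncs, coding, config.cis_window_bp)
    pairs.sort(key=lambda p: (p.lncrna_id, p.distance_bp, p.gene_id))
    pd.DataFrame(
        [(p.lncrna_id, p.gene_id, p.distance_bp, p.relative_position)
         for p in pairs],
        columns=["lncrna_id", "gene_id", "distance_bp", "relative_position"],
    ).to_csv(_results(outdir) / "cis_pairs.tsv", sep="\t", index=False)


def stage_cnc(config: PipelineConfig, outdir: Path) -> None:
    matrix = cio.read_expression_tsv(_inputs(outdir) / "expression.tsv")
    de = _read_de(outdir)
    nc_ids = _de_ids(de, "lncRNA") + _de_ids(de, "circRNA")
    coding_ids = _de_ids(de, "mRNA")
    cnc = build_cnc(matrix, nc_ids, coding_ids, config.cnc_r_min,
                    config.cnc_p_max, config.cnc_q_max)
    res = _results(outdir)
    table = pd.DataFrame(
        [(e.nc_id, e.coding_id, e.r, e.p, e.q, e.sign, round(e.r, 4))
         for e in cnc.edges],
        columns=["nc_id", "coding_id", "r", "p", "q", "sign", "r_display"],
    )
    table.to_csv(res / "cnc_edges.tsv", sep="\t", index=False)
    cio.export_network(cnc.edges, "sif", res / "cnc_edges.sif")
    cio.export_network(cnc.edges, "graphml", res / "cnc_edges.graphml")
    with open(res / "cnc_log.json", "w") as fh:
        json.dump({"n_pairs_tested": cnc.n_pairs_tested,
                   "n_skipped_constant": cnc.n_skipped_constant,
                   "thresholds": cnc.thresholds}, fh, sort_keys=True)
        fh.write("\n")


def stage_tfnet(config: PipelineConfig, outdir: Path) -> None:
    pfms = cio.read_meme(_inputs(outdir) / "motifs.meme")
    promoters = cio.read_fasta(_inputs(outdir) / "promoters.fa")
    de = _read_de(outdir)
    res = _results(outdir)
    rows = []
    summaries = {}
    for direction in ("up", "down"):
        ids = _de_ids(de, "lncRNA", direction)
        sub = {i: promoters[i] for i in ids if i in promoters}
        net = build_tf_lncrna_network(pfms, sub, config.motif_e_max)
        summaries[direction] = {
            "n_tfs": net.n_tfs, "n_lncrnas": net.n_lncrnas,
            "n_edges": net.n_edges, "summary": net.summary,
        }
        for h in net.hits:
            rows.append((direction, h.tf_name, h.lncrna_id, h.offset,
                         h.strand, h.score, h.e_value))
    pd.DataFrame(rows, columns=["direction", "tf_name", "lncrna_id", "offset",
                                "strand", "score", "e_value"]).to_csv(
        res / "tf_hits.tsv", sep="\t", index=False)
    edges = sorted({(tf, lnc, "tf_binds") for (_, tf, lnc, *_rest) in rows})
    cio.export_network(edges, "sif", res / "tf_edges.sif")
    pd.DataFrame(sorted({(d, tf, lnc) for (d, tf, lnc, *_r) in rows}),
                 columns=["direction", "tf_name", "lncrna_id"]).to_csv(
        res / "tf_edges.tsv", sep="\t", index=False)
    with open(res / "tf_summary.json", "w") as fh:
        json.dump(summaries, fh, sort_keys=True)
        fh.write("\n")


def stage_ternary(config: PipelineConfig, outdir: Path) -> None:
    res = _results(outdir)
    de = _read_de(outdir)
    cnc = pd.read_csv(res / "cnc_edges.tsv", sep="\t")
    tf_edges = pd.read_csv(res / "tf_edges.tsv", sep="\t")
    tf_targets = cio.read_tf_targets(_inputs(outdir) / "tf_targets.tsv")

    @dataclass
    class _E:
        nc_id: str
        coding_id: str
        r: float
        q: float
    edges = [_E(r.nc_id, r.coding_id, r.r, r.q) for r in cnc.itertuples()]
    pairs = sorted({(r.tf_name, r.lncrna_id) for r in tf_edges.itertuples()})
    # universe: every measured coding gene (standard over-representation
    # practice), not just the DE set
    universe = sorted(de.index[de["rna_type"] == "mRNA"])
    net = build_ternary_network(edges, pairs, tf_targets, universe,
                                config.ternary_r_min, config.ternary_q_max,
                                config.tf_enrich_p_max, config.tf_enrich_q_max)
    pd.DataFrame(net.triples, columns=["lncrna_id", "tf_name", "gene_id"]) \
        .to_csv(res / "ternary_triples.tsv", sep="\t", index=False)
    pd.DataFrame(net.enrichment,
                 columns=["lncrna_id", "tf_name", "overlap", "p", "q",
                          "passes"]).to_csv(res / "tf_enrichment.tsv",
                                            sep="\t", index=False)
    with open(res / "ternary_summary.json", "w") as fh:
        json.dump({"n_lncrnas": net.n_lncrnas, "n_tfs": net.n_tfs,
                   "n_genes": net.n_genes, "summary": net.summary},
                  fh, sort_keys=True)
        fh.write("\n")


def stage_cerna(config: PipelineConfig, outdir: Path) -> None:
    inp = _inputs(outdir)
    res = _results(outdir)
    de = _read_de(outdir)
    utr = cio.read_fasta(inp / "mrna_utr.fa")
    lnc = cio.read_fasta(inp / "lncrna.fa")
    circ = cio.read_fasta(inp / "circrna.fa")
    mirna = cio.read_fasta(inp / "mirna.fa")
    de_lnc = _de_ids(de, "lncRNA")
    de_circ = _de_ids(de, "circRNA")
    de_mrna = _de_ids(de, "mRNA")
    sites = []
    for mid in sorted(mirna):
        for tid in de_lnc:
            sites += find_seed_sites(mirna[mid], lnc[tid], False, mid, tid)
        for tid in de_circ:
            sites += find_seed_sites(mirna[mid], circ[tid], True, mid, tid)
        for tid in de_mrna:
            sites += find_seed_sites(mirna[mid], utr[tid], False, mid, tid)
    pd.DataFrame(
        sorted((s.mirna_id, s.target_id, s.offset, s.site_type) for s in sites),
        columns=["mirna_id", "target_id", "offset", "site_type"],
    ).to_csv(res / "seed_sites.tsv", sep="\t", index=False)
    nc_ids = de_lnc + de_circ
    if config.cerna_require_correlation:
        cnc = pd.read_csv(res / "cnc_edges.tsv", sep="\t")
        allowed = {(r.nc_id, r.coding_id) for r in cnc.itertuples()
                   if abs(r.r) >= config.cerna_r_min}
        result = build_cerna(nc_ids, de_mrna, sites)
        result.triples = [t for t in result.triples
                          if (t.nc_id, t.mrna_id) in allowed]
        result.edges = sorted(
            {(t.nc_id, t.mirna_id, "mirna_site") for t in result.triples}
            | {(t.mirna_id, t.mrna_id, "mirna_site") for t in result.triples})
    else:
        result = build_cerna(nc_ids, de_mrna, sites)
    pd.DataFrame(
        [(t.nc_id, t.mirna_id, t.mrna_id) for t in result.triples],
        columns=["nc_id", "mirna_id", "mrna_id"],
    ).to_csv(res / "cerna_triples.tsv", sep="\t", index=False)
    cio.export_network(result.edges, "sif", res / "cerna_edges.sif")


def stage_enrich(config: PipelineConfig, outdir: Path) -> None:
    inp = _inputs(outdir)
    res = _results(outdir)
    de = _read_de(outdir)
    table = cio.read_term_table(inp / "terms.tsv")
    terms = cio.term_mapping(table)
    universe = sorted(de.index[de["rna_type"] == "mRNA"])
    for direction in ("up", "down"):
        genes = _de_ids(de, "mRNA", direction)
        results = enrich_terms(genes, terms, universe, config.enrich_method,
                               config.enrich_p_max, config.enrich_top)
        pd.DataFrame(
            [(r.term_id, r.k, r.K, r.n, r.N, r.p, r.q, r.fold_enrichment)
             for r in results],
            columns=["term_id", "k", "K", "n", "N", "p", "q",
                     "fold_enrichment"],
        ).to_csv(res / f"enrichment_{direction}.tsv", sep="\t", index=False)
        edges = [(t, g, "term_member")
                 for t, g in pathway_gene_network(results, genes)]
        cio.export_network(edges, "sif", res / f"pathway_gene_{direction}.sif")


def stage_report(config: PipelineConfig, outdir: Path) -> None:
    """Aggregate counts, recomputed from the emitted files."""
    res = _results(outdir)
    de = _read_de(outdir)
    report: dict = {"thresholds": config.to_jsonable()}
    de_counts = {}
    for t in ("mRNA", "lncRNA", "circRNA"):
        de_counts[t] = {"up": len(_de_ids(de, t, "up")),
                        "down": len(_de_ids(de, t, "down"))}
    report["differential_expression"] = de_counts
    cats = pd.read_csv(res / "category_counts.tsv", sep="\t")
    report["categories"] = {r.category: {"count": int(r.count),
                                         "percent": float(r.percent)}
                            for r in cats.itertuples()}
    report["cis_pairs"] = int(len(pd.read_csv(res / "cis_pairs.tsv", sep="\t")))
    cnc = pd.read_csv(res / "cnc_edges.tsv", sep="\t")
    report["cnc"] = {"n_edges": int(len(cnc)),
                     "n_negative": int((cnc["sign"] == "negative").sum())
                     if len(cnc) else 0}
    with open(res / "tf_summary.json") as fh:
        report["tf_networks"] = json.load(fh)
    with open(res / "ternary_summary.json") as fh:
        report["ternary"] = json.load(fh)
    report["cerna_triples"] = int(len(pd.read_csv(res / "cerna_triples.tsv",
                                                  sep="\t")))
    for d in ("up", "down"):
        report[f"enriched_terms_{d}"] = int(len(pd.read_csv(
            res / f"enrichment_{d}.tsv", sep="\t")))
    with open(res / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    lines = [
        "cncnet run report",
        f"DE (fold change >= {config.fc_min}, p < {config.de_p_max}, "
        f"FDR < {config.de_q_max}):",
    ]
    for t, c in de_counts.items():
        lines.append(f"  {t}: {c['up']} up-regulated, {c['down']} down-regulated")
    for d in ("up", "down"):
        s = report["tf_networks"][d]
        lines.append(f"The {d}-regulated lncRNAs-TFs network consisted of "
                     f"{s['summary']}.")
    lines.append(f"The lncRNA-TF-gene network consisted of "
                 f"{report['ternary']['summary']}.")
    lines.append(f"ceRNA triples: {report['cerna_triples']}")
    with open(res / "report.txt", "w") as fh:
        fh.write("\n".join(lines) + "\n")


STAGES = {
    "simulate": stage_simulate,
    "de": stage_de,
    "classify": stage_classify,
    "cis": stage_cis,
    "cnc": stage_cnc,
    "tfnet": stage_tfnet,
    "ternary": stage_ternary,
    "cerna": stage_cerna,
    "enrich": stage_enrich,
    "report": stage_report,
}

_ORDER = ["de", "classify", "cis", "cnc", "tfnet", "ternary", "cerna",
          "enrich", "report"]


def run_pipeline(config: PipelineConfig, outdir, simulate: bool = True) -> Path:
    """Run every stage; on failure remove the partial results directory and
    raise a PipelineError naming the stage."""
    outdir = Path(outdir)
    stages = (["simulate"] if simulate else []) + _ORDER
    for name in stages:
        try:
            STAGES[name](config, outdir)
        except Exception as exc:
            if name != "simulate":
                shutil.rmtree(_results(outdir), ignore_errors=True)
            raise PipelineError(name, str(exc)) from exc
    return _results(outdir)
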