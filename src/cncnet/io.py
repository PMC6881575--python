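"""File-format adapters and network export.

Formats: expression TSV (header carries group labels as ``sample:group``),
GFF3 (1-based inclusive on disk, 0-based half-open in memory), FASTA,
MEME-minimal motif text, two-column term tables, truth JSON, and network
export as SIF / GraphML / TSV (loadable by Cytoscape-class tools).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import networkx as nx
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .diffexpr import ExpressionMatrix
from .errors import FormatError
from .genome import TranscriptRecord
from .regulatory import PFM
from .simulate import SyntheticTruth

RNA_TYPES = ("mRNA", "lncRNA", "circRNA")
_GFF_TYPE = {"mRNA": "mRNA", "lncRNA": "lnc_RNA", "circRNA": "circRNA"}
_GFF_TYPE_REV = {v: k for k, v in _GFF_TYPE.items()}


# ---------------------------------------------------------------------------
# Expression TSV
# ---------------------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    cols = [f"{s}:{matrix.groups[s]}" for s in matrix.values.columns]
    out = matrix.values.copy()
    out.insert(0, "type", matrix.rna_type)
    out.columns = ["type"] + cols
    out.to_csv(path, sep="\t", index_label="probe_id")


def read_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    if df.columns[0] != "probe_id" or df.columns[1] != "type":
        raise FormatError(f"{path}: header must start with 'probe_id\\ttype'")
    sample_cols = list(df.columns[2:])
    samples, groups = [], []
    for c in sample_cols:
        if ":" not in c:
            raise FormatError(f"{path}: sample column {c!r} lacks ':group'")
        sid, grp = c.rsplit(":", 1)
        samples.append(sid)
        groups.append(grp)
    dup = df["probe_id"][df["probe_id"].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicated probe_id {dup.iloc[0]!r}")
    bad_type = df.loc[~df["type"].isin(RNA_TYPES), "probe_id"]
    if not bad_type.empty:
        raise FormatError(f"{path}: unknown rna_type for probe {bad_type.iloc[0]!r}")
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        r, c = np.argwhere(values.isna().to_numpy())[0]
        raise FormatError(f"{path}: missing/non-numeric value at probe "
                          f"{df['probe_id'].iloc[r]!r}, sample {samples[c]!r}")
    if (values.to_numpy() <= 0).any():
        r, c = np.argwhere((values <= 0).to_numpy())[0]
        raise FormatError(f"{path}: non-positive intensity at probe "
                          f"{df['probe_id'].iloc[r]!r}, sample {samples[c]!r}")
    values.index = pd.Index(df["probe_id"], name="probe_id")
    values.columns = samples
    return ExpressionMatrix(values,
                            pd.Series(df["type"].to_numpy(), index=values.index),
                            pd.Series(groups, index=samples))


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(records: Sequence[TranscriptRecord], path) -> None:
    """Write transcripts (one parent feature + exon children), converting the
    internal 0-based half-open coordinates to GFF3 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = f"ID={r.id};gene_id={r.gene_id}"
            if r.is_circular:
                attrs += ";circular=true"
            fh.write("\t".join([r.chrom, "cncnet", _GFF_TYPE[r.rna_type],
                                str(r.start + 1), str(r.end), ".", r.strand,
                                ".", attrs]) + "\n")
            for (s, e) in r.exons:
                fh.write("\t".join([r.chrom, "cncnet", "exon", str(s + 1),
                                    str(e), ".", r.strand, ".",
                                    f"Parent={r.id}"]) + "\n")


def read_gff3(path) -> list[TranscriptRecord]:
    try:
        db = gffutils.create_db(str(path), ":memory:", keep_order=True)
    except Exception as exc:  # noqa: BLE001 - normalize parser failures
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc
    records = []
    for f in db.all_features():
        if f.featuretype == "exon":
            if not f.attributes.get("Parent"):
                raise FormatError(f"{path}: orphan exon at {f.seqid}:{f.start}")
            continue
        if f.featuretype not in _GFF_TYPE_REV:
            continue
        if f.strand not in ("+", "-"):
            raise FormatError(f"{path}: feature {f.id!r} lacks a strand")
        exons = tuple(sorted((c.start - 1, c.end)
                             for c in db.children(f.id, featuretype="exon")))
        gene_id = (f.attributes.get("gene_id") or [f.id])[0]
        circular = (f.attributes.get("circular") or ["false"])[0] == "true"
        records.append(TranscriptRecord(
            f.id, gene_id, _GFF_TYPE_REV[f.featuretype], f.seqid,
            f.start - 1, f.end, f.strand, exons, circular))
    records.sort(key=lambda r: (r.chrom, r.start, r.id))
    return records


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path) -> None:
    recs = [SeqRecord(Seq(sequences[k]), id=k, description="")
            for k in sorted(sequences)]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# MEME-minimal motif text
# ---------------------------------------------------------------------------

def write_meme(pfms: Sequence[PFM], path, background=(0.25, 0.25, 0.25, 0.25)
               ) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.6f} C {:.6f} G {:.6f} T {:.6f}\n\n".format(*background))
        for p in pfms:
            colsum = p.counts.sum(axis=0)
            nsites = int(round(colsum[0]))
            probs = p.counts / colsum
            fh.write(f"MOTIF {p.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width} "
                     f"nsites= {nsites} E= 0\n")
            for i in range(p.width):
                fh.write(" " + " ".join(f"{probs[b, i]:.6f}" for b in range(4))
                         + "\n")
            fh.write("\n")


def read_meme(path) -> list[PFM]:
    with open(path) as fh:
        try:
            record = bio_motifs.parse(fh, "minimal")
        except Exception as exc:  # noqa: BLE001
            raise FormatError(f"{path}: not MEME-minimal motif text ({exc})") \
                from exc
    pfms = []
    for m in record:
        counts = np.array([[m.counts[b][i] for i in range(m.length)]
                           for b in "ACGT"], float)
        pfms.append(PFM(m.name, counts))
    return pfms


# ---------------------------------------------------------------------------
# Term tables, TF target tables, truth JSON
# ---------------------------------------------------------------------------

def write_term_table(table: pd.DataFrame, path) -> None:
    table[["term_id", "gene_id"]].to_csv(path, sep="\t", index=False)


def read_term_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["term_id", "gene_id"]:
        raise FormatError(f"{path}: expected columns term_id, gene_id")
    return df


def term_mapping(table: pd.DataFrame) -> dict:
    return {t: sorted(g) for t, g in table.groupby("term_id")["gene_id"]}


def write_tf_targets(tf_targets: Mapping[str, Iterable[str]], path) -> None:
    rows = [(tf, g) for tf in sorted(tf_targets) for g in sorted(tf_targets[tf])]
    pd.DataFrame(rows, columns=["tf_name", "gene_id"]).to_csv(
        path, sep="\t", index=False)


def read_tf_targets(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["tf_name", "gene_id"]:
        raise FormatError(f"{path}: expected columns tf_name, gene_id")
    return {tf: set(g) for tf, g in df.groupby("tf_name")["gene_id"]}


def write_truth(truth: SyntheticTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        return SyntheticTruth.from_jsonable(json.load(fh))


def load_config_mapping(path) -> dict:
    """YAML (superset of JSON) mapping for SimConfig / PipelineConfig."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return data


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("sif", "graphml", "tsv")


def _as_edge_records(edges) -> list[dict]:
    """Normalize CncEdge / (a, b, relation) tuples / dicts to edge records."""
    records = []
    for e in edges:
        if isinstance(e, dict):
            records.append(e)
        elif hasattr(e, "nc_id"):  # CncEdge
            records.append({
                "source": e.nc_id, "target": e.coding_id,
                "relation": "pos_corr" if e.sign == "positive" else "neg_corr",
                "r": e.r, "p": e.p, "q": e.q, "sign": e.sign,
            })
        elif isinstance(e, tuple) and len(e) == 3:
            records.append({"source": e[0], "target": e[1], "relation": e[2]})
        else:
            raise FormatError(f"cannot export edge {e!r}")
    records.sort(key=lambda d: (d["source"], d["relation"], d["target"]))
    return records


def export_network(edges, fmt: str, path) -> None:
    """Write an edge list as SIF, GraphML or TSV.

    SIF relation tags encode the edge semantics (pos_corr / neg_corr /
    tf_binds / mirna_site / term_member); negative correlations keep their
    own tag so graph tools can render them dashed.  GraphML carries numeric
    attributes (r, p, q, sign, site_type, ...) as typed attributes.
    """
    if fmt not in NETWORK_FORMATS:
        raise FormatError(f"unknown network format {fmt!r}")
    records = _as_edge_records(edges)
    if fmt == "sif":
        with open(path, "w") as fh:
            for d in records:
                fh.write(f"{d['source']}\t{d['relation']}\t{d['target']}\n")
    elif fmt == "tsv":
        cols = ["source", "relation", "target"]
        extra = sorted({k for d in records for k in d} - set(cols))
        df = pd.DataFrame([{k: d.get(k) for k in cols + extra}
                           for d in records])
        if df.empty:
            df = pd.DataFrame(columns=cols + extra)
        df.to_csv(path, sep="\t", index=False)
    else:
        g = nx.MultiGraph()
        for d in records:
            attrs = {k: v for k, v in d.items()
                     if k not in ("source", "target") and v is not None}
            g.add_edge(d["source"], d["target"], **attrs)
        nx.write_graphml(g, str(path))


def read_sif(path) -> list[tuple[str, str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}: malformed SIF line {line!r}")
            edges.append((parts[0], parts[2], parts[1]))
    return edges


def read_graphml(path) -> nx.MultiGraph:
    return nx.read_graphml(str(path), force_multigraph=True)
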