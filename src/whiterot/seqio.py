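"""Thin I/O helpers shared across the toolkit.

Sequences are handled as plain ``{id: str}`` dictionaries; Biopython does the
FASTA parsing/writing.  Interval truth tables use 0-based half-open
coordinates internally and are converted at the boundary when written as
GFF3 (1-based closed) or BED (0-based half-open).
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read a (multi-record, possibly line-wrapped) FASTA into an ordered dict."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def write_fasta(seqs: Mapping[str, str], path, width: int = 60) -> None:
    recs = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def fasta_bytes(seqs: Mapping[str, str], width: int = 60) -> bytes:
    """Serialize to FASTA in memory (used for byte-determinism checks)."""
    buf = io.StringIO()
    writer = SeqIO.FastaIO.FastaWriter(buf, wrap=width)
    writer.write_file(
        [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    )
    return buf.getvalue().encode()


def write_bed(intervals: Iterable[tuple], path) -> None:
    """Write (scaffold, start, end, name) tuples as BED4; coordinates pass through."""
    with open(path, "w") as fh:
        for row in intervals:
            scaffold, start, end, name = row[:4]
            fh.write(f"{scaffold}\t{start}\t{end}\t{name}\n")


def write_gff3_genes(gene_models, path) -> None:
    """Write gene models (see :class:`whiterot.gene_structure.GeneModel`) as GFF3.

    Internal 0-based half-open exon intervals become 1-based closed GFF3 lines.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in gene_models:
            g_start = min(s for s, _ in gm.exons)
            g_end = max(e for _, e in gm.exons)
            fh.write(
                f"{gm.scaffold}\twhiterot\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{gm.strand}\t.\tID={gm.gene_id}\n"
            )
            mrna = f"{gm.gene_id}.t1"
            fh.write(
                f"{gm.scaffold}\twhiterot\tmRNA\t{g_start + 1}\t{g_end}\t.\t"
                f"{gm.strand}\t.\tID={mrna};Parent={gm.gene_id}\n"
            )
            for i, (s, e) in enumerate(gm.exons, start=1):
                fh.write(
                    f"{gm.scaffold}\twhiterot\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                    f"ID={mrna}.exon{i};Parent={mrna}\n"
                )


def read_gff3_genes(path):
    """Read gene models back from a GFF3 produced by :func:`write_gff3_genes`.

    Only ``gene``/``exon`` features are used; exon Parent ids are mapped to the
    gene via the ``<gene>.t1`` mRNA naming convention or an explicit Parent chain.
    """
    from .gene_structure import GeneModel

    genes: dict[str, dict] = {}
    parents: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        scaffold, _, ftype, start, end, _, strand, _, attrs = fields
        attr = dict(
            kv.split("=", 1) for kv in attrs.rstrip(";").split(";") if "=" in kv
        )
        if ftype == "gene":
            genes[attr["ID"]] = {
                "scaffold": scaffold,
                "strand": strand,
                "exons": [],
            }
        elif ftype == "mRNA":
            parents[attr["ID"]] = attr["Parent"]
        elif ftype == "exon":
            parent = attr["Parent"]
            gene_id = parents.get(parent, parent)
            genes[gene_id]["exons"].append((int(start) - 1, int(end)))
    out = []
    for gene_id, info in genes.items():
        exons = sorted(info["exons"])
        out.append(
            GeneModel(
                gene_id=gene_id,
                scaffold=info["scaffold"],
                strand=info["strand"],
                exons=exons,
            )
        )
    return out


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
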