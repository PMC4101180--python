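"""Splice-site validation under the GT-AG rule and intron-position homology.

Canonical spliceosomal introns begin with GT and end with AG on the coding
strand.  Gene models are exon chains in genomic (0-based half-open)
coordinates; introns are the gaps between consecutive exons.  For comparing
gene structures across homologous genes, each intron is mapped to its codon
position and phase in the encoded protein and projected through a protein
alignment; genes sharing intron positions group into structural families,
the way multi-copy laccase and peroxidase gene families are organized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .seqio import revcomp


@dataclass
class GeneModel:
    gene_id: str
    scaffold: str
    strand: str  # '+' or '-'
    exons: list = field(default_factory=list)  # 0-based half-open, genomic, sorted

    def __post_init__(self):
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if e1 > s2:
                raise ValueError(f"{self.gene_id}: overlapping exons")

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons (genome order)."""
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        ]

    def coding_sequence(self, genome: dict[str, str]) -> str:
        seq = "".join(genome[self.scaffold][s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq


@dataclass
class SpliceFlag:
    intron: tuple
    valid: bool
    reason: str  # 'gt-ag' | 'non-canonical:XX..YY' | 'too-short'


def validate_splice_sites(model: GeneModel, genome: dict[str, str]) -> list[SpliceFlag]:
    """Check every intron of ``model`` for GT..AG ends on the coding strand.

    Minus-strand models are evaluated on the reverse complement, so a
    genomic plus-strand CT..AC intron is valid for a minus-strand gene.
    Introns shorter than 4 bp are invalid with a distinct reason.
    """
    scaffold = genome[model.scaffold]
    flags = []
    for start, end in model.introns:
        if not 0 <= start <= end <= len(scaffold):
            raise ValueError(f"{model.gene_id}: intron ({start},{end}) out of bounds")
        if end - start < 4:
            flags.append(SpliceFlag((start, end), False, "too-short"))
            continue
        seq = scaffold[start:end]
        if model.strand == "-":
            seq = revcomp(seq)
        donor, acceptor = seq[:2], seq[-2:]
        if donor == "GT" and acceptor == "AG":
            flags.append(SpliceFlag((start, end), True, "gt-ag"))
        else:
            flags.append(
                SpliceFlag((start, end), False, f"non-canonical:{donor}..{acceptor}")
            )
    return flags


def six_frame_translate(sequence: str) -> dict[str, str]:
    """Translate in all six frames with the standard code; N codons give X.

    Frames are labelled +1..+3 (forward) and -1..-3 (reverse complement);
    frame -1 of S equals frame +1 of revcomp(S).  A three-frame (forward
    only) view is just the '+' entries.
    """
    sequence = sequence.upper()
    bad = set(sequence) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in input: {sorted(bad)}")
    frames = {}
    rc = revcomp(sequence)
    for offset in range(3):
        for label, s in ((f"+{offset + 1}", sequence), (f"-{offset + 1}", rc)):
            sub = s[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            frames[label] = str(Seq(sub).translate()) if sub else ""
    return frames


# ---------------------------------------------------------------------------
# intron-position homology

def intron_protein_positions(model: GeneModel) -> list[tuple[int, int]]:
    """Introns as (codon index, phase) on the encoded protein.

    The codon index counts codons 0-based along the CDS; the phase is 0 when
    the intron falls between codons, 1 or 2 when it splits a codon after the
    first or second base.  Computed on the coding strand, 5'->3'.
    """
    exon_lengths = [e - s for s, e in model.exons]
    if model.strand == "-":
        exon_lengths = exon_lengths[::-1]
    positions = []
    cds_offset = 0
    for length in exon_lengths[:-1]:
        cds_offset += length
        positions.append((cds_offset // 3, cds_offset % 3))
    return positions


def _project_to_columns(aligned_seq: str, protein_positions: list[int]) -> list:
    """Map ungapped protein indices to alignment column indices."""
    col_of = {}
    res = 0
    for col, ch in enumerate(aligned_seq):
        if ch != "-":
            col_of[res] = col
            res += 1
    return [col_of.get(p) for p in protein_positions]


@dataclass
class IntronHomologyReport:
    shared: list = field(default_factory=list)  # (column, phase)
    unique_a: list = field(default_factory=list)
    unique_b: list = field(default_factory=list)
    unmatched: list = field(default_factory=list)  # introns in alignment gaps

    @property
    def score(self) -> float:
        union = len(self.shared) + len(self.unique_a) + len(self.unique_b)
        return len(self.shared) / union if union else 1.0


def intron_position_homology(
    model_a: GeneModel,
    model_b: GeneModel,
    aligned_a: str,
    aligned_b: str,
) -> IntronHomologyReport:
    """Compare intron positions of two gene models through a protein alignment.

    ``aligned_a``/``aligned_b`` are the two proteins as equal-length aligned
    rows.  An intron is *shared* when both genes carry an intron at the same
    alignment column with the same phase; introns landing where the own
    protein has a gap are reported unmatched.  The score is
    ``shared / union`` and is symmetric in the two models.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned rows must have equal length")
    report = IntronHomologyReport()
    keyed = {}
    for tag, model, row in (("a", model_a, aligned_a), ("b", model_b, aligned_b)):
        pos = intron_protein_positions(model)
        cols = _project_to_columns(row, [codon for codon, _ in pos])
        entries = set()
        for (codon, phase), col in zip(pos, cols):
            if col is None:
                report.unmatched.append((tag, codon, phase))
            else:
                entries.add((col, phase))
        keyed[tag] = entries
    report.shared = sorted(keyed["a"] & keyed["b"])
    report.unique_a = sorted(keyed["a"] - keyed["b"])
    report.unique_b = sorted(keyed["b"] - keyed["a"])
    return report


def group_by_structure(
    models: list[GeneModel],
    alignments: dict[tuple[str, str], tuple[str, str]],
    threshold: float = 0.5,
) -> list[set[str]]:
    """Single-linkage grouping of gene models on intron-homology score.

    ``alignments`` maps (gene_id_a, gene_id_b) to the pairwise aligned rows;
    either key order is accepted.  Genes joined by any pair with score >=
    ``threshold`` end up in one group.
    """
    import networkx as nx

    graph = nx.Graph()
    graph.add_nodes_from(m.gene_id for m in models)
    by_id = {m.gene_id: m for m in models}
    for (ida, idb), (row_a, row_b) in alignments.items():
        report = intron_position_homology(by_id[ida], by_id[idb], row_a, row_b)
        if report.score >= threshold:
            graph.add_edge(ida, idb)
    return [set(c) for c in nx.connected_components(graph)]
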