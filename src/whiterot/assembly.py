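"""Assembly contiguity and composition statistics from a scaffold FASTA.

Conventions: *span* counts all characters including ambiguous N (gap fill);
*bases* counts non-N characters only.  N50 is the length L such that
scaffolds of length >= L, taken in descending order, cumulatively cover at
least half the assembly.  Whether published N50 values are computed on
gapped spans or ungapped bases is often unstated, so both variants are
reported; the span-based value is the default (the common assembler
convention).  Soft-masked lowercase bases count normally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

VALID_CHARS = set("ACGTN")


@dataclass
class AssemblyStats:
    n_scaffolds: int
    total_span: int  # bp including N
    total_bases: int  # bp excluding N
    gc_percent: float  # of non-N bases
    n50: int  # span-based (default convention)
    n50_ungapped: int  # computed on N-free lengths
    max_scaffold: int
    mean_exons_per_gene: Optional[float] = None
    mean_exon_size: Optional[float] = None
    mean_cds_size: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _n50(lengths: list[int]) -> int:
    total = sum(lengths)
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if 2 * acc >= total:
            return length
    return 0


def compute_assembly_stats(
    scaffolds: Mapping[str, str],
    gene_models: Optional[Iterable] = None,
) -> AssemblyStats:
    """Compute contiguity/composition statistics for a scaffold collection.

    ``scaffolds`` maps scaffold id to sequence over {A,C,G,T,N} (case
    insensitive).  When ``gene_models`` (GeneModel objects) are supplied the
    gene-derived means (exons per gene, exon size, CDS size) are added.
    Raises on an empty collection and on any non-IUPAC character, naming the
    offending scaffold and position.
    """
    if not scaffolds:
        raise ValueError("empty assembly: no scaffolds")
    spans, bases = [], []
    gc = at = 0
    for name, seq in scaffolds.items():
        up = seq.upper()
        invalid = set(up) - VALID_CHARS
        if invalid:
            pos = next(i for i, c in enumerate(up) if c in invalid)
            raise ValueError(
                f"non-IUPAC character {up[pos]!r} in scaffold {name!r} at position {pos}"
            )
        spans.append(len(up))
        n_count = up.count("N")
        bases.append(len(up) - n_count)
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    total_bases = sum(bases)
    stats = AssemblyStats(
        n_scaffolds=len(spans),
        total_span=sum(spans),
        total_bases=total_bases,
        gc_percent=100.0 * gc / total_bases if total_bases else 0.0,
        n50=_n50(spans),
        n50_ungapped=_n50(bases),
        max_scaffold=max(spans),
    )
    if gene_models is not None:
        models = list(gene_models)
        if models:
            exon_sizes = [e - s for m in models for s, e in m.exons]
            stats.mean_exons_per_gene = len(exon_sizes) / len(models)
            stats.mean_exon_size = sum(exon_sizes) / len(exon_sizes)
            stats.mean_cds_size = sum(exon_sizes) / len(models)
    return stats
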