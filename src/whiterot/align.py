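"""Shared pairwise-alignment core.

All protein comparisons in the toolkit go through Biopython's
:class:`Bio.Align.PairwiseAligner` (affine gaps, BLOSUM62).  Expectation
values for local alignments use the Karlin–Altschul formula

    E = K * m * n * exp(-lambda * S)

with fixed constants for gapped BLOSUM62 scoring (lambda = 0.267,
K = 0.041, the standard gapped parameters for BLOSUM62 with open 11 /
extend 1 penalties).  These constants are adequate for thresholding
desk-scale comparisons; precomputed tabular hits from a real search engine
remain the fidelity path for large inputs.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: Karlin–Altschul constants for gapped BLOSUM62 (open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041


@lru_cache(maxsize=None)
def protein_aligner(mode: str = "local") -> Align.PairwiseAligner:
    """A BLOSUM62 affine-gap aligner (open 11, extend 1, as in blastp)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_score(a: str, b: str) -> float:
    """Best local alignment score of two protein sequences."""
    return float(protein_aligner("local").score(a, b))


def ka_evalue(score: float, m: int, n: int) -> float:
    """Karlin–Altschul expectation for a raw local score over an m x n search."""
    if score <= 0:
        return float("inf")
    return KA_K * m * n * math.exp(-KA_LAMBDA * score)


def local_evalue(a: str, b: str) -> tuple[float, float]:
    """(score, E-value) of the best local alignment of ``a`` vs ``b``."""
    s = local_score(a, b)
    return s, ka_evalue(s, len(a), len(b))


def bit_score(score: float) -> float:
    """Normalized bit score S' = (lambda*S - ln K) / ln 2."""
    return (KA_LAMBDA * score - math.log(KA_K)) / math.log(2)


def global_alignment(a: str, b: str):
    """Best global alignment (needed for reference-anchored residue mapping)."""
    aligner = protein_aligner("global")
    return next(iter(aligner.align(a, b)))


def alignment_identity(alignment) -> float:
    """Fraction of aligned columns (both residues) that are identical."""
    a_aln, b_aln = alignment[0], alignment[1]
    matches = compared = 0
    for x, y in zip(a_aln, b_aln):
        if x == "-" or y == "-":
            continue
        compared += 1
        if x == y:
            matches += 1
    return matches / compared if compared else 0.0
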