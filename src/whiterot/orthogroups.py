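"""Orthologous-group construction from all-vs-all protein similarity.

The pipeline follows the published OrthoMCL algorithm at desk scale:

1. all-vs-all protein comparison kept at an E-value cutoff (default 1e-8);
2. putative *ortholog* edges = reciprocal best hits between species pairs;
3. putative *in-paralog* edges = within-species pairs scoring at least as
   well as either member's best inter-species hit;
4. edge weights = -log10(E), capped at 300 for E = 0, then normalized per
   species pair by the pair's average weight;
5. Markov clustering (iterated expansion/inflation) on the weighted graph
   yields the orthologous groups (OGs); singletons are allowed.

Bi-directional best hits (RBH at a stricter cutoff, default 1e-10) are also
exposed directly for one-to-one annotation transfer between two proteomes.

Comparisons use the built-in local aligner (affine-gap BLOSUM62 scoring with
fixed Karlin-Altschul constants, see :mod:`whiterot.align`); precomputed
12-column tabular hits from a dedicated search engine can be imported
instead and are the fidelity path for large inputs.
"""

from __future__ import annotations

import itertools
import math
import warnings
from collections import namedtuple
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .align import bit_score, ka_evalue, local_evalue, protein_aligner

#: -log10(E) cap used for E = 0 (mirrors common OrthoMCL practice).
WEIGHT_CAP = 300.0

DEFAULT_EVALUE = 1e-8
DEFAULT_INFLATION = 1.5

Member = namedtuple("Member", "species protein_id length")


@dataclass
class SimilarityHit:
    query: str
    subject: str
    query_species: str
    subject_species: str
    bits: float
    e_value: float
    pident: float = 0.0
    length: int = 0
    query_cov: float = 0.0
    subject_cov: float = 0.0

    @property
    def is_self(self) -> bool:
        return self.query == self.subject

    def sort_key(self):
        """Deterministic 'better hit' key: bits, then coverage, then id."""
        return (-self.bits, -self.query_cov, self.subject)


@dataclass
class OrthoGroup:
    og_id: str
    members: list = field(default_factory=list)  # Member tuples

    @property
    def species(self) -> set[str]:
        return {m.species for m in self.members}

    @property
    def protein_ids(self) -> list[str]:
        return [m.protein_id for m in self.members]


# ---------------------------------------------------------------------------
# similarity search

def all_vs_all_similarity(
    proteomes: dict[str, dict[str, str]],
    e_cutoff: float = DEFAULT_EVALUE,
) -> list[SimilarityHit]:
    """All ordered pairs above the cutoff, via the built-in local aligner.

    ``proteomes`` maps species -> {protein_id: sequence}; ids must be unique
    across species.  Hits are emitted symmetrically (both orderings of each
    unordered pair) and deterministically; self-hits are excluded.
    """
    if len(proteomes) < 2:
        raise ValueError("need at least two proteomes")
    species_of: dict[str, str] = {}
    seqs: dict[str, str] = {}
    for sp, prots in proteomes.items():
        for pid, seq in prots.items():
            if pid in species_of:
                raise ValueError(f"duplicate protein id {pid!r} across proteomes")
            species_of[pid] = sp
            seqs[pid] = seq
    hits: list[SimilarityHit] = []
    aligner = protein_aligner("local")
    ids = sorted(seqs)
    for a, b in itertools.combinations(ids, 2):
        score = float(aligner.score(seqs[a], seqs[b]))
        e = ka_evalue(score, len(seqs[a]), len(seqs[b]))
        if e > e_cutoff:
            continue
        aln = next(iter(aligner.align(seqs[a], seqs[b])))
        a_aln, b_aln = aln[0], aln[1]
        matches = sum(1 for x, y in zip(a_aln, b_aln) if x == y and x != "-")
        aln_len = len(a_aln)
        a_res = sum(1 for x in a_aln if x != "-")
        b_res = sum(1 for x in b_aln if x != "-")
        common = dict(
            bits=bit_score(score), e_value=e, length=aln_len,
            pident=100.0 * matches / aln_len if aln_len else 0.0,
        )
        hits.append(SimilarityHit(
            query=a, subject=b, query_species=species_of[a],
            subject_species=species_of[b],
            query_cov=a_res / len(seqs[a]), subject_cov=b_res / len(seqs[b]),
            **common,
        ))
        hits.append(SimilarityHit(
            query=b, subject=a, query_species=species_of[b],
            subject_species=species_of[a],
            query_cov=b_res / len(seqs[b]), subject_cov=a_res / len(seqs[a]),
            **common,
        ))
    return hits


def bidirectional_best_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    e_cutoff: float = 1e-10,
) -> list[tuple[str, str]]:
    """Pairs (a, b) that are each other's best hit at the cutoff.

    Ties are broken by higher raw score then lexicographic subject id.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")

    def best_hits(src: dict[str, str], dst: dict[str, str]) -> dict[str, str]:
        best = {}
        for q, qseq in src.items():
            candidates = []
            for s, sseq in dst.items():
                score, e = local_evalue(qseq, sseq)
                if e <= e_cutoff:
                    candidates.append((-score, s))
            if candidates:
                best[q] = min(candidates)[1]
        return best

    a_best = best_hits(proteome_a, proteome_b)
    b_best = best_hits(proteome_b, proteome_a)
    return sorted(
        (a, b) for a, b in a_best.items() if b_best.get(b) == a
    )


# ---------------------------------------------------------------------------
# 12-column tabular interchange

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(path, species_of) -> list[SimilarityHit]:
    """Read 12-column tabular hits; ``species_of`` maps protein id -> species."""
    hits = []
    get_species = species_of.get if hasattr(species_of, "get") else species_of
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"{path}:{lineno}: expected 12 tab-separated fields, got {len(fields)}"
            )
        try:
            q, s = fields[0], fields[1]
            hits.append(SimilarityHit(
                query=q, subject=s,
                query_species=get_species(q), subject_species=get_species(s),
                pident=float(fields[2]), length=int(fields[3]),
                e_value=float(fields[10]), bits=float(fields[11]),
            ))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed tabular line: {exc}") from exc
    return hits


def write_tabular_hits(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query}\t{h.subject}\t{h.pident:.2f}\t{h.length}\t0\t0\t"
                f"0\t0\t0\t0\t{h.e_value:.3g}\t{h.bits:.1f}\n"
            )


# ---------------------------------------------------------------------------
# Markov clustering

@dataclass
class ClusterResult:
    clusters: list  # list of frozensets of node labels
    converged: bool
    n_iter: int


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = DEFAULT_INFLATION,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterResult:
    """Markov clustering of a weighted undirected graph.

    The adjacency matrix (plus self loops at each column's maximum weight)
    is made column-stochastic, then expansion (matrix square) and inflation
    (entrywise power + renormalization) are iterated until the matrix
    changes by less than ``tol`` or ``max_iter`` is reached (warning, result
    flagged unconverged).  Clusters are read off the attractor rows.
    Node order never affects the partition: nodes are processed sorted.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return ClusterResult([], True, 0)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    mat = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("negative edge weight")
        mat[index[a], index[b]] = w
        mat[index[b], index[a]] = w
    # self loops: column max (or 1 for isolated nodes)
    col_max = mat.max(axis=0)
    np.fill_diagonal(mat, np.where(col_max > 0, col_max, 1.0))
    mat /= mat.sum(axis=0, keepdims=True)

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = mat @ mat
        new = np.power(new, inflation)
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        diff = np.abs(new - mat).max()
        mat = new
        if diff < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge in {max_iter} iterations", RuntimeWarning
        )
    mat[mat < 1e-9] = 0.0
    # attractors have mass on their own diagonal; each cluster is the set of
    # nodes attracted to one attractor row-support
    attractors = np.flatnonzero(np.diag(mat) > 1e-6)
    clusters_idx: list[set[int]] = []
    for a in attractors:
        support = set(np.flatnonzero(mat[a] > 1e-6)) | {int(a)}
        for existing in clusters_idx:
            if existing & support:
                existing |= support
                break
        else:
            clusters_idx.append(support)
    # merge any chains created late
    merged = True
    while merged:
        merged = False
        for i in range(len(clusters_idx)):
            for j in range(i + 1, len(clusters_idx)):
                if clusters_idx[i] & clusters_idx[j]:
                    clusters_idx[i] |= clusters_idx[j]
                    del clusters_idx[j]
                    merged = True
                    break
            if merged:
                break
    assigned = set().union(*clusters_idx) if clusters_idx else set()
    for i in range(n):  # nodes with no attractor become singletons
        if i not in assigned:
            clusters_idx.append({i})
    clusters = sorted(
        (frozenset(nodes[i] for i in c) for c in clusters_idx),
        key=lambda c: (-len(c), sorted(map(str, c))),
    )
    return ClusterResult(clusters, converged, it)


# ---------------------------------------------------------------------------
# orthogroup assembly

def _neg_log10(e: float) -> float:
    if e <= 0:
        return WEIGHT_CAP
    return min(-math.log10(e), WEIGHT_CAP)


def build_orthogroups(
    hits: list[SimilarityHit],
    inflation: float = DEFAULT_INFLATION,
    proteins: dict[str, tuple[str, int]] | None = None,
) -> list[OrthoGroup]:
    """Build OGs from cutoff-filtered hits via RBH + in-paralog edges + MCL.

    ``proteins`` optionally maps protein id -> (species, length): it fixes
    the protein universe (so proteins without qualifying hits come out as
    singletons) and supplies member lengths.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    species_of: dict[str, str] = {}
    lengths: dict[str, int | None] = {}
    if proteins:
        for pid, (sp, length) in proteins.items():
            species_of[pid] = sp
            lengths[pid] = length
    for h in hits:
        species_of.setdefault(h.query, h.query_species)
        species_of.setdefault(h.subject, h.subject_species)

    # best hit of each protein in each *other* species, and per-pair weights
    best: dict[tuple[str, str], SimilarityHit] = {}
    best_inter_weight: dict[str, float] = {}
    pair_weight: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.is_self:
            continue
        key = (min(h.query, h.subject), max(h.query, h.subject))
        w = _neg_log10(h.e_value)
        pair_weight[key] = max(pair_weight.get(key, 0.0), w)
        if h.query_species != h.subject_species:
            bkey = (h.query, h.subject_species)
            cur = best.get(bkey)
            if cur is None or h.sort_key() < cur.sort_key():
                best[bkey] = h
            best_inter_weight[h.query] = max(best_inter_weight.get(h.query, 0.0), w)

    graph = nx.Graph()
    graph.add_nodes_from(species_of)
    # ortholog edges: reciprocal best hits
    for (q, _), h in best.items():
        back = best.get((h.subject, h.query_species))
        if back is not None and back.subject == q and q < h.subject:
            graph.add_edge(q, h.subject,
                           weight=pair_weight[(min(q, h.subject), max(q, h.subject))],
                           kind="ortholog")
    # in-paralog edges: within-species pairs at least as good as either
    # member's best inter-species hit
    for (a, b), w in pair_weight.items():
        if species_of[a] != species_of[b]:
            continue
        if w >= best_inter_weight.get(a, 0.0) and w >= best_inter_weight.get(b, 0.0):
            graph.add_edge(a, b, weight=w, kind="in-paralog")

    # normalize weights per species pair by the pair's average weight
    sums: dict[tuple[str, str], list[float]] = {}
    for a, b, data in graph.edges(data=True):
        spair = tuple(sorted((species_of[a], species_of[b])))
        sums.setdefault(spair, []).append(data["weight"])
    averages = {k: sum(v) / len(v) for k, v in sums.items()}
    for a, b, data in graph.edges(data=True):
        spair = tuple(sorted((species_of[a], species_of[b])))
        avg = averages[spair]
        data["weight"] = data["weight"] / avg if avg > 0 else 0.0

    result = mcl_cluster(graph, inflation=inflation)
    groups = []
    for i, cluster in enumerate(result.clusters, start=1):
        members = sorted(
            Member(species_of[p], p, lengths.get(p)) for p in cluster
        )
        groups.append(OrthoGroup(og_id=f"OG{i:05d}", members=members))
    return groups


def write_orthogroups(groups: list[OrthoGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("og_id\tspecies\tprotein_id\n")
        for og in groups:
            for m in og.members:
                fh.write(f"{og.og_id}\t{m.species}\t{m.protein_id}\n")
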