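"""Phylogenomic GO propagation through orthologous groups.

The procedure annotates a focal proteome by exploiting orthology instead of
single-gene homology searches: OGs containing at least one focal-species
member are selected; within each OG the members are ordered by a species
priority list (focal species first, then the comparison genomes) and by
descending length within a species; members are consulted in that order
against a reference database at a *strict* E-value threshold (default
1e-120), and the first member that retrieves any GO terms supplies the
annotation for every focal gene in the OG (the walk stops there).  Focal
genes in no OG ("orphans") fall back to the same strict-threshold mapping
on their own hits.

Depth of a term in the ontology is the longest is_a path from its category
root (root = depth 0), matching a bottom-up recursive depth search; a
shortest-path variant is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .orthogroups import OrthoGroup

STRICT_E = 1e-120

CATEGORY_ROOTS = {
    "biological_process": "GO:0008150",
    "cellular_component": "GO:0005575",
    "molecular_function": "GO:0003674",
}


@dataclass
class SpeciesPriority:
    """Ordered species list; rank 1 is the focal species."""

    species: list

    def __post_init__(self):
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species in priority list")

    @property
    def focal(self) -> str:
        return self.species[0]

    def rank(self, species: str) -> int:
        try:
            return self.species.index(species)
        except ValueError:
            return len(self.species)  # unlisted species sink to the end


@dataclass
class GOAnnotation:
    gene_id: str
    terms: frozenset
    source_member: str  # OG member whose hits supplied the terms
    source_hit: str  # reference protein the terms were mapped from
    source_evalue: float
    route: str  # 'og-propagated' | 'orphan-direct'


# ---------------------------------------------------------------------------
# ontology loading

def load_ontology(path) -> nx.MultiDiGraph:
    """Read an OBO file (is_a edges; obsolete terms dropped with a warning).

    ``alt_id`` resolution: :func:`resolve_term` maps alternate ids to their
    primary id using the ``alt_id`` attributes obonet preserves.
    """
    graph = obonet.read_obo(str(path), ignore_obsolete=False)
    obsolete = [n for n, d in graph.nodes(data=True) if d.get("is_obsolete") == "true"]
    if obsolete:
        warnings.warn(f"dropping {len(obsolete)} obsolete GO terms")
        graph.remove_nodes_from(obsolete)
    return graph


def alt_id_map(graph: nx.MultiDiGraph) -> dict[str, str]:
    mapping = {}
    for node, data in graph.nodes(data=True):
        for alt in data.get("alt_id", []):
            mapping[alt] = node
    return mapping


def read_go_map(path) -> dict[str, set[str]]:
    """Tab-separated protein accession -> comma/semicolon-separated GO ids."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            acc, terms = line.split("\t")[:2]
            mapping[acc] = {
                t.strip() for t in terms.replace(";", ",").split(",") if t.strip()
            }
    return mapping


# ---------------------------------------------------------------------------
# OG selection and ordering

def select_focal_ogs(ogs: Iterable[OrthoGroup], focal_species: str) -> list[OrthoGroup]:
    """Exactly the OGs with at least one focal-species member, order preserved."""
    ogs = list(ogs)
    known = {m.species for og in ogs for m in og.members}
    if focal_species not in known:
        raise ValueError(f"unknown focal species {focal_species!r}")
    return [og for og in ogs if focal_species in og.species]


def order_og_members(
    og: OrthoGroup,
    priority: SpeciesPriority,
    lengths: Mapping[str, int] | None = None,
    longest_first: bool = True,
):
    """Members ordered by species rank, then length, then id.

    Within a species, longer sequences come first by default (the longer
    isoform is read as the more informative one); ``longest_first=False``
    inverts that.  Missing lengths sort after known ones.
    """
    def length_of(m):
        if m.length is not None:
            return m.length
        if lengths is not None:
            return lengths.get(m.protein_id)
        return None

    sign = -1 if longest_first else 1

    def key(m):
        length = length_of(m)
        return (
            priority.rank(m.species),
            (1, 0) if length is None else (0, sign * length),
            m.protein_id,
        )

    return sorted(og.members, key=key)


# ---------------------------------------------------------------------------
# propagation

def _qualifying_terms(member_id, hits, go_map, strict_e):
    """Terms mapped from this member's hits at E <= strict_e.

    Hits are (reference_id, e_value) pairs; the best-E informative hit is
    recorded as provenance.
    """
    best = None
    terms: set[str] = set()
    for ref_id, e in sorted(hits.get(member_id, []), key=lambda h: (h[1], h[0])):
        if e > strict_e:
            continue
        mapped = go_map.get(ref_id)
        if mapped:
            terms |= set(mapped)
            if best is None:
                best = (ref_id, e)
    return terms, best


def propagate_go(
    og: OrthoGroup,
    priority: SpeciesPriority,
    reference_hits: Mapping[str, list],
    go_map: Mapping[str, set],
    strict_e: float = STRICT_E,
    lengths: Mapping[str, int] | None = None,
) -> list[GOAnnotation]:
    """Walk OG members in priority order; first informative member annotates.

    The terms retrieved from the first member with any qualifying hit are
    attached to *every* focal gene in the OG and the walk stops.  An OG
    where no member yields terms produces no annotations (a valid outcome).
    """
    if strict_e <= 0:
        raise ValueError("strict_e must be positive")
    ordered = order_og_members(og, priority, lengths=lengths)
    focal_genes = [m.protein_id for m in og.members if m.species == priority.focal]
    for member in ordered:
        terms, best = _qualifying_terms(member.protein_id, reference_hits,
                                        go_map, strict_e)
        if terms:
            return [
                GOAnnotation(
                    gene_id=g, terms=frozenset(terms),
                    source_member=member.protein_id,
                    source_hit=best[0], source_evalue=best[1],
                    route="og-propagated",
                )
                for g in focal_genes
            ]
    return []


def annotate_ogs(
    ogs: Iterable[OrthoGroup],
    priority: SpeciesPriority,
    reference_hits: Mapping[str, list],
    go_map: Mapping[str, set],
    strict_e: float = STRICT_E,
) -> list[GOAnnotation]:
    """Select focal OGs and propagate through each (convenience wrapper)."""
    annotations = []
    for og in select_focal_ogs(ogs, priority.focal):
        annotations.extend(
            propagate_go(og, priority, reference_hits, go_map, strict_e)
        )
    return annotations


def annotate_orphans(
    orphan_genes: Iterable[str],
    reference_hits: Mapping[str, list],
    go_map: Mapping[str, set],
    strict_e: float = STRICT_E,
) -> list[GOAnnotation]:
    """Direct strict-threshold mapping for focal genes outside any OG."""
    annotations = []
    for gene in orphan_genes:
        terms, best = _qualifying_terms(gene, reference_hits, go_map, strict_e)
        if terms:
            annotations.append(
                GOAnnotation(
                    gene_id=gene, terms=frozenset(terms),
                    source_member=gene, source_hit=best[0],
                    source_evalue=best[1], route="orphan-direct",
                )
            )
    return annotations


# ---------------------------------------------------------------------------
# depth and summaries

def term_namespace(graph: nx.MultiDiGraph, term: str) -> str | None:
    return graph.nodes[term].get("namespace") if term in graph else None


def go_term_depth(graph: nx.MultiDiGraph, term: str, longest: bool = True) -> int:
    """Depth of ``term``: longest (default) or shortest is_a path from its root."""
    namespace = term_namespace(graph, term)
    root = CATEGORY_ROOTS.get(namespace)
    if root is None or term not in graph:
        raise KeyError(term)
    if term == root:
        return 0
    lengths = []
    # obonet edges point child -> parent; walk upwards
    sub = nx.MultiDiGraph(
        (u, v) for u, v, k in graph.edges(keys=True) if k == "is_a"
    )
    if term not in sub or not nx.has_path(sub, term, root):
        raise KeyError(f"{term} not connected to {root}")
    for path in nx.all_simple_paths(sub, term, root):
        lengths.append(len(path) - 1)
    return max(lengths) if longest else min(lengths)


def go_depth(
    annotations: Iterable[GOAnnotation],
    graph: nx.MultiDiGraph,
    longest: bool = True,
) -> dict[str, dict[int, int]]:
    """Histogram of annotated-term depths per GO category.

    Terms absent from the ontology are tallied under the pseudo-category
    ``"missing"`` with a warning rather than failing the run.
    """
    hist: dict[str, dict[int, int]] = {}
    missing = 0
    for ann in annotations:
        for term in ann.terms:
            if term not in graph:
                missing += 1
                hist.setdefault("missing", {})
                hist["missing"][0] = hist["missing"].get(0, 0) + 1
                continue
            namespace = term_namespace(graph, term)
            depth = go_term_depth(graph, term, longest=longest)
            cat = hist.setdefault(namespace, {})
            cat[depth] = cat.get(depth, 0) + 1
    if missing:
        warnings.warn(f"{missing} annotated terms absent from the ontology")
    return hist


def annotation_summary(
    annotations: Iterable[GOAnnotation],
    graph: nx.MultiDiGraph,
) -> dict[str, int]:
    """Genes per GO category; a gene counts once in every category it touches."""
    counts = {ns: 0 for ns in CATEGORY_ROOTS}
    seen: dict[str, set[str]] = {ns: set() for ns in CATEGORY_ROOTS}
    for ann in annotations:
        for term in ann.terms:
            ns = term_namespace(graph, term)
            if ns in seen and ann.gene_id not in seen[ns]:
                seen[ns].add(ann.gene_id)
                counts[ns] += 1
    return counts


def write_annotations(annotations: Iterable[GOAnnotation], path) -> None:
    """GAF-like TSV: gene, term, route and provenance columns."""
    with open(path, "w") as fh:
        fh.write("gene_id\tgo_id\troute\tsource_member\tsource_hit\tsource_evalue\n")
        for ann in annotations:
            for term in sorted(ann.terms):
                fh.write(
                    f"{ann.gene_id}\t{term}\t{ann.route}\t{ann.source_member}\t"
                    f"{ann.source_hit}\t{ann.source_evalue:.3g}\n"
                )
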