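"""Synthetic genomes, proteomes and peroxidase sets with planted ground truth.

Every generator takes a :class:`SimulationConfig` and returns the simulated
data together with a :class:`SyntheticTruth` describing exactly what was
planted, so each downstream stage (orthogroup construction, GO propagation,
repeat annotation, peroxidase classification, splice-site validation) can be
scored against a known answer without any external download.

Model choices, deliberately simple so that truth stays exact:

* substitutions are drawn per site with a uniform replacement model (a site
  mutates with probability equal to the substitution rate and is replaced by
  a uniformly chosen *different* letter); no indels are introduced in
  proteins, which keeps residue-position truth exact;
* within-species duplicates (in-paralogs) are re-mutated from the species
  copy at a quarter of the species-level rate, so the sibling pair is always
  expected to be more similar to each other than to any cross-species member;
* GO labels are attached at the family level — orthology is assumed to
  conserve function — mirroring the propagation assumption of the annotation
  pipeline;
* planted genome features are placed collision-free by rejection sampling
  with a bounded number of retries.

All randomness flows from ``config.seed`` through ``numpy`` generators, so a
fixed seed gives byte-identical FASTA output across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .peroxidase import SUBTYPES, load_reference_profile
from .seqio import fasta_bytes, write_bed, write_fasta, write_gff3_genes

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: background alphabet for peroxidase mutagenesis — no Cys/Trp, so that
#: disulfide counts and the single catalytic tryptophan stay exact.
AA_BACKGROUND = "ADEFGHIKLMNPQRSTVY"
NT_ALPHABET = "ACGT"


class PlacementError(RuntimeError):
    """A planted genome feature could not be placed without collision."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study system.

    Defaults emulate a desk-scale version of a polypore genome project: a
    handful of related proteomes with moderate divergence, a GC-rich genome
    (the assembly under study has GC ~52.5%), and a few planted repeat and
    gene features per scaffold.
    """

    seed: int = 0
    n_species: int = 4
    n_families: int = 20
    duplication_rate: float = 0.1
    substitution_rate: float = 0.05
    protein_length: int = 200
    genome_length: int = 100_000
    gc_fraction: float = 0.525
    planted_te_specs: list = field(default_factory=list)
    planted_ssr_specs: list = field(default_factory=list)
    planted_tandem_specs: list = field(default_factory=list)
    planted_gene_specs: list = field(default_factory=list)
    class2_counts: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("duplication_rate", "substitution_rate", "gc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.protein_length <= 0:
            raise ValueError("zero-length ancestral proteins are not allowed")
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every simulated dataset."""

    family_membership: dict = field(default_factory=dict)  # protein id -> family id
    go_labels: dict = field(default_factory=dict)  # family id -> set of GO ids
    repeat_intervals: list = field(default_factory=list)  # (scaf, start, end, class, name)
    gene_models: list = field(default_factory=list)  # GeneModel objects
    class2_labels: dict = field(default_factory=dict)  # sequence id -> subtype
    te_library: dict = field(default_factory=dict)  # consensus name -> sequence
    protein_species: dict = field(default_factory=dict)  # protein id -> species


# ---------------------------------------------------------------------------
# toy ontology

def toy_ontology() -> nx.MultiDiGraph:
    """A small deterministic GO-like DAG with the three real category roots.

    Shaped like ``obonet`` output: one node per term with ``name`` and
    ``namespace`` attributes, edges child -> parent keyed ``is_a``.  Each
    category has three mid-level terms with two leaves each, and one extra
    diamond edge (a leaf with two parents) so longest-path and shortest-path
    depths differ somewhere.
    """
    graph = nx.MultiDiGraph()
    roots = {
        "GO:0008150": "biological_process",
        "GO:0005575": "cellular_component",
        "GO:0003674": "molecular_function",
    }
    counter = 1
    for root, namespace in roots.items():
        graph.add_node(root, name=namespace, namespace=namespace)
        mids = []
        for _ in range(3):
            mid = f"GO:{7000000 + counter:07d}"
            counter += 1
            graph.add_node(mid, name=f"syn term {mid}", namespace=namespace)
            graph.add_edge(mid, root, key="is_a")
            mids.append(mid)
        for mid in mids:
            for _ in range(2):
                leaf = f"GO:{7000000 + counter:07d}"
                counter += 1
                graph.add_node(leaf, name=f"syn term {leaf}", namespace=namespace)
                graph.add_edge(leaf, mid, key="is_a")
        # diamond: last leaf also hangs directly off the root
        graph.add_edge(leaf, root, key="is_a")
    return graph


def toy_ontology_obo(path) -> None:
    """Serialize :func:`toy_ontology` as an OBO v1.2 file (for reader tests)."""
    graph = toy_ontology()
    lines = ["format-version: 1.2", "ontology: go-synthetic", ""]
    for node in sorted(graph.nodes):
        attrs = graph.nodes[node]
        lines += [
            "[Term]",
            f"id: {node}",
            f"name: {attrs['name']}",
            f"namespace: {attrs['namespace']}",
        ]
        for _, parent, key in sorted(graph.out_edges(node, keys=True)):
            if key == "is_a":
                lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def ontology_leaves(graph: nx.MultiDiGraph) -> list[str]:
    """Terms with no children (no incoming is_a edges), sorted."""
    return sorted(n for n in graph.nodes if graph.in_degree(n) == 0)


# ---------------------------------------------------------------------------
# mutation helpers

def _mutate(seq: str, rate: float, rng: np.random.Generator, alphabet: str,
            frozen: set[int] = frozenset()) -> str:
    """Per-site uniform substitution to a different letter with probability ``rate``."""
    if rate == 0.0:
        return seq
    out = list(seq)
    hit = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hit:
        if i in frozen:
            continue
        choices = [c for c in alphabet if c != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AA_ALPHABET[i] for i in rng.integers(0, len(AA_ALPHABET), length))


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return "".join(NT_ALPHABET[i] for i in rng.choice(4, size=length, p=probs))


# ---------------------------------------------------------------------------
# proteomes

def generate_proteome_set(config: SimulationConfig):
    """Simulate one proteome per species with planted families and in-paralogs.

    Returns ``(proteomes, truth)`` where ``proteomes`` maps species name to an
    ordered ``{protein_id: sequence}`` dict.  Each family derives from one
    ancestral protein, mutated independently per species; with probability
    ``duplication_rate`` a species carries two in-paralog copies re-mutated at
    a quarter of the species rate.  Family-level GO labels are drawn from the
    toy ontology.
    """
    config.validate()
    if config.n_species < 2:
        raise ValueError("need at least two species")
    if config.n_families < 1:
        raise ValueError("need at least one family")

    rng = np.random.default_rng([config.seed, 11])
    leaves = ontology_leaves(toy_ontology())
    species = [f"sp{i + 1}" for i in range(config.n_species)]
    proteomes: dict[str, dict[str, str]] = {sp: {} for sp in species}
    truth = SyntheticTruth()
    counters = {sp: 0 for sp in species}

    for fam_idx in range(config.n_families):
        fam_id = f"fam{fam_idx + 1:04d}"
        length = int(config.protein_length * (0.8 + 0.4 * rng.random()))
        ancestor = _random_protein(max(length, 1), rng)
        n_terms = int(rng.integers(1, 4))
        term_idx = rng.choice(len(leaves), size=n_terms, replace=False)
        truth.go_labels[fam_id] = {leaves[i] for i in sorted(term_idx)}
        for sp in species:
            base = _mutate(ancestor, config.substitution_rate, rng, AA_ALPHABET)
            n_copies = 2 if rng.random() < config.duplication_rate else 1
            for _ in range(n_copies):
                counters[sp] += 1
                pid = f"{sp}.g{counters[sp]:04d}"
                if n_copies == 1:
                    seq = base
                else:
                    seq = _mutate(base, config.substitution_rate / 4, rng, AA_ALPHABET)
                proteomes[sp][pid] = seq
                truth.family_membership[pid] = fam_id
                truth.protein_species[pid] = sp
    return proteomes, truth


# ---------------------------------------------------------------------------
# genome

def _place_features(lengths: list[int], genome_length: int,
                    rng: np.random.Generator, margin: int = 10,
                    max_tries: int = 1000) -> list[int]:
    """Collision-free start positions by rejection sampling (retry cap 1000)."""
    placed: list[tuple[int, int]] = []
    starts = []
    for length in lengths:
        if length > genome_length:
            raise PlacementError(f"feature of length {length} exceeds genome")
        for _ in range(max_tries):
            start = int(rng.integers(0, genome_length - length + 1))
            interval = (start - margin, start + length + margin)
            if all(interval[1] <= s or interval[0] >= e for s, e in placed):
                placed.append((start, start + length))
                starts.append(start)
                break
        else:
            raise PlacementError(
                f"could not place feature of length {length} after {max_tries} tries"
            )
    return starts


def _make_intron(length: int, gc: float, rng: np.random.Generator) -> str:
    if length < 4:
        raise ValueError("introns must be at least 4 bp for GT..AG ends")
    return "GT" + _random_dna(length - 4, gc, rng) + "AG"


def generate_genome(config: SimulationConfig):
    """Simulate one scaffold with planted TEs, SSRs, tandem arrays and genes.

    Planted features never overlap; the truth table records every interval as
    0-based half-open with its feature class.  TE copies are mutated per the
    requested per-copy divergence; introns of planted genes are GT..AG by
    construction.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 23])
    scaffold = "scf1"

    # build feature sequences first so total length is known
    features: list[tuple[str, str, str]] = []  # (class, name, sequence)
    truth = SyntheticTruth()
    for i, spec in enumerate(config.planted_te_specs):
        length, copies, divergence = spec
        name = f"te{i + 1}"
        consensus = _random_dna(length, config.gc_fraction, rng)
        truth.te_library[name] = consensus
        for c in range(copies):
            copy_seq = _mutate(consensus, divergence, rng, NT_ALPHABET)
            features.append(("te", f"{name}_copy{c + 1}", copy_seq))
    for i, (motif, units) in enumerate(config.planted_ssr_specs):
        features.append(("ssr", f"ssr{i + 1}_{motif}x{units}", motif * units))
    for i, spec in enumerate(config.planted_tandem_specs):
        period, copies = spec[0], spec[1]
        divergence = spec[2] if len(spec) > 2 else 0.0
        motif = _random_dna(period, config.gc_fraction, rng)
        array = "".join(
            _mutate(motif, divergence, rng, NT_ALPHABET) for _ in range(copies)
        )
        features.append(("tandem", f"tandem{i + 1}_p{period}x{copies}", array))
    gene_parts = []  # (name, [part lengths alternating exon/intron])
    for i, (n_exons, intron_lengths) in enumerate(config.planted_gene_specs):
        if len(intron_lengths) != n_exons - 1:
            raise ValueError("need exactly exon_count - 1 intron lengths")
        name = f"gene{i + 1}"
        exon_lengths = [int(rng.integers(100, 301)) * 3 for _ in range(n_exons)]
        parts = []
        for j, el in enumerate(exon_lengths):
            parts.append(("exon", _random_dna(el, config.gc_fraction, rng)))
            if j < n_exons - 1:
                parts.append(("intron", _make_intron(intron_lengths[j],
                                                     config.gc_fraction, rng)))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_parts.append((name, strand, parts))
        features.append(("gene", name, "".join(s for _, s in parts)))

    total_feature_len = sum(len(s) for _, _, s in features)
    if total_feature_len > config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} cannot hold "
            f"{total_feature_len} bp of planted features"
        )

    genome = list(_random_dna(config.genome_length, config.gc_fraction, rng))
    starts = _place_features([len(s) for _, _, s in features],
                             config.genome_length, rng)

    from .gene_structure import GeneModel

    gene_iter = iter(gene_parts)
    for (fclass, name, seq), start in zip(features, starts):
        genome[start:start + len(seq)] = seq
        truth.repeat_intervals.append((scaffold, start, start + len(seq), fclass, name))
        if fclass == "gene":
            gname, strand, parts = next(gene_iter)
            exons = []
            pos = start
            for kind, part in parts:
                if kind == "exon":
                    exons.append((pos, pos + len(part)))
                pos += len(part)
            if strand == "-":
                # feature sequence was built 5'->3' on the plus strand; for a
                # minus-strand model we reverse-complement the planted block
                # in place so the coding strand reads through revcomp
                from .seqio import revcomp

                genome[start:start + len(seq)] = revcomp(seq)
                span = start + len(seq)
                exons = sorted((span - e + start, span - s + start) for s, e in exons)
            truth.gene_models.append(
                GeneModel(gene_id=gname, scaffold=scaffold, strand=strand,
                          exons=sorted(exons))
            )
    truth.repeat_intervals.sort(key=lambda r: r[1])
    return {scaffold: "".join(genome)}, truth


# ---------------------------------------------------------------------------
# class II peroxidase sets

def generate_class2_set(config: SimulationConfig):
    """Simulate class II peroxidase sequences with planted subtypes.

    Starting from the bundled (synthetic) reference template — itself a
    VP-type configuration — background positions are mutated at
    ``substitution_rate`` and catalytic features are planted or ablated per
    subtype:

    * ``VP``: catalytic Trp + intact Glu/Glu/Asp Mn site (the template);
    * ``atypicalVP``: Trp + one conservative D/E swap in the Mn site;
    * ``LiP``: Trp + Mn site ablated (acidics replaced by non-acidics);
    * ``shortMnP``: Mn site intact, Trp replaced, no C-terminal extension;
    * ``longMnP``: Mn site intact, Trp replaced, 15-aa C-terminal extension
      carrying two extra cysteines;
    * ``GP``: Trp replaced and Mn site ablated.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 37])
    profile = load_reference_profile()
    template = profile.sequence
    frozen = set(p - 1 for p in profile.all_positions())

    seqs: dict[str, str] = {}
    truth = SyntheticTruth()
    for subtype in config.class2_counts:
        if subtype not in SUBTYPES:
            raise ValueError(f"unknown class II subtype {subtype!r}; "
                             f"expected one of {sorted(SUBTYPES)}")
    for subtype, count in config.class2_counts.items():
        for i in range(count):
            seq = list(_mutate(template, config.substitution_rate, rng,
                               AA_BACKGROUND, frozen=frozen))
            mn = sorted(int(p) for p in profile.features["mn_site"])
            trp = int(next(iter(profile.features["catalytic_trp"])))
            if subtype in ("LiP", "GP"):
                for p in mn:
                    seq[p - 1] = "ANT"[rng.integers(0, 3)]
            if subtype == "atypicalVP":
                p = mn[int(rng.integers(0, len(mn)))]
                seq[p - 1] = "D" if seq[p - 1] == "E" else "E"
            if subtype in ("shortMnP", "longMnP", "GP"):
                seq[trp - 1] = "F"
            if subtype == "longMnP":
                ext = list(_random_protein(15, rng).replace("C", "A").replace("W", "Y"))
                ext[3] = "C"
                ext[9] = "C"
                seq += ext
            sid = f"aa2_{subtype}_{i + 1}"
            seqs[sid] = "".join(seq)
            truth.class2_labels[sid] = subtype
    return seqs, truth


# ---------------------------------------------------------------------------
# truth writers

def write_truth_tables(truth: SyntheticTruth, outdir) -> None:
    """Write truth as plain-text tables (TSV/BED/GFF3/JSON) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if truth.family_membership:
        with open(outdir / "families.tsv", "w") as fh:
            fh.write("protein_id\tfamily_id\tspecies\n")
            for pid, fam in sorted(truth.family_membership.items()):
                fh.write(f"{pid}\t{fam}\t{truth.protein_species.get(pid, '')}\n")
    if truth.go_labels:
        with open(outdir / "go_labels.tsv", "w") as fh:
            fh.write("family_id\tgo_ids\n")
            for fam, terms in sorted(truth.go_labels.items()):
                fh.write(f"{fam}\t{','.join(sorted(terms))}\n")
    if truth.repeat_intervals:
        write_bed(
            [(s, a, b, f"{c}:{n}") for s, a, b, c, n in truth.repeat_intervals],
            outdir / "repeat_intervals.bed",
        )
    if truth.gene_models:
        write_gff3_genes(truth.gene_models, outdir / "gene_models.gff3")
    if truth.class2_labels:
        with open(outdir / "class2_labels.tsv", "w") as fh:
            fh.write("sequence_id\tsubtype\n")
            for sid, sub in sorted(truth.class2_labels.items()):
                fh.write(f"{sid}\t{sub}\n")
    if truth.te_library:
        write_fasta(truth.te_library, outdir / "te_library.fasta")


def proteome_set_bytes(proteomes: dict[str, dict[str, str]]) -> bytes:
    """Concatenated FASTA bytes of all proteomes (determinism checks)."""
    return b"".join(fasta_bytes(proteomes[sp]) for sp in proteomes)


def config_to_json(config: SimulationConfig, path) -> None:
    Path(path).write_text(json.dumps(config.__dict__, indent=1, default=list))


def config_from_json(path) -> SimulationConfig:
    data = json.loads(Path(path).read_text())
    return SimulationConfig(**data)
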