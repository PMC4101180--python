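# Methods

This note documents the models, parameter choices and numerical decisions
behind each module, what the synthetic data does and does not emulate, and
the known limitations.

## Synthetic data (`whiterot.simulate`)

The generators define a desk-scale study system with exact, inspectable
ground truth.

**Proteomes.** Each gene family derives from one random ancestral protein
(length drawn uniformly in 0.8–1.2 × `protein_length`, default 200 aa).
Per species, the ancestor is mutated with a per-site uniform replacement
model: a site substitutes with probability `substitution_rate` and receives
a uniformly chosen *different* residue. No indels are introduced in
proteins, which keeps residue-position truth exact (an indel mode was
deliberately not made the default for this reason). With probability
`duplication_rate` a species carries two in-paralog copies, each re-mutated
from the species copy at a quarter of the species rate, so the sibling pair
is expected to be closer to each other than to any cross-species member —
the property that defines in-paralogs in the orthogroup model. GO labels
attach at the family level (orthology is assumed to conserve function, the
same assumption the propagation pipeline makes), drawn from a small
deterministic GO-like DAG with the three real category roots.

**Genomes.** Background sequence is i.i.d. with the target GC (default
52.5 %, typical of a polypore assembly). Planted features — TE copies
mutated per a per-copy divergence, SSR runs, tandem arrays, GT-AG gene
models — are placed collision-free by rejection sampling with a retry cap
of 1000 (a `PlacementError` is raised beyond it). Truth intervals are
0-based half-open throughout; GFF3/BED writers convert at the boundary.
Minus-strand genes are built 5′→3′ and reverse-complemented in place, so
their splice sites read GT..AG on the coding strand and CT..AC on the
assembly's plus strand.

**Peroxidase sets.** The bundled reference template is *synthetic* (see
below); per requested subtype the template is mutated at background
positions — from an alphabet excluding Cys and Trp, so disulfide counts and
the single catalytic tryptophan stay exact — and catalytic features are
planted or ablated: VP keeps everything; atypical VP gets one conservative
D/E swap in the Mn triad; LiP has the triad ablated to non-acidics; short
MnP loses the tryptophan; long MnP additionally gains a 15-aa C-terminal
extension carrying two extra cysteines; GP loses both features.

What the simulations do **not** emulate: realistic phylogenetic branch
lengths (all species are equidistant from the ancestor), codon structure or
composition bias in coding regions, nested/fragmented repeats, and
sequencing artefacts. Passing tests therefore demonstrate algorithmic
correctness against the stated models, not performance on real assemblies,
where divergence structure and repeat nesting are harsher.

## Assembly statistics

N50 is the length L such that scaffolds of length ≥ L, in descending
order, cumulatively cover at least half the assembly. Published totals
distinguish gapped span from ungapped bases but rarely say which feeds the
N50, so both variants are computed; the span-based value is the default,
the common assembler convention. GC is computed over non-N bases;
soft-masked lowercase counts normally. Empty assemblies and non-IUPAC
characters are hard errors naming the offending scaffold and position.

## Orthogroups

The built-in all-vs-all search uses Biopython's `PairwiseAligner` (local,
BLOSUM62, gap open 11 / extend 1) with Karlin–Altschul expectations
E = K·m·n·e^(−λS) at fixed gapped-BLOSUM62 constants λ = 0.267, K = 0.041.
Fixed constants are adequate for *thresholding* at desk scale; importing
precomputed 12-column tabular hits is the fidelity path for large inputs.
Default cutoff 10⁻⁸.

Graph construction follows the published OrthoMCL algorithm: ortholog
edges are reciprocal best hits between species pairs (ties broken by bit
score, then coverage, then lexicographic id — determinism over speed);
in-paralog edges are within-species pairs scoring at least as well as
either member's best inter-species hit; weights are −log₁₀ E capped at 300
(the conventional floor for E = 0), normalized per species pair by the
pair's average weight. Markov clustering adds self-loops at each column's
maximum, column-normalizes, and iterates expansion/inflation (default
inflation 1.5, OrthoMCL's default) to a 10⁻⁶ sup-norm tolerance with a
100-iteration cap; non-convergence returns the current clustering flagged
with a warning. Nodes are always processed in sorted order, so the
partition is invariant to input order. Matrix entries below 10⁻⁹ are
zeroed before reading off attractors, and overlapping attractor supports
are merged, which guarantees the output partitions the protein universe.

## GO propagation

Members of each focal-species OG are ordered by species priority rank,
then by length *descending* (the longer isoform is read as the more
informative record; a flag inverts this), then id. Members are consulted
in that order: hits at E ≤ 10⁻¹²⁰ are mapped to GO, and the first member
yielding any terms annotates every focal gene in the OG, after which the
walk stops. Orphans (focal genes in no OG) reuse the same strict threshold
on their own hits — the pipeline treats "annotate directly as described
above" literally; a looser comparison profile can be selected by passing a
different `strict_e`. Term depth is the *longest* is_a path from the
category root (a bottom-up recursive search over parents), with a
shortest-path variant by flag; obsolete terms are dropped with a warning
and alt_ids resolve to primary ids. Category summaries multi-count: a gene
contributes to every category in which it has at least one term.

## Repeats

**Library filtering** applies, in order: length < 100 bp; genome copy
count < 10; translated hits to known non-TE proteins. Copy counting and
masking match each consensus against both strands with banded edit
distance (edlib) at ≥ 80 % identity; the two consensus halves are also
searched so truncated copies covering ≥ 50 % of the consensus are found.
The 80 % / 50 % thresholds mirror common RepeatMasker-era practice and are
configurable. The protein screen translates the consensus in six frames,
splits at stop codons, and compares fragments ≥ 15 aa by local alignment;
the significance cutoff (E ≤ 10⁻⁵) is a package decision, as no standard
value exists for this screen. Each removed record carries exactly one
reason — the first failing filter.

**Masking** merges overlapping match intervals before any coverage
arithmetic (total ≤ sum of parts by construction) and reports percent of
total span overall and per classification. Span (rather than ungapped
bases) is the denominator; synthetic genomes contain no N, so the choice
is only visible on gapped real assemblies.

**SSRs** are maximal perfect runs of primitive 1–6 bp motifs at the
published MISA defaults (mono 10, di 6, tri/tetra/penta/hexa 5). The scan
is left-to-right; at each position the smallest qualifying unit wins, so a
run is reported once at its fundamental period; runs never span an N;
motifs are reported strand-as-found (reverse-complement classes are not
collapsed, matching the original tool). Compound SSRs (interruptions
≤ 100 bp) are merged but reported separately from the simple tallies.

**Tandem repeats** use a simplified detector, explicitly an emulation of
the classical tool rather than a bit-compatible reimplementation. For each
trial period p (2 … 500), the self-recurrence mask s[i] = s[i+p] seeds
candidate arrays: True-runs are chained across gaps ≤ 3 (one substitution
in an array breaks the mask at two single positions) or when the next
run's match gain exceeds the gap's mismatch cost, then near-adjacent
candidates ≤ p apart are rejoined. Candidates are scored against their
per-column majority consensus with +2/−7 match/mismatch weights and kept
at score ≥ 50 with ≥ 2 copies; the indel weight and the pm = 80 / pi = 10
probabilities act only through the seeding heuristics (the model is
substitution-only; arrays with internal indels shift phase and are found
fragmented, a known limitation). Smaller periods are scanned first and
larger-period candidates overlapping an accepted locus are dropped, so
arrays report at their fundamental period. Periods 7–100 are
minisatellites, > 100 satellites; shorter periods are detected but belong
to neither class (SSR territory).

## Class II peroxidase classification

Solvent exposure of the catalytic tryptophan cannot be computed from
sequence, so the criterion is positional: the query is globally aligned to
an annotated reference (BLOSUM62, affine gaps) and every feature position
projects through the alignment; a gap at a feature position reports
"unalignable". The bundled template is a **synthetic** stand-in — a
constructed 331-aa sequence carrying the canonical VP-type features at
mature-protein-numbering positions (Mn site Glu36/Glu40/Asp175, distal
Arg43/His47, catalytic Trp164, proximal His169, eight cysteines), with a
background alphabet free of Cys/Trp so feature counts are exact. A curated
profile for real sequences can be supplied as JSON with the same schema.

Rules, applied in order: invalid scaffold (axial His or distal Arg
missing) → unclassifiable; Trp + canonical triad → VP; Trp + all-acidic
triad with exactly one D/E swap → atypical VP; Trp + incomplete triad →
LiP (a *non-conservative* change at one triad position with Trp present is
deliberately read as an incomplete site, hence LiP, with the substitution
recorded in the evidence); triad without Trp → MnP, split long/short on a
10–30 aa C-terminal extension and/or ≥ 10 cysteines; otherwise GP. The
function is total and deterministic. Queries below 25 % alignment identity
to the profile are flagged as profile mismatches (e.g. heme-thiolate
peroxidases) rather than forced into the rule table; queries outside
0.5–2× the reference length are rejected before alignment.

## Dendrograms

p-distances count differing sites over compared sites; pairwise deletion
(ignore positions gapped in either member of the pair) is the default gap
mode, complete deletion by flag. Poisson correction d = −ln(1 − p) is
exact for p < 1 and errors at saturation. UPGMA merges the closest pair
(ties broken by the lexicographically smallest pair — the reference
implementations leave tie order unspecified), sets node height to half the
merge distance, and updates distances as size-weighted arithmetic means.
Newick branch lengths are height differences printed to six decimals.
UPGMA trees are inherently rooted: a designated outgroup is only checked
to sit at the deepest split, with a warning otherwise. A column-resampling
bootstrap is not provided; trees here serve cluster illustration, not
support estimation.

## Gene structure

Introns are the gaps between consecutive exons of a model (0-based
half-open genomic intervals); validation requires GT..AG on the coding
strand, with minus-strand models evaluated on the reverse complement, and
introns < 4 bp invalid with a distinct reason. Six-frame translation
labels frames +1..+3/−1..−3 (frame −1 of S equals frame +1 of revcomp(S));
a forward-only three-frame view is the '+' subset. For structure
comparison, each intron maps to its codon index and phase (0 between
codons, 1/2 within), projects through a protein alignment, and is *shared*
only at equal aligned column **and** equal phase (tolerance 0 columns by
default — homologous intron positions are read strictly; configurable).
The similarity score is shared/union, symmetric by construction; families
group by single-linkage at a score threshold (default 0.5).

## Problem sizes

Tests and the acceptance script run on synthetic instances sized for a
single CPU: proteome sets of 3 species × 8 families (~25–35 proteins),
genomes of 20–100 kb, 100 small graphs for the exhaustive-partition
comparison (≤ 8 nodes, where enumerating all partitions is feasible), 300–
1000 × 2 kb sequences for the SSR oracle, and 5–10 seeds per recovery
statistic. These sizes were chosen so every quantity is recomputed from
scratch in minutes while keeping the planted-truth statistics stable
across seeds.
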