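"""Repeat-library filtering, genome masking, SSR and tandem-repeat annotation.

Four stages, mirroring a classical fungal-genome repeat annotation:

* **library filtering** of de-novo repeat consensuses, in order: (i) drop
  consensuses shorter than 100 bp; (ii) drop repeats with fewer than ten
  genome copies (they may be protein-coding gene families); (iii) drop
  repeats with significant translated hits to known proteins other than
  transposable-element (TE) proteins;
* **masking**: soft-mask every genome interval matching a retained
  consensus and report percent coverage overall and per TE classification,
  plus per-family copy counts;
* **SSR scan**: maximal perfect tandem runs of 1-6 bp motifs at per-unit
  minimum copy thresholds (mono 10, di 6, tri/tetra/penta/hexa 5 — the
  published MISA defaults), each run reported once at its smallest period;
* **tandem-repeat scan**: a simplified detector for minisatellites (period
  7-100 bp) and satellites (period >100 bp), parameterized like Tandem
  Repeats Finder (match 2, mismatch 7, indel 7, pm 80, pi 10, min score 50,
  max period 500).  It seeds candidate arrays from exact recurrence at the
  trial period and scores them against the array consensus with the
  match/mismatch weights; it is an emulation of the original tool, not a
  bit-compatible reimplementation (substitution-only model, no indel
  alignment within arrays).

Genome matching of consensuses (copy counting and masking) uses banded
edit-distance alignment (edlib) at >=80% identity; half-consensus queries
extend detection to truncated copies covering >=50% of the consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib
import numpy as np

from .align import ka_evalue, protein_aligner
from .gene_structure import six_frame_translate
from .seqio import revcomp

MISA_DEFAULT_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}

CLASSIFICATIONS = ("gypsy", "copia", "DIRS", "LINE", "class2-DNA", "uncategorized")


@dataclass
class RepeatConsensus:
    id: str
    sequence: str
    classification: str = "uncategorized"
    copy_count: int = 0
    provenance: str = "input"  # 'input' | 'filtered-out'
    reason: str | None = None  # exactly one reason when filtered out


@dataclass
class SSRLocus:
    scaffold: str
    start: int  # 0-based half-open
    end: int
    motif: str
    unit_length: int
    unit_count: int

    def __post_init__(self):
        assert self.end - self.start == self.unit_length * self.unit_count


@dataclass
class CompoundSSR:
    scaffold: str
    start: int
    end: int
    members: list  # constituent SSRLocus records


@dataclass
class TandemRepeatLocus:
    scaffold: str
    start: int
    end: int
    period: int
    copy_number: float
    score: int
    consensus: str

    @property
    def repeat_class(self) -> str | None:
        """'minisatellite' (period 7-100), 'satellite' (>100), None below 7."""
        if self.period > 100:
            return "satellite"
        if self.period >= 7:
            return "minisatellite"
        return None


@dataclass
class TandemParams:
    """Tandem-detector weights, defaulting to the classical 2;7;7;80;10;50;500."""

    match: int = 2
    mismatch: int = 7
    indel: int = 7
    match_probability: int = 80
    indel_probability: int = 10
    min_score: int = 50
    max_period: int = 500

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# consensus-to-genome matching

def _edlib_hits(query: str, target: str, max_dist: int) -> list[tuple[int, int, int]]:
    """Non-overlapping infix matches of ``query`` in ``target``.

    Scans overlapping windows of twice the query length so every copy is
    fully contained in at least one window, then takes the best infix
    alignment per window at edit distance <= ``max_dist``.
    Returns (start, end, distance) triples in target coordinates.
    """
    L = len(query)
    hits = []
    step = L
    for w_start in range(0, max(1, len(target) - L + 1), step):
        window = target[w_start:w_start + 2 * L]
        if len(window) < L // 2:
            continue
        res = edlib.align(query, window, mode="HW", task="locations", k=max_dist)
        if res["editDistance"] < 0:
            continue
        for s, e in res["locations"]:
            hits.append((w_start + s, w_start + e + 1, res["editDistance"]))
    # greedy non-overlapping selection, best (lowest distance) first
    hits.sort(key=lambda h: (h[2], h[0]))
    chosen: list[tuple[int, int, int]] = []
    for s, e, d in hits:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, d))
    return sorted(chosen)


def find_consensus_matches(
    genome: Mapping[str, str],
    consensus: str,
    min_identity: float = 0.8,
    min_coverage: float = 0.5,
) -> list[tuple[str, int, int]]:
    """Greedy non-overlapping genome matches of a repeat consensus.

    Both strands are searched.  Full-length matches require identity >=
    ``min_identity``; additionally the two consensus halves are searched so
    truncated copies covering >= ``min_coverage`` of the consensus are
    found.  Returns (scaffold, start, end) intervals on the forward strand.
    """
    L = len(consensus)
    queries = [consensus]
    if L >= 40:  # halves pick up truncated copies (>=50% coverage)
        queries += [consensus[: L // 2], consensus[L - L // 2:]]
    out = []
    for scaffold, seq in genome.items():
        intervals: list[tuple[int, int]] = []
        for strand_seq in (seq, None):
            target = seq if strand_seq is not None else revcomp(seq)
            for q in queries:
                max_dist = int(len(q) * (1 - min_identity))
                for s, e, _ in _edlib_hits(q, target, max_dist):
                    if strand_seq is None:  # map back from reverse strand
                        s, e = len(seq) - e, len(seq) - s
                    intervals.append((s, e))
        merged = merge_intervals(intervals)
        out.extend((scaffold, s, e) for s, e in merged)
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


# ---------------------------------------------------------------------------
# library filtering

def _protein_screen_hit(
    consensus: str,
    protein_db: Mapping[str, str],
    e_cutoff: float,
) -> bool:
    """True when any six-frame translation fragment hits ``protein_db``.

    Frames are split at stop codons; fragments of >= 15 aa are compared by
    local alignment with Karlin-Altschul E-values at ``e_cutoff``.
    """
    if not protein_db:
        return False
    aligner = protein_aligner("local")
    fragments = [
        frag
        for frame in six_frame_translate(consensus).values()
        for frag in frame.split("*")
        if len(frag) >= 15 and "X" not in frag
    ]
    for frag in fragments:
        for prot in protein_db.values():
            score = float(aligner.score(frag, prot))
            if ka_evalue(score, len(frag), len(prot)) <= e_cutoff:
                return True
    return False


def filter_repeat_library(
    library: Iterable[RepeatConsensus],
    genome: Mapping[str, str],
    protein_db: Mapping[str, str] | None = None,
    te_protein_db: Mapping[str, str] | None = None,
    min_length: int = 100,
    min_copies: int = 10,
    protein_e: float = 1e-5,
    min_identity: float = 0.8,
) -> list[RepeatConsensus]:
    """Apply the three library filters in order; annotate removals in place.

    Returns the full record list: retained consensuses keep
    ``provenance='input'`` and gain a genome ``copy_count``; removed ones
    get ``provenance='filtered-out'`` and exactly one ``reason`` among
    ``length``, ``low-copy``, ``protein-hit``.  The UNIPROT-style screen
    significance cutoff is a package decision (default E <= 1e-5); TE
    proteins in ``te_protein_db`` are exempt.
    """
    records = list(library)
    for rec in records:
        if len(rec.sequence) < min_length:
            rec.provenance, rec.reason = "filtered-out", "length"
            continue
        matches = find_consensus_matches(genome, rec.sequence,
                                         min_identity=min_identity)
        rec.copy_count = len(matches)
        if rec.copy_count < min_copies:
            rec.provenance, rec.reason = "filtered-out", "low-copy"
            continue
        if protein_db and _protein_screen_hit(rec.sequence, protein_db, protein_e):
            if not (te_protein_db
                    and _protein_screen_hit(rec.sequence, te_protein_db, protein_e)):
                rec.provenance, rec.reason = "filtered-out", "protein-hit"
    return records


def kept(library: Iterable[RepeatConsensus]) -> list[RepeatConsensus]:
    return [r for r in library if r.provenance == "input"]


# ---------------------------------------------------------------------------
# masking

@dataclass
class MaskReport:
    genome_span: int
    masked_bp: int
    percent_masked: float
    per_class: dict = field(default_factory=dict)  # classification -> (bp, percent)
    copy_counts: dict = field(default_factory=dict)  # consensus id -> copies


def mask_genome(
    genome: Mapping[str, str],
    library: Iterable[RepeatConsensus],
    min_identity: float = 0.8,
):
    """Soft-mask all intervals matching any library consensus.

    Overlapping intervals are merged before any coverage arithmetic, so the
    total is never more than the sum of parts.  Returns
    ``(masked_genome, MaskReport)``; percentages are of total span.
    """
    span = sum(len(s) for s in genome.values())
    all_iv: dict[str, list] = {sc: [] for sc in genome}
    class_iv: dict[str, dict[str, list]] = {}
    report = MaskReport(genome_span=span, masked_bp=0, percent_masked=0.0)
    for rec in library:
        matches = find_consensus_matches(genome, rec.sequence,
                                         min_identity=min_identity)
        report.copy_counts[rec.id] = len(matches)
        for scaffold, s, e in matches:
            all_iv[scaffold].append((s, e))
            class_iv.setdefault(rec.classification, {}).setdefault(
                scaffold, []
            ).append((s, e))
    masked = {}
    masked_bp = 0
    for scaffold, seq in genome.items():
        merged = merge_intervals(all_iv[scaffold])
        chars = list(seq)
        for s, e in merged:
            masked_bp += e - s
            chars[s:e] = seq[s:e].lower()
        masked[scaffold] = "".join(chars)
    report.masked_bp = masked_bp
    report.percent_masked = 100.0 * masked_bp / span if span else 0.0
    for cls, by_scaffold in sorted(class_iv.items()):
        bp = sum(
            e - s
            for ivs in by_scaffold.values()
            for s, e in merge_intervals(ivs)
        )
        report.per_class[cls] = (bp, 100.0 * bp / span if span else 0.0)
    return masked, report


# ---------------------------------------------------------------------------
# SSR scan

def _is_primitive(motif: str) -> bool:
    """True unless the motif is a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[: d] * (n // d):
            return False
    return True


def find_ssrs(
    genome: Mapping[str, str],
    thresholds: Mapping[int, int] | None = None,
) -> list[SSRLocus]:
    """Maximal perfect SSR runs of 1-6 bp motifs above per-unit thresholds.

    Scans left to right; at each position the smallest qualifying unit
    length wins (so "ATATATAT..." is a dinucleotide run, never a 4-mer), the
    whole run is reported maximally and the scan resumes past it.  Runs
    never span an N; motifs are reported strand-as-found (reverse-complement
    classes are not collapsed).
    """
    thresholds = dict(MISA_DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    loci: list[SSRLocus] = []
    for scaffold in sorted(genome):
        seq = genome[scaffold].upper()
        L = len(seq)
        i = 0
        while i < L:
            if seq[i] == "N":
                i += 1
                continue
            hit = None
            for u in range(1, 7):
                if u not in thresholds:
                    continue
                motif = seq[i:i + u]
                if len(motif) < u or "N" in motif or not _is_primitive(motif):
                    continue
                k = 1
                while seq[i + k * u:i + (k + 1) * u] == motif:
                    k += 1
                if k >= thresholds[u]:
                    hit = (u, k, motif)
                    break
            if hit:
                u, k, motif = hit
                loci.append(SSRLocus(scaffold, i, i + u * k, motif, u, k))
                i += u * k
            else:
                i += 1
    return loci


def merge_compound_ssrs(
    loci: Iterable[SSRLocus], max_gap: int = 100
) -> list[CompoundSSR]:
    """Group SSRs interrupted by <= ``max_gap`` bp into compound records.

    Reported separately from the simple loci; only groups of two or more
    constituent SSRs are emitted.
    """
    by_scaffold: dict[str, list[SSRLocus]] = {}
    for locus in loci:
        by_scaffold.setdefault(locus.scaffold, []).append(locus)
    compounds = []
    for scaffold in sorted(by_scaffold):
        run: list[SSRLocus] = []
        for locus in sorted(by_scaffold[scaffold], key=lambda l: l.start):
            if run and locus.start - run[-1].end <= max_gap:
                run.append(locus)
            else:
                if len(run) > 1:
                    compounds.append(
                        CompoundSSR(scaffold, run[0].start, run[-1].end, run)
                    )
                run = [locus]
        if len(run) > 1:
            compounds.append(CompoundSSR(scaffold, run[0].start, run[-1].end, run))
    return compounds


# ---------------------------------------------------------------------------
# tandem repeats

def _candidate_segments(match: np.ndarray, period: int, params: TandemParams):
    """Chain True-runs of the recurrence mask into candidate segments.

    Runs are chained across short gaps (an isolated substitution in an array
    breaks the recurrence mask at two single positions) and across longer
    gaps when the next run's match gain exceeds the gap's mismatch cost.
    Candidates below half match density or with too little match score to
    ever reach min_score are dropped early.  Yields (start, end) in mask
    coordinates.
    """
    if not match.any():
        return
    idx = np.flatnonzero(match)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], breaks + 1))
    run_ends = np.concatenate((breaks, [len(idx) - 1]))
    runs = [(int(idx[s]), int(idx[e]) + 1) for s, e in zip(run_starts, run_ends)]

    def emit(s, e):
        seg = match[s:e]
        true_count = int(seg.sum())
        if (true_count >= max(1, (e - s)) * 0.5
                and params.match * (true_count + period) >= params.min_score):
            yield (s, e)

    cur_s, cur_e = runs[0]
    for s, e in runs[1:]:
        gap = s - cur_e
        if gap <= 3 or params.match * (e - s) > params.mismatch * gap:
            cur_e = e
        else:
            yield from emit(cur_s, cur_e)
            cur_s, cur_e = s, e
    yield from emit(cur_s, cur_e)


def _score_array(seq: str, period: int, params: TandemParams) -> tuple[int, str]:
    """Score an array against its per-column majority consensus."""
    cols: list[dict[str, int]] = [{} for _ in range(period)]
    for i, ch in enumerate(seq):
        col = cols[i % period]
        col[ch] = col.get(ch, 0) + 1
    consensus = "".join(
        min(col, key=lambda b: (-col[b], b)) if col else "N" for col in cols
    )
    score = 0
    for i, ch in enumerate(seq):
        score += params.match if ch == consensus[i % period] else -params.mismatch
    return score, consensus


def find_tandem_repeats(
    genome: Mapping[str, str],
    params: TandemParams | None = None,
) -> list[TandemRepeatLocus]:
    """Simplified tandem-repeat detection over periods 2..max_period.

    For each trial period the self-recurrence mask ``s[i] == s[i+p]`` seeds
    candidate arrays; candidates are scored against their consensus with
    the +match/-mismatch weights and kept at score >= min_score with at
    least two copies.  Smaller periods are scanned first and larger-period
    candidates overlapping an accepted locus are dropped, so an array is
    reported at its fundamental period.  Arrays with period < 7 are
    detected but belong to neither satellite class (SSR territory).
    """
    if params is None:
        params = TandemParams()
    loci: list[TandemRepeatLocus] = []
    for scaffold in sorted(genome):
        seq = genome[scaffold].upper()
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        accepted: list[tuple[int, int]] = []
        max_p = min(params.max_period, max(len(seq) - 1, 1))
        for p in range(2, max_p + 1):
            if len(arr) <= p:
                break
            match = arr[p:] == arr[:-p]
            candidates = [
                (s, e + p)
                for s, e in _candidate_segments(match, p, params)
                if e - s >= p  # at least two full copies
            ]
            # a divergent array can still split; rejoin near-adjacent pieces
            rejoined: list[list[int]] = []
            for s, e in candidates:
                if rejoined and s - rejoined[-1][1] <= p:
                    rejoined[-1][1] = max(rejoined[-1][1], e)
                else:
                    rejoined.append([s, e])
            for start, end in rejoined:
                if any(
                    min(end, e) - max(start, s) > (end - start) // 2
                    for s, e in accepted
                ):
                    continue
                score, consensus = _score_array(seq[start:end], p, params)
                if score < params.min_score:
                    continue
                accepted.append((start, end))
                loci.append(
                    TandemRepeatLocus(
                        scaffold=scaffold, start=start, end=end, period=p,
                        copy_number=round((end - start) / p, 2),
                        score=score, consensus=consensus,
                    )
                )
    loci.sort(key=lambda l: (l.scaffold, l.start))
    return loci


# ---------------------------------------------------------------------------
# summary tables

def repeat_summary_table(library: Iterable[RepeatConsensus], report: MaskReport):
    """Families / copies / percent-coverage rows per classification."""
    rows = []
    by_class: dict[str, list[RepeatConsensus]] = {}
    for rec in library:
        if rec.provenance == "input":
            by_class.setdefault(rec.classification, []).append(rec)
    for cls in sorted(by_class):
        recs = by_class[cls]
        bp, pct = report.per_class.get(cls, (0, 0.0))
        rows.append({
            "classification": cls,
            "families": len(recs),
            "copies": sum(report.copy_counts.get(r.id, 0) for r in recs),
            "coverage_percent": round(pct, 2),
        })
    rows.append({
        "classification": "All",
        "families": sum(r["families"] for r in rows),
        "copies": sum(r["copies"] for r in rows),
        "coverage_percent": round(report.percent_masked, 2),
    })
    return rows
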