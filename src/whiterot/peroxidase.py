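"""Rule-based classification of class II (AA2) peroxidase subtypes.

Secreted fungal heme peroxidases of class II share a conserved scaffold:
two axial histidines (the proximal His ligating the heme iron, the distal
His activating the enzyme with peroxide), a distal arginine, four disulfide
bridges (eight cysteines) and two structural calcium sites.  Subtypes differ
in two catalytic features:

* a **Mn(II) oxidation site** formed by two glutamates and one aspartate at
  the internal heme propionate region (manganese peroxidases, MnP);
* a **solvent-exposed catalytic tryptophan** responsible for oxidation of
  high-redox-potential aromatics (lignin peroxidases, LiP).

Versatile peroxidases (VP) carry both; an "atypical VP" differs from VP in a
single conservative Asp/Glu swap at one of the three Mn-site acidics; long
and extralong MnPs carry 10-30 extra residues at the C-terminal end (and an
extra disulfide) relative to short MnPs; sequences with neither feature on a
valid scaffold are generic peroxidases (GP).

Solvent exposure cannot be computed from sequence alone, so the tryptophan
criterion here is positional: the query is globally aligned to an annotated
reference template and each feature position is projected through the
alignment.  The bundled default template is synthetic — a constructed
stand-in carrying the canonical features at mature-protein-numbering
positions — and a custom curated profile can be supplied as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .align import alignment_identity, global_alignment

SUBTYPES = ("LiP", "shortMnP", "longMnP", "VP", "atypicalVP", "GP")

#: below this global-alignment identity the query is not a class II
#: peroxidase matching the profile (possibly a heme-thiolate peroxidase).
MIN_PROFILE_IDENTITY = 0.25

#: C-terminal extension band (aa) characteristic of long/extralong MnPs.
LONG_TAIL_RANGE = (10, 30)
#: long MnPs carry one more disulfide bridge, hence ten cysteines.
LONG_CYS_COUNT = 10

ACIDIC = frozenset("DE")


@dataclass
class ReferenceProfile:
    """Annotated reference template; feature positions are 1-based."""

    name: str
    sequence: str
    features: dict  # group -> {position(str): expected residue}
    tail_boundary: int

    def __post_init__(self):
        length = len(self.sequence)
        for group, positions in self.features.items():
            for pos in positions:
                if not 1 <= int(pos) <= length:
                    raise ValueError(f"{group} position {pos} outside reference")
        if len(self.features.get("mn_site", {})) != 3:
            raise ValueError("Mn site must have exactly 3 positions")
        if len(self.features.get("cysteines", {})) != 8:
            raise ValueError("reference cysteine set must have exactly 8 positions")

    def all_positions(self) -> list[int]:
        return sorted(
            int(p) for group in self.features.values() for p in group
        )


@dataclass
class FeatureState:
    """State of one annotated feature position after projection."""

    position: int  # reference position, 1-based
    expected: str
    observed: str | None  # None when the query has a gap there

    @property
    def present(self) -> bool:
        return self.observed == self.expected

    @property
    def unalignable(self) -> bool:
        return self.observed is None

    def label(self) -> str:
        if self.unalignable:
            return "unalignable"
        if self.present:
            return "present"
        return f"substituted({self.observed})"


@dataclass
class ResidueMap:
    """Per-feature presence/absence at reference-anchored positions."""

    states: dict = field(default_factory=dict)  # group -> [FeatureState, ...]
    c_terminal_extension: int = 0
    cysteine_count: int = 0
    identity: float = 0.0
    profile_mismatch: bool = False

    def group_present(self, group: str) -> bool:
        return all(s.present for s in self.states.get(group, []))

    def scaffold_valid(self) -> bool:
        return (
            self.group_present("proximal_his")
            and self.group_present("distal_his")
            and self.group_present("distal_arg")
        )


@dataclass
class ClassIICall:
    subtype: str
    evidence: list = field(default_factory=list)
    scaffold_valid: bool = True


def load_reference_profile(path=None) -> ReferenceProfile:
    """Load the bundled synthetic template, or a custom JSON profile."""
    if path is None:
        text = (
            resources.files("whiterot.data")
            .joinpath("class2_reference_synthetic.json")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    data = json.loads(text)
    return ReferenceProfile(
        name=data["name"],
        sequence=data["sequence"],
        features=data["features"],
        tail_boundary=data["tail_boundary"],
    )


def map_residues(query: str, profile: ReferenceProfile) -> ResidueMap:
    """Project the profile's annotated positions onto ``query`` via global alignment.

    A gap in the query at a feature position is reported as unalignable.  The
    C-terminal extension is the number of query residues past the query
    column aligned to the reference tail boundary (negative for truncations).
    """
    ref = profile.sequence
    if not 0.5 * len(ref) <= len(query) <= 2 * len(ref):
        raise ValueError(
            f"query length {len(query)} outside 0.5-2x of reference ({len(ref)})"
        )
    aln = global_alignment(ref, query)
    identity = alignment_identity(aln)
    rmap = ResidueMap(identity=identity, cysteine_count=query.count("C"))
    if identity < MIN_PROFILE_IDENTITY:
        rmap.profile_mismatch = True
        return rmap

    # reference position (0-based) -> query position or None
    ref_to_query: dict[int, int | None] = {}
    ref_aln, query_aln = aln[0], aln[1]
    ri = qi = 0
    last_query_for_ref = {}
    for rc, qc in zip(ref_aln, query_aln):
        if rc != "-" and qc != "-":
            ref_to_query[ri] = qi
        elif rc != "-":
            ref_to_query[ri] = None
        if rc != "-":
            ri += 1
        if qc != "-":
            qi += 1

    for group, positions in profile.features.items():
        states = []
        for pos_str, expected in sorted(positions.items(), key=lambda kv: int(kv[0])):
            pos = int(pos_str)
            qpos = ref_to_query.get(pos - 1)
            observed = query[qpos] if qpos is not None else None
            states.append(FeatureState(pos, expected, observed))
        rmap.states[group] = states

    boundary_q = ref_to_query.get(profile.tail_boundary - 1)
    if boundary_q is None:
        # boundary deleted in query: fall back to the last aligned reference
        # column and adjust by the remaining reference tail length
        aligned = [r for r in range(profile.tail_boundary - 1, -1, -1)
                   if ref_to_query.get(r) is not None]
        if aligned:
            r_last = aligned[0]
            boundary_q = ref_to_query[r_last] + (profile.tail_boundary - 1 - r_last)
        else:
            boundary_q = len(query) - 1
    rmap.c_terminal_extension = len(query) - 1 - boundary_q
    return rmap


def classify_class2(rmap: ResidueMap) -> ClassIICall:
    """Apply the catalytic-residue rule table to one residue map.

    Rules, in order: an invalid scaffold (any axial His or the distal Arg
    absent/unalignable) is unclassifiable; Trp + canonical Mn site = VP;
    Trp + Mn site with exactly one conservative D/E swap = atypical VP;
    Trp + incomplete Mn site = LiP; Mn site without Trp = MnP, split
    long/short on C-terminal extension (10-30 aa) and/or ten cysteines;
    anything else on a valid scaffold = GP.  Total and deterministic.
    """
    if rmap.profile_mismatch:
        return ClassIICall(
            "unclassifiable",
            evidence=[f"profile mismatch: identity {rmap.identity:.2f} < "
                      f"{MIN_PROFILE_IDENTITY:.2f} (possible non-class-II, e.g. HTP)"],
            scaffold_valid=False,
        )
    if not rmap.scaffold_valid():
        missing = [
            f"{g}:{s.label()}"
            for g in ("proximal_his", "distal_his", "distal_arg")
            for s in rmap.states.get(g, [])
            if not s.present
        ]
        return ClassIICall(
            "unclassifiable",
            evidence=["scaffold invalid: " + ", ".join(missing)],
            scaffold_valid=False,
        )

    mn = rmap.states["mn_site"]
    trp = rmap.states["catalytic_trp"][0]
    mn_acidic = [s for s in mn if s.observed in ACIDIC]
    mn_canonical = [s for s in mn if s.present]
    triad_all_acidic = len(mn_acidic) == 3
    triad_canonical = len(mn_canonical) == 3
    swaps = len(mn_acidic) - len(mn_canonical)

    if trp.present and triad_canonical:
        return ClassIICall("VP", ["catalytic Trp present", "Mn site complete (E,E,D)"])
    if trp.present and triad_all_acidic and swaps == 1:
        swapped = next(s for s in mn if s.observed in ACIDIC and not s.present)
        return ClassIICall(
            "atypicalVP",
            ["catalytic Trp present",
             f"Mn site acidic with one D/E swap at {swapped.position} "
             f"({swapped.expected}->{swapped.observed})"],
        )
    if trp.present:
        # non-conservative change(s) at the Mn site count as an incomplete
        # site, so Trp-bearing sequences with e.g. E->A land here as LiP
        absent = [f"{s.position}:{s.label()}" for s in mn if s.observed not in ACIDIC]
        return ClassIICall(
            "LiP",
            ["catalytic Trp present", "Mn site absent/incomplete: " + ", ".join(absent)],
        )
    if triad_all_acidic:
        ext = rmap.c_terminal_extension
        long_tail = LONG_TAIL_RANGE[0] <= ext <= LONG_TAIL_RANGE[1]
        extra_cys = rmap.cysteine_count >= LONG_CYS_COUNT
        base = ["Mn site complete", f"catalytic Trp absent ({trp.label()})"]
        if long_tail or extra_cys:
            detail = []
            if long_tail:
                detail.append(f"C-terminal extension {ext} aa")
            if extra_cys:
                detail.append(f"{rmap.cysteine_count} cysteines")
            return ClassIICall("longMnP", base + detail)
        return ClassIICall(
            "shortMnP", base + [f"short C-terminal tail (extension {ext} aa)"]
        )
    return ClassIICall(
        "GP",
        [f"catalytic Trp absent ({trp.label()})",
         "Mn site absent/incomplete",
         "valid class II scaffold"],
    )


def batch_classify(sequences: dict[str, str], profile: ReferenceProfile | None = None):
    """Classify every sequence; returns (calls dict, subtype summary counts)."""
    if profile is None:
        profile = load_reference_profile()
    calls: dict[str, ClassIICall] = {}
    for sid, seq in sequences.items():
        try:
            calls[sid] = classify_class2(map_residues(seq, profile))
        except ValueError as exc:
            calls[sid] = ClassIICall("unclassifiable", [str(exc)], scaffold_valid=False)
    summary: dict[str, int] = {}
    for call in calls.values():
        summary[call.subtype] = summary.get(call.subtype, 0) + 1
    return calls, summary


def write_call_table(calls: dict[str, ClassIICall], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tsubtype\tscaffold_valid\tevidence\n")
        for sid, call in calls.items():
            fh.write(
                f"{sid}\t{call.subtype}\t{call.scaffold_valid}\t"
                f"{'; '.join(call.evidence)}\n"
            )
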