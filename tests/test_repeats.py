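"""Repeat annotation: library filters, masking arithmetic, SSR and tandem scans."""

import re

import numpy as np
import pytest

from whiterot.repeats import (
    MISA_DEFAULT_THRESHOLDS,
    RepeatConsensus,
    TandemParams,
    filter_repeat_library,
    find_consensus_matches,
    find_ssrs,
    find_tandem_repeats,
    kept,
    mask_genome,
    merge_compound_ssrs,
    merge_intervals,
)
from whiterot.simulate import SimulationConfig, generate_genome

# ---------------------------------------------------------------------------
# independent SSR oracle (regex-driven maximal-run enumeration)


def ssr_oracle(seq, thresholds=MISA_DEFAULT_THRESHOLDS):
    """Enumerate maximal perfect runs with regex backreferences.

    Independent of the scanner: for every unit length a greedy backreference
    pattern finds maximal runs; non-primitive motifs are dropped; candidates
    are accepted left to right at the smallest unit, and the search resumes
    on the remaining suffix so runs truncated by an accepted locus are
    re-tested against the thresholds.
    """
    def primitive(m):
        return all(
            m != m[:d] * (len(m) // d)
            for d in range(1, len(m)) if len(m) % d == 0
        )

    out = []
    pos = 0
    while pos < len(seq):
        candidates = []
        sub = seq[pos:]
        for u, thr in thresholds.items():
            pattern = re.compile(rf"([ACGT]{{{u}}})\1{{{thr - 1},}}")
            for m in pattern.finditer(sub):
                motif = m.group(1)
                if not primitive(motif):
                    continue
                run_len = (m.end() - m.start()) // u * u
                candidates.append((pos + m.start(), u, motif, run_len // u))
        if not candidates:
            break
        start, u, motif, k = min(candidates)
        out.append((start, start + u * k, motif, u, k))
        pos = start + u * k
    return out


def random_dna(length, seed, gc=0.5):
    rng = np.random.default_rng(seed)
    return "".join(
        "ACGT"[i]
        for i in rng.choice(4, size=length, p=[(1 - gc) / 2, gc / 2, gc / 2,
                                               (1 - gc) / 2])
    )


class TestSSR:
    def test_mono_run_embedded_in_random_sequence(self):
        seq = random_dna(500, 1).replace("A" * 10, "GC" + "T" * 8)
        seq = seq[:200] + "A" * 12 + seq[200:]
        loci = [l for l in find_ssrs({"s": seq}) if l.motif == "A"]
        assert any(l.unit_count >= 12 and l.start <= 200 <= l.end for l in loci)

    def test_dinucleotide_below_threshold_not_reported(self):
        seq = "GGC" + "AT" * 5 + "CGG"  # 5 units < threshold 6
        assert find_ssrs({"s": seq}) == []

    def test_trinucleotide_at_threshold_reported_maximally(self):
        seq = "TT" + "ACG" * 5 + "TT"
        (locus,) = find_ssrs({"s": seq})
        assert (locus.motif, locus.unit_count) == ("ACG", 5)
        assert (locus.start, locus.end) == (2, 17)

    def test_smallest_period_wins(self):
        seq = "G" + "AT" * 8 + "C"
        (locus,) = find_ssrs({"s": seq})
        assert locus.unit_length == 2  # never reported as a 4-mer

    def test_runs_never_span_an_n(self):
        seq = "A" * 7 + "N" + "A" * 7
        assert find_ssrs({"s": seq}) == []

    def test_scanner_matches_regex_oracle_on_planted_sequences(self):
        for seed in range(30):
            seq = random_dna(2000, seed)
            insert = ["A" * 12, "AG" * 7, "ACG" * 6, "ACGT" * 5, "AT" * 4][seed % 5]
            mid = 400 + (seed * 37) % 1000
            seq = seq[:mid] + insert + seq[mid:]
            got = [
                (l.start, l.end, l.motif, l.unit_length, l.unit_count)
                for l in find_ssrs({"s": seq})
            ]
            assert got == ssr_oracle(seq), f"seed {seed}"

    def test_compound_merging_reported_separately(self):
        seq = "A" * 12 + "GCGTA" + "AG" * 7
        simple = find_ssrs({"s": seq})
        assert len(simple) == 2
        (compound,) = merge_compound_ssrs(simple, max_gap=100)
        assert compound.start == 0 and compound.end == len(seq)
        assert len(compound.members) == 2
        assert merge_compound_ssrs(simple, max_gap=2) == []


class TestLibraryFilter:
    def test_short_consensus_removed_with_length_reason(self):
        genome = {"s": random_dna(2000, 2)}
        (rec,) = filter_repeat_library(
            [RepeatConsensus("c", random_dna(90, 3))], genome
        )
        assert (rec.provenance, rec.reason) == ("filtered-out", "length")

    def test_low_copy_consensus_removed(self):
        consensus = random_dna(150, 4)
        genome = {"s": random_dna(3000, 5) + consensus + random_dna(500, 6)}
        (rec,) = filter_repeat_library([RepeatConsensus("c", consensus)], genome)
        assert (rec.provenance, rec.reason) == ("filtered-out", "low-copy")
        assert rec.copy_count == 1

    def test_planted_copies_counted_and_retained(self):
        cfg = SimulationConfig(seed=77, genome_length=40_000,
                               planted_te_specs=[(400, 12, 0.03)])
        genome, truth = generate_genome(cfg)
        (rec,) = filter_repeat_library(
            [RepeatConsensus("te1", truth.te_library["te1"])], genome
        )
        assert rec.provenance == "input"
        assert rec.copy_count == 12

    def test_protein_hit_removes_unless_te_exempt(self):
        # deterministic reverse translation of a 60-aa peptide
        codon = {
            "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
            "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
            "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
            "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
        }
        rng = np.random.default_rng(8)
        protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i]
                          for i in rng.integers(0, 20, 60))
        orf = "".join(codon[aa] for aa in protein)
        consensus = random_dna(60, 9) + orf + random_dna(60, 10)
        genome_parts = [random_dna(300, 20 + i) + consensus for i in range(12)]
        genome = {"s": "".join(genome_parts) + random_dna(300, 99)}

        without_exemption = filter_repeat_library(
            [RepeatConsensus("c", consensus)], genome,
            protein_db={"prot": protein},
        )
        assert without_exemption[0].reason == "protein-hit"

        with_exemption = filter_repeat_library(
            [RepeatConsensus("c", consensus)], genome,
            protein_db={"prot": protein}, te_protein_db={"te_prot": protein},
        )
        assert with_exemption[0].provenance == "input"

    def test_empty_library_is_not_an_error(self):
        assert filter_repeat_library([], {"s": "ACGT"}) == []

    def test_filters_applied_in_order_one_reason_each(self):
        genome = {"s": random_dna(2000, 11)}
        short_and_rare = RepeatConsensus("c", random_dna(50, 12))
        (rec,) = filter_repeat_library([short_and_rare], genome)
        assert rec.reason == "length"  # filter i fires before ii


class TestMasking:
    def test_empty_library_masks_nothing(self):
        genome = {"s": random_dna(1000, 13)}
        masked, report = mask_genome(genome, [])
        assert masked == genome
        assert report.percent_masked == 0.0

    def test_planted_element_coverage_arithmetic(self):
        cfg = SimulationConfig(seed=88, genome_length=100_000,
                               planted_te_specs=[(1000, 10, 0.0)])
        genome, truth = generate_genome(cfg)
        masked, report = mask_genome(
            genome, [RepeatConsensus("te1", truth.te_library["te1"])]
        )
        assert report.percent_masked == pytest.approx(10.0, abs=0.3)
        assert report.copy_counts["te1"] == 10
        # soft masking preserves the sequence itself
        assert masked["scf1"].upper() == genome["scf1"]

    def test_overlapping_hits_merge_before_coverage(self):
        consensus = random_dna(200, 14)
        genome = {"s": random_dna(400, 15) + consensus + random_dna(400, 16)}
        library = [
            RepeatConsensus("full", consensus, classification="gypsy"),
            RepeatConsensus("half", consensus[:120], classification="copia"),
        ]
        _, report = mask_genome(genome, library)
        total_parts = sum(bp for bp, _ in report.per_class.values())
        assert report.masked_bp <= total_parts
        assert report.masked_bp == pytest.approx(200, abs=20)

    def test_coverage_monotone_in_library_size(self):
        cfg = SimulationConfig(seed=89, genome_length=30_000,
                               planted_te_specs=[(300, 10, 0.02), (250, 10, 0.02)])
        genome, truth = generate_genome(cfg)
        lib = [RepeatConsensus(n, s) for n, s in truth.te_library.items()]
        coverages = []
        for k in range(len(lib) + 1):
            _, report = mask_genome(genome, lib[:k])
            coverages.append(report.percent_masked)
        assert all(0 <= c <= 100 for c in coverages)
        assert coverages == sorted(coverages)

    def test_interval_merge_helper(self):
        assert merge_intervals([(0, 10), (5, 15), (20, 30)]) == [(0, 15), (20, 30)]


class TestTandem:
    def test_perfect_seven_bp_array_scored_two_per_base(self):
        (locus,) = find_tandem_repeats({"s": "ACGTAAC" * 10})
        assert locus.period == 7
        assert locus.score == 140  # 70 positions x match weight 2
        assert locus.repeat_class == "minisatellite"

    def test_long_period_array_is_satellite(self):
        motif = random_dna(120, 17)
        loci = find_tandem_repeats({"s": motif * 3})
        assert [l.repeat_class for l in loci] == ["satellite"]
        assert loci[0].period == 120

    def test_short_period_detected_but_unclassified(self):
        (locus,) = find_tandem_repeats({"s": "ACGTA" * 20})
        assert locus.period == 5
        assert locus.repeat_class is None

    def test_min_score_threshold_respected(self):
        # 7 x 3 = 21 bp, score 42 < 50
        assert find_tandem_repeats({"s": "ACGTAAC" * 3}) == []

    def test_params_validated(self):
        with pytest.raises(ValueError):
            TandemParams(min_score=0)

    def test_planted_divergent_arrays_recovered(self):
        """>=95% of arrays at <=10% per-copy divergence recovered (10 seeds)."""
        recovered = total = 0
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, genome_length=20_000,
                planted_tandem_specs=[(15, 12, 0.1), (40, 6, 0.1), (120, 3, 0.08)],
            )
            genome, truth = generate_genome(cfg)
            loci = find_tandem_repeats(genome)
            for _, start, end, fclass, _ in truth.repeat_intervals:
                if fclass != "tandem":
                    continue
                total += 1
                covered = sum(
                    max(0, min(end, l.end) - max(start, l.start)) for l in loci
                )
                if covered >= 0.5 * (end - start):
                    recovered += 1
        assert total == 30
        assert recovered / total >= 0.95


def test_consensus_matches_found_on_both_strands():
    from whiterot.seqio import revcomp

    consensus = random_dna(200, 18)
    genome = {"s": random_dna(300, 19) + revcomp(consensus) + random_dna(300, 21)}
    matches = find_consensus_matches(genome, consensus)
    assert len(matches) == 1
    (scaffold, start, end) = matches[0]
    assert (start, end) == (300, 500)
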