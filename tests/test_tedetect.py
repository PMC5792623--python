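"""Insertion calling and TSD detection against planted truth and string oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiline import synthgen as sg
from epiline import tedetect as td
from epiline._util import reverse_complement


class TestNaiveMap:
    def test_exact_read_single_placement(self, small_genome):
        seq = small_genome.sequences["chr1"]
        read = seq[500:650]
        pairs = [sg.ReadPair("r1", read, reverse_complement(seq[800:950]), "chr1", 500, 950)]
        aln = td.naive_map(pairs, small_genome, {})
        r1 = aln[(aln["read_id"] == "r1") & (aln["mate"] == 1)].iloc[0]
        assert (r1["contig"], r1["start"], r1["strand"]) == ("chr1", 500, "+")
        assert r1["unique"]

    def test_read_from_repeat_flagged_non_unique(self):
        core = sg.make_reference(5, {"x": 2_000}).sequences["x"]
        genome = sg.GenomeModel({"c": core + core})  # perfect duplication
        read = core[100:250]
        pairs = [sg.ReadPair("r", read, reverse_complement(core[400:550]), "c", 0, 0)]
        aln = td.naive_map(pairs, genome, {})
        assert not aln[aln["mate"] == 1]["unique"].iloc[0]

    def test_reverse_complement_read_minus_strand(self, small_genome):
        seq = small_genome.sequences["chr1"]
        read = reverse_complement(seq[700:850])
        pairs = [sg.ReadPair("r", read, seq[100:250], "chr1", 0, 0)]
        aln = td.naive_map(pairs, small_genome, {})
        r = aln[aln["mate"] == 1].iloc[0]
        assert (r["start"], r["strand"]) == (700, "-")

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            td.naive_map([], sg.GenomeModel({"c": "ACGT" * 300}), {"te": ""})


@pytest.fixture(scope="module")
def detection(small_genome, te_sequence):
    ins = sg.PlantedInsertion("chr1", 9_000, te_sequence, tsd_length=7)
    carrier = sg.plant_insertion(small_genome, ins)
    pairs = sg.simulate_read_pairs(carrier, coverage=30, seed=42)
    aln = td.naive_map(pairs, small_genome, {"te": te_sequence})
    return small_genome, carrier, ins, aln


class TestDiscordantCalling:
    def test_no_te_mates_no_clusters(self, small_genome):
        pairs = sg.simulate_read_pairs(small_genome, coverage=2, seed=1)
        aln = td.naive_map(pairs, small_genome, {"te": "A" * 2000})
        assert td.find_discordant_pairs(aln, {"te"}) == []

    def test_single_planted_insertion_one_cluster_both_sides(self, detection):
        *_, aln = detection
        clusters = td.find_discordant_pairs(aln, {"te"})
        assert len(clusters) == 1
        assert len(clusters[0].left) >= 3 and len(clusters[0].right) >= 3

    def test_call_interval_overlaps_target_site(self, detection):
        genome, carrier, ins, aln = detection
        calls, candidates = td.call_insertions(aln, {"te"})
        assert len(calls) == 1 and not candidates
        call = calls[0]
        # with a TSD the junction is ambiguous within the duplicated target
        # site [point - tsd, point]; the interval must overlap it
        assert call.lo <= ins.point and call.hi >= ins.point - ins.tsd_length
        assert call.hi - call.lo <= 500

    def test_two_insertions_two_clusters(self, te_sequence):
        genome = sg.make_reference(33, {"chr1": 60_000})
        c1 = sg.plant_insertion(genome, sg.PlantedInsertion("chr1", 15_000, te_sequence))
        carrier = sg.plant_insertion(
            c1, sg.PlantedInsertion("chr1", 45_000 + len(te_sequence), te_sequence)
        )
        pairs = sg.simulate_read_pairs(carrier, coverage=30, seed=2)
        aln = td.naive_map(pairs, genome, {"te": te_sequence})
        calls, _ = td.call_insertions(aln, {"te"})
        assert len(calls) == 2

    def test_support_below_threshold_yields_candidate(self, detection):
        *_, aln = detection
        clusters = td.find_discordant_pairs(aln, {"te"})
        result = td.call_insertion(clusters[0], min_support=10_000)
        assert isinstance(result, td.InsertionCandidate)
        assert "support below threshold" in result.reason

    def test_inverted_insertion_orientation(self, small_genome, te_sequence):
        ins = sg.PlantedInsertion("chr1", 9_000, te_sequence, inverted=True, tsd_length=5)
        carrier = sg.plant_insertion(small_genome, ins)
        pairs = sg.simulate_read_pairs(carrier, coverage=30, seed=3)
        aln = td.naive_map(pairs, small_genome, {"te": te_sequence})
        calls, _ = td.call_insertions(aln, {"te"})
        assert calls[0].orientation == "inverted"


def _brute_force_tsd(ref_left: str, ref_right: str, allele: str, te: str, max_tsd: int) -> int:
    """All-substrings oracle: try every candidate length and rebuild the
    insertion allele from reference flanks + element + duplicated suffix;
    the true TSD length is the one whose reconstruction equals the allele."""
    for te_try in (te, reverse_complement(te)):
        if te_try in allele:
            te = te_try
            break
    best = 0
    for length in range(max_tsd + 1):
        tsd = ref_left[-length:] if length else ""
        if ref_left + te + tsd + ref_right == allele:
            best = length
    return best


class TestDetectTsd:
    def test_planted_length_recovered(self, small_genome, te_sequence):
        p = 9_000
        ins = sg.PlantedInsertion("chr1", p, te_sequence, tsd_length=8)
        carrier = sg.plant_insertion(small_genome, ins)
        src = small_genome.sequences["chr1"]
        flanks = (src[p - 60: p], src[p: p + 60])
        allele = carrier.sequences["chr1"][p - 60: p + len(te_sequence) + 68]
        length, seq = td.detect_tsd(flanks, allele, te_sequence)
        assert (length, seq) == (8, src[p - 8: p])

    def test_blunt_junction_zero(self, small_genome, te_sequence):
        p = 9_000
        ins = sg.PlantedInsertion("chr1", p, te_sequence, tsd_length=0)
        carrier = sg.plant_insertion(small_genome, ins)
        src = small_genome.sequences["chr1"]
        flanks = (src[p - 60: p], src[p: p + 60])
        allele = carrier.sequences["chr1"][p - 60: p + len(te_sequence) + 60]
        assert td.detect_tsd(flanks, allele, te_sequence) == (0, "")

    def test_te_absent_raises(self):
        with pytest.raises(ValueError, match="not found"):
            td.detect_tsd(("A" * 40, "C" * 40), "A" * 40 + "C" * 40, "GTGTGTGT")

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(tsd=st.integers(0, 30), seed=st.integers(0, 500), inverted=st.booleans())
    def test_recovery_exact_for_all_tsd_lengths(self, tsd, seed, inverted):
        genome = sg.make_reference(seed, {"c": 2_000})
        te = sg.make_reference(seed + 1_000, {"te": 1_000}).sequences["te"]
        p = 1_000
        ins = sg.PlantedInsertion("c", p, te, tsd_length=tsd, inverted=inverted)
        carrier = sg.plant_insertion(genome, ins)
        src = genome.sequences["c"]
        flanks = (src[p - 60: p], src[p: p + 60])
        allele = carrier.sequences["c"][p - 60: p + len(te) + tsd + 60]
        length, seq = td.detect_tsd(flanks, allele, ins.inserted_sequence)
        assert length == tsd
        assert seq == src[p - tsd: p] if tsd else seq == ""

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(tsd=st.integers(0, 12), seed=st.integers(0, 200))
    def test_matches_brute_force_oracle(self, tsd, seed):
        genome = sg.make_reference(seed, {"c": 2_000})
        te = sg.make_reference(seed + 5_000, {"te": 1_000}).sequences["te"]
        p = 1_000
        ins = sg.PlantedInsertion("c", p, te, tsd_length=tsd)
        carrier = sg.plant_insertion(genome, ins)
        src = genome.sequences["c"]
        left, right = src[p - 40: p], src[p: p + 40]
        allele = carrier.sequences["c"][p - 40: p + len(te) + tsd + 40]
        length, _ = td.detect_tsd((left, right), allele, te, max_tsd=12)
        assert length == _brute_force_tsd(left, right, allele, te, 12)


class TestEndToEndTsd:
    def test_tsd_from_genomes_matches_truth(self, small_genome, te_sequence):
        ins = sg.PlantedInsertion(
            "chr1", 9_000, te_sequence, tsd_length=7, inverted=True, truncation=150
        )
        carrier = sg.plant_insertion(small_genome, ins)
        pairs = sg.simulate_read_pairs(carrier, coverage=30, seed=9)
        aln = td.naive_map(pairs, small_genome, {"te": te_sequence})
        calls, _ = td.call_insertions(aln, {"te"})
        length, seq = td.tsd_from_genomes(
            small_genome, carrier, calls[0], ins.inserted_sequence
        )
        src = small_genome.sequences["chr1"]
        assert (length, seq) == (7, src[9_000 - 7: 9_000])
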