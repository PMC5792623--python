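"""Generators: reproducibility, planted ground truth, model expectations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epiline import synthgen as sg
from epiline._util import reverse_complement
from epiline.tedate import raw_distance


class TestMakeReference:
    def test_gc_content_converges(self):
        g = sg.make_reference(1, {"c": 200_000}, gc_fraction=0.36)
        seq = g.sequences["c"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.34 <= gc <= 0.38

    def test_deterministic(self):
        a = sg.make_reference(7, {"c": 5_000})
        b = sg.make_reference(7, {"c": 5_000})
        assert a.sequences == b.sequences

    def test_pure_gc_boundary(self):
        g = sg.make_reference(1, {"c": 2_000}, gc_fraction=1.0)
        assert set(g.sequences["c"]) <= {"G", "C"}

    def test_rejects_short_chromosome(self):
        with pytest.raises(ValueError):
            sg.make_reference(1, {"c": 10})


class TestPlantInsertion:
    def test_zero_tsd_simple_insertion(self, small_genome, te_sequence):
        ins = sg.PlantedInsertion("chr1", 5_000, te_sequence, tsd_length=0)
        derived = sg.plant_insertion(small_genome, ins)
        assert len(derived.sequences["chr1"]) == 20_000 + len(te_sequence)

    def test_tsd_duplicated_around_te(self, small_genome, te_sequence):
        p = 5_000
        ins = sg.PlantedInsertion("chr1", p, te_sequence, tsd_length=8)
        derived = sg.plant_insertion(small_genome, ins).sequences["chr1"]
        src = small_genome.sequences["chr1"]
        tsd = src[p - 8: p]
        te_len = len(te_sequence)
        assert derived[p - 8: p] == tsd  # left copy (pre-existing target site)
        assert derived[p + te_len: p + te_len + 8] == tsd  # duplicated copy
        assert derived[p: p + te_len] == te_sequence

    def test_inverted_is_reverse_complement(self, small_genome, te_sequence):
        ins = sg.PlantedInsertion("chr1", 5_000, te_sequence, inverted=True, truncation=100)
        derived = sg.plant_insertion(small_genome, ins).sequences["chr1"]
        expected = reverse_complement(te_sequence[100:])
        assert derived[5_000: 5_000 + len(expected)] == expected

    def test_tsd_larger_than_left_flank_rejected(self, small_genome, te_sequence):
        ins = sg.PlantedInsertion("chr1", 3, te_sequence, tsd_length=8)
        with pytest.raises(ValueError, match="left flank"):
            sg.plant_insertion(small_genome, ins)


class TestReadPairs:
    def test_pair_count_matches_coverage(self):
        g = sg.make_reference(3, {"c": 200_000})
        pairs = sg.simulate_read_pairs(g, read_len=150, coverage=30, seed=1)
        assert len(pairs) == pytest.approx(30 * 200_000 / 300, rel=0.01)

    def test_error_free_reads_are_substrings(self, small_genome):
        pairs = sg.simulate_read_pairs(small_genome, coverage=2, error_rate=0.0, seed=2)
        seq = small_genome.sequences["chr1"]
        for pair in pairs[:50]:
            assert pair.seq1 in seq
            assert reverse_complement(pair.seq2) in seq

    def test_truth_tags_locate_fragment(self, small_genome):
        pairs = sg.simulate_read_pairs(small_genome, coverage=1, seed=3)
        seq = small_genome.sequences["chr1"]
        for pair in pairs[:20]:
            frag = seq[pair.frag_start: pair.frag_end]
            assert frag.startswith(pair.seq1)
            assert frag.endswith(reverse_complement(pair.seq2))

    def test_invalid_parameters(self, small_genome):
        with pytest.raises(ValueError):
            sg.simulate_read_pairs(small_genome, coverage=0)
        with pytest.raises(ValueError):
            sg.simulate_read_pairs(small_genome, read_len=150, insert_mean=200)


class TestBisulfite:
    def test_contexts_match_hand_oracle(self):
        #      0123456789012 3
        seq = "ACGTTCAGCTCTTA"
        ctx = sg.cytosine_contexts(seq)
        table = {(int(r.pos), r.strand): r.context for r in ctx.itertuples()}
        # + strand: CG at 1, CAG -> CHG at 5, CTC -> CHH at 8, CTT -> CHH at 10
        assert table[(1, "+")] == "CG"
        assert table[(5, "+")] == "CHG"
        assert table[(8, "+")] == "CHH"
        assert table[(10, "+")] == "CHH"
        # - strand (context read 3'->5' on the plus sequence): CG at 2, CHG at 7
        assert table[(2, "-")] == "CG"
        assert table[(7, "-")] == "CHG"
        assert len(table) == 6

    def test_unmethylated_region_low_level(self, small_genome):
        calls = sg.simulate_bisulfite_calls(
            small_genome, [("chr1", 0, 5_000, "unmethylated")], depth_mean=50,
            conversion_error=0.0, seed=4,
        )
        level = calls["count_methylated"].sum() / calls["count_total"].sum()
        assert level <= 0.05

    def test_zero_depth_rows_excluded(self, small_genome):
        calls = sg.simulate_bisulfite_calls(
            small_genome, [("chr1", 0, 2_000, "methylated")], depth_mean=1.0, seed=5
        )
        assert (calls["count_total"] > 0).all()

    def test_deterministic(self, small_genome):
        args = (small_genome, [("chr1", 0, 1_000, "methylated")], 20.0, 0.0, 9)
        assert sg.simulate_bisulfite_calls(*args).equals(sg.simulate_bisulfite_calls(*args))


class TestCross:
    def test_f2_genotype_ratio_1_2_1(self):
        pop = sg.simulate_cross(sg.CrossConfig(seed=1, epsilon=0.0), "F2", 20_000)
        geno = pop.epi_genotype()
        counts = {g: int((geno == g).sum()) for g in ("mm", "mu", "uu")}
        n = len(pop)
        assert counts["mm"] == pytest.approx(n / 4, abs=4 * np.sqrt(n * 3 / 16))
        assert counts["mu"] == pytest.approx(n / 2, abs=4 * np.sqrt(n / 4))

    def test_f2_parental_allele_frequency_half(self):
        pop = sg.simulate_cross(sg.CrossConfig(seed=2, epsilon=0.0), "F2", 10_000)
        freq_a = (pop.marker == 0).mean()
        assert freq_a == pytest.approx(0.5, abs=0.02)

    def test_no_epsilon_no_state_changes_across_generations(self):
        cfg = sg.CrossConfig(seed=3, epsilon=0.0)
        series = sg.simulate_selfing_series(cfg, ("m", "m"), ("d", "d"), n_generations=5, n=200)
        for pop in series:
            assert (pop.epi == 0).all()  # every allele still methylated

    def test_ddm1_loss_is_geometric_and_irreversible(self):
        eps = 0.3
        cfg = sg.CrossConfig(seed=4, epsilon=eps)
        series = sg.simulate_selfing_series(cfg, ("m", "m"), ("d", "d"), n_generations=4, n=5_000)
        fractions = [(pop.epi == 0).mean() for pop in series]
        # methylated-allele frequency decays as (1-eps)^generation
        for g, frac in enumerate(fractions):
            assert frac == pytest.approx((1 - eps) ** g, abs=0.03)
        assert fractions == sorted(fractions, reverse=True)

    def test_wildtype_ddm1_never_loses(self):
        cfg = sg.CrossConfig(seed=5, epsilon=0.5)
        series = sg.simulate_selfing_series(cfg, ("m", "m"), ("D", "D"), n_generations=3, n=500)
        assert (series[-1].epi == 0).all()

    def test_deterministic(self):
        cfg = sg.CrossConfig(seed=6)
        a = sg.simulate_cross(cfg, "F2", 500).to_frame()
        b = sg.simulate_cross(cfg, "F2", 500).to_frame()
        assert a.equals(b)


class TestEvolveStar:
    def test_zero_time_identical_tips(self):
        cfg = sg.EvolutionConfig(length=500, n_tips=5, age_years=0.0, seed=1)
        al = sg.evolve_star(cfg)
        assert all(s == al.ancestor for s in al.sequences)

    def test_tip_divergence_matches_rate_times_age(self, star_alignment):
        al, cfg = star_alignment
        div = np.mean([raw_distance(s, al.ancestor) for s in al.sequences])
        expected = cfg.rate * cfg.age_years
        assert div == pytest.approx(expected, rel=0.15)

    def test_pairwise_divergence_twice_tip_divergence(self, star_alignment):
        al, cfg = star_alignment
        pair = np.mean(
            [raw_distance(al.sequences[i], al.sequences[j]) for i in range(10) for j in range(i)]
        )
        assert pair == pytest.approx(2 * cfg.rate * cfg.age_years, rel=0.2)

    def test_long_time_converges_to_stationary_frequencies(self):
        params = sg.TN93Params((0.32, 0.18, 0.18, 0.32), 2.0, 2.0, 1.0)
        cfg = sg.EvolutionConfig(
            length=20_000, n_tips=3, age_years=1e9, rate=1e-8, params=params, seed=2
        )
        al = sg.evolve_star(cfg)
        tip = al.sequences[0]
        freqs = np.array([tip.count(b) for b in "ACGT"]) / len(tip)
        assert np.allclose(freqs, params.freqs, atol=0.02)

    def test_zero_length_ancestor_rejected(self):
        with pytest.raises(ValueError):
            sg.EvolutionConfig(ancestor="", n_tips=2)


class TestClimateTable:
    def test_group_sizes_follow_proportions(self):
        t = sg.simulate_climate_table(1_000, (0.2, 0.3, 0.5), seed=1)
        counts = t["group"].value_counts()
        assert counts["methylated"] == pytest.approx(200, abs=60)
        assert counts["deletion"] == pytest.approx(500, abs=70)

    def test_methylation_zero_when_absent(self):
        t = sg.simulate_climate_table(seed=2)
        deleted = t[t["group"] == "deletion"]
        assert (deleted["meth_total"] == 0).all()
        assert (~deleted["presence_4"]).all()

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            sg.simulate_climate_table(100, (0.5, 0.2, 0.2))


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_generators_bit_reproducible(seed):
    """Any generator called twice with one seed yields identical output."""
    a = sg.make_reference(seed, {"c": 1_000})
    b = sg.make_reference(seed, {"c": 1_000})
    assert a.sequences == b.sequences
    ca = sg.simulate_climate_table(30, seed=seed)
    cb = sg.simulate_climate_table(30, seed=seed)
    assert ca.equals(cb)
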