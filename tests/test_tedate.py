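"""TN93 distances, NJ, ancestral reconstruction and the two age estimators.

The TN93 closed form is checked against an independent numerical inversion
of the substitution model (matrix exponentials + root finding), and NJ
against three-point formulas, brute-force topology recovery on additive
matrices, and scikit-bio's implementation.
"""

import itertools
from io import StringIO

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from oracles import (
    balanced_pair,
    random_additive_tree as _random_additive_tree,
    splits as _splits,
    tn93_numeric_oracle,
)

from epiline import synthgen as sg
from epiline import tedate


class TestTN93:
    def test_identical_sequences_zero(self):
        assert tedate.tn93_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_symmetry(self, star_alignment):
        al, _ = star_alignment
        a, b = al.sequences[0], al.sequences[1]
        assert tedate.tn93_distance(a, b) == pytest.approx(tedate.tn93_distance(b, a))

    def test_closed_form_matches_numeric_inversion(self, star_alignment):
        al, _ = star_alignment
        for i, j in [(0, 1), (2, 9), (5, 17)]:
            a, b = al.sequences[i], al.sequences[j]
            assert tedate.tn93_distance(a, b) == pytest.approx(
                tn93_numeric_oracle(a, b), abs=1e-9
            )

    def test_reduces_to_jukes_cantor_in_equal_rates_limit(self):
        a, b = balanced_pair()
        p = sum(x != y for x, y in zip(a, b)) / len(a)
        jc = -0.75 * np.log(1 - 4 * p / 3)
        assert tedate.tn93_distance(a, b) == pytest.approx(jc, abs=1e-9)

    def test_saturated_pair_flagged(self):
        with pytest.raises(tedate.SaturatedDistanceError):
            tedate.tn93_distance("A" * 100, "G" * 100)

    def test_gap_sites_excluded_pairwise(self):
        a = "ACGTAC-TAC"
        b = "ACGTACGTNC"
        # only the 8 mutually unambiguous sites are compared; all match
        assert tedate.tn93_distance(a, b) == 0.0

    def test_zero_iff_identical_over_included_sites(self, star_alignment):
        al, _ = star_alignment
        a, b = al.sequences[0], al.sequences[3]
        if a != b:
            assert tedate.tn93_distance(a, b) > 0


# ---------------------------------------------------------------------------
# Neighbor joining


class TestNJ:
    def test_three_taxon_exact_branch_lengths(self):
        dm = np.array([[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        newick = tedate.nj_tree(dm, ["a", "b", "c"])
        tree = TreeNode.read(StringIO(newick))
        lengths = {t.name: t.length for t in tree.tips()}
        # three-point formulas: (d_ab + d_ac - d_bc)/2 etc.
        assert lengths["a"] == pytest.approx(0.05)
        assert lengths["b"] == pytest.approx(0.15)
        assert lengths["c"] == pytest.approx(0.25)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_recovers_all_additive_topologies(self, n_taxa):
        rng = np.random.default_rng(17)
        names = [f"t{i}" for i in range(n_taxa)]
        seen = set()
        for _ in range(30):
            tree = _random_additive_tree(names, rng)
            true_newick = str(tree)
            dm = tree.tip_tip_distances()
            order = [dm.ids.index(n) for n in names]
            mat = dm.data[np.ix_(order, order)]
            mine = tedate.nj_tree(mat, names)
            assert _splits(mine) == _splits(true_newick)
            seen.add(frozenset(_splits(true_newick)))
        # the random trees covered more than one topology
        assert len(seen) >= (3 if n_taxa == 4 else 5)

    def test_additive_branch_lengths_recovered(self):
        rng = np.random.default_rng(3)
        names = ["a", "b", "c", "d"]
        tree = _random_additive_tree(names, rng)
        dm = tree.tip_tip_distances()
        order = [dm.ids.index(n) for n in names]
        mine = tedate.nj_tree(dm.data[np.ix_(order, order)], names)
        got = TreeNode.read(StringIO(mine)).tip_tip_distances()
        for i, j in itertools.combinations(names, 2):
            assert got[i, j] == pytest.approx(dm[i, j], abs=1e-9)

    def test_agrees_with_skbio_topology(self, star_alignment):
        al, _ = star_alignment
        n = 12
        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            mat[i, j] = mat[j, i] = tedate.tn93_distance(al.sequences[i], al.sequences[j])
        names = al.names[:n]
        mine = tedate.nj_tree(mat, names)
        ref = skbio_nj(DistanceMatrix(mat, names))
        assert _splits(mine) == _splits(str(ref))

    def test_star_distances_give_no_internal_structure(self):
        # perfectly ultrametric star: all pairwise distances equal
        n = 6
        mat = np.full((n, n), 0.2)
        np.fill_diagonal(mat, 0.0)
        newick = tedate.nj_tree(mat, [f"t{i}" for i in range(n)])
        tree = TreeNode.read(StringIO(newick))
        internal = [
            node.length for node in tree.non_tips(include_self=False) if node.length
        ]
        assert all(l == pytest.approx(0.0, abs=1e-12) for l in internal)

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            tedate.nj_tree(np.zeros((2, 2)), ["a", "b"])
        with pytest.raises(ValueError):
            tedate.nj_tree(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])


# ---------------------------------------------------------------------------
# Rate calibration and ages


class TestEstimators:
    def test_calibration_arithmetic(self):
        assert tedate.calibrate_rate(0.0, 5e6) == 0.0
        assert tedate.calibrate_rate(0.068, 5e6) == pytest.approx(6.8e-9)
        with pytest.raises(ValueError):
            tedate.calibrate_rate(0.1, 0.0)

    def test_star_age_is_mean_pairwise_over_twice_rate(self, star_alignment):
        al, _ = star_alignment
        r = 6.8e-9
        expected = tedate.mean_pairwise_distance(al) / (2 * r)
        assert tedate.star_age(al, r) == pytest.approx(expected)

    def test_identical_sequences_age_zero(self):
        al = tedate.AlignedSet(["a", "b"], ["ACGT" * 50, "ACGT" * 50])
        assert tedate.star_age(al, 6.8e-9) == 0.0
        assert tedate.mrca_age(al, "ACGT" * 50, 6.8e-9) == 0.0

    def test_mrca_age_counts_raw_substitutions(self):
        anc = "ACGT" * 75  # 300 sites
        tip = "TCGT" + anc[4:]  # one substitution
        al = tedate.AlignedSet(["a", "b"], [tip, tip])
        expected = (1 / 300) / 6.8e-9
        assert tedate.mrca_age(al, anc, 6.8e-9) == pytest.approx(expected)

    def test_parameter_recovery_single_seed(self, star_alignment):
        al, cfg = star_alignment
        t_star = tedate.star_age(al, cfg.rate)
        assert t_star == pytest.approx(cfg.age_years, rel=0.15)


class TestAncestralReconstruction:
    @staticmethod
    def _nj_of(al):
        n = len(al)
        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            mat[i, j] = mat[j, i] = tedate.tn93_distance(al.sequences[i], al.sequences[j])
        return tedate.nj_tree(mat, al.names)

    def test_identical_tips_reconstructed_exactly(self):
        seq = "ACGTTGCA" * 40
        al = tedate.AlignedSet(["a", "b", "c"], [seq] * 3)
        newick = "(a:0.01,b:0.01,c:0.01);"
        assert tedate.ancestral_sequence(al, newick) == seq

    def test_low_divergence_matches_majority_consensus(self, star_alignment):
        al, _ = star_alignment
        anc = tedate.ancestral_sequence(al, self._nj_of(al))
        arr = np.array([list(s) for s in al.sequences])
        consensus = []
        for col in arr.T:
            vals, counts = np.unique(col, return_counts=True)
            consensus.append(vals[np.argmax(counts)])
        agreement = np.mean([a == c for a, c in zip(anc, consensus)])
        assert agreement >= 0.999

    def test_two_tip_tie_broken_by_stationary_frequency(self):
        # A is the overwhelmingly common base, so an A/G site resolves to A
        base = "A" * 99
        al = tedate.AlignedSet(["x", "y"], [base + "A", base + "G"])
        anc = tedate.ancestral_sequence(al, "(x:0.02,y:0.02);")
        assert anc[-1] == "A"

    def test_mismatched_leaf_names_rejected(self):
        al = tedate.AlignedSet(["a", "b"], ["ACGT", "ACGT"])
        with pytest.raises(ValueError):
            tedate.ancestral_sequence(al, "(a:0.1,z:0.1);")


class TestDateInsertion:
    def test_zero_divergence_gives_zero_ages(self):
        seq = "ACGT" * 100
        al = tedate.AlignedSet(["a", "b", "c"], [seq] * 3)
        orth = (seq, seq[:-4] + "TGCA")  # small ortholog divergence for the rate
        res = tedate.date_insertion(al, orth)
        assert res.t_star == 0.0 and res.t_mrca == 0.0

    def test_end_to_end_recovery_and_sensitivity_bracket(self):
        rate, age = 6.8e-9, 5e5
        al = sg.evolve_star(
            sg.EvolutionConfig(length=3_000, n_tips=40, age_years=age, rate=rate, seed=31)
        )
        t_div = (3.5e6, 5.8e6)
        orth = sg.evolve_star(
            sg.EvolutionConfig(
                length=3_000, n_tips=2, age_years=0.5 * sum(t_div), rate=rate, seed=32
            )
        )
        res = tedate.date_insertion(al, tuple(orth.sequences), t_div)
        assert res.rate == pytest.approx(rate, rel=0.2)
        assert res.t_star == pytest.approx(age, rel=0.15)
        assert res.t_mrca == pytest.approx(age, rel=0.15)
        # the reported T_div sensitivity interval spans the truth
        lo = min(res.t_star_range[0], res.t_mrca_range[0])
        hi = max(res.t_star_range[1], res.t_mrca_range[1])
        assert lo <= age <= hi

    def test_drop_all_gap_columns_utility(self):
        al = tedate.AlignedSet(["a", "b"], ["AC-T", "AG-T"])
        stripped = al.drop_all_gap_columns()
        assert stripped.sequences == ["ACT", "AGT"]


def test_estimator_bias_shrinks_with_length():
    """Consistency: star-age error decreases as the alignment grows."""
    rate, age = 6.8e-9, 5e5
    errors = []
    for length in (1_000, 10_000):
        errs = [
            abs(
                tedate.star_age(
                    sg.evolve_star(
                        sg.EvolutionConfig(
                            length=length, n_tips=20, age_years=age, rate=rate, seed=s
                        )
                    ),
                    rate,
                )
                - age
            )
            for s in range(41, 46)
        ]
        errors.append(np.mean(errs))
    assert errors[1] < errors[0]
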