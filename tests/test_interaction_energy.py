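import math

import pytest

from loopscreen.interaction_energy import (
    HybridError,
    accessibility_penalty,
    combined_energy,
    hybrid_energy,
    minimum_energy_interaction,
    unpaired_probability,
)
from loopscreen.params import DEFAULT_MODEL
from loopscreen.sequences import RnaSequence
from loopscreen.synthetic import generate_mirna_mrna_pair
from tests.oracles import enumerate_duplexes


def _seq(bases, id="x", kind="mRNA"):
    return RnaSequence(id=id, bases=bases, kind=kind)


class TestUnpairedProbability:
    def test_pairless_sequence_always_free(self):
        seq = _seq("AAAAAAA")  # no U: nothing can pair
        for i in range(1, 8):
            for k in range(i, 8):
                assert unpaired_probability(seq, i, k) == pytest.approx(1.0)

    def test_hairpin_loop_bases_free_in_both_structures(self):
        # GAAAC has exactly two structures; 2..4 unpaired in both
        assert unpaired_probability(_seq("GAAAC"), 2, 4) == pytest.approx(1.0)

    def test_closing_bases_probability_from_boltzmann_weights(self):
        # P(1..5 all unpaired) = w(open) / (w(open) + w(hairpin))
        seq = _seq("GAAAC")
        e_hairpin = DEFAULT_MODEL.pair("G", "C") + DEFAULT_MODEL.hairpin(3)
        expected = 1.0 / (1.0 + math.exp(-e_hairpin / DEFAULT_MODEL.rt))
        assert unpaired_probability(seq, 1, 5) == pytest.approx(expected, abs=1e-12)

    def test_superinterval_not_more_probable(self, random_sequences):
        for seq in random_sequences(8, 10, 18, seed=41):
            pu_wide = unpaired_probability(seq, 2, 8)
            for i, k in [(2, 5), (4, 8), (3, 7)]:
                assert pu_wide <= unpaired_probability(seq, i, k) + 1e-12

    def test_enumeration_and_partition_routes_agree(self, random_sequences):
        for seq in random_sequences(10, 10, 22, seed=42):
            n = len(seq)
            i, k = 2, min(n, 6)
            pe = unpaired_probability(seq, i, k, method="enumeration")
            pp = unpaired_probability(seq, i, k, method="partition")
            assert pe == pytest.approx(pp, abs=1e-9)

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            unpaired_probability(_seq("ACGUA"), 3, 2)

    def test_ed_zero_iff_fully_accessible(self):
        assert accessibility_penalty(_seq("AAAAA"), 1, 5) == pytest.approx(0.0)
        assert accessibility_penalty(_seq("GGGAAACCC"), 4, 6) >= 0.0


class TestHybridEnergy:
    def test_perfect_duplex_is_pairs_stacks_and_initiation(self):
        m = DEFAULT_MODEL
        h = hybrid_energy(_seq("GGGAGG", kind="miRNA"), _seq("CCUCCC"), 1, 6, 1, 6)
        expected = (
            sum(m.pair(a, b) for a, b in zip("GGGAGG", "CCUCCC"[::-1]))
            + 5 * m.stack_bonus
            + m.duplex_init
        )
        assert h.energy == pytest.approx(expected)

    def test_interior_mismatch_costs_energy(self):
        perfect = hybrid_energy(_seq("GGGAGG", kind="miRNA"), _seq("CCUCCC"), 1, 6, 1, 6)
        # central mismatch: A->C opposite the unchanged mRNA
        worse = hybrid_energy(_seq("GGGCGG", kind="miRNA"), _seq("CCUCCC"), 1, 6, 1, 6)
        assert worse.energy > perfect.energy

    def test_unpairable_terminal_rejected(self):
        with pytest.raises(HybridError):
            hybrid_energy(_seq("AGGAGG", kind="miRNA"), _seq("CCUCCC"), 1, 6, 1, 6)

    def test_matches_duplex_enumeration(self, random_sequences):
        mis = random_sequences(12, 8, 8, seed=43)
        ms = random_sequences(12, 10, 10, seed=44)
        checked = 0
        for mi, m in zip(mis, ms):
            for (i, k, j, l) in [(1, 6, 2, 9), (2, 7, 1, 8), (1, 8, 1, 10)]:
                try:
                    h = hybrid_energy(mi, m, i, k, j, l, max_loop=4)
                except (HybridError, ValueError):
                    continue
                energies = enumerate_duplexes(
                    mi.bases, m.bases, i, k, j, l, DEFAULT_MODEL, max_loop=4
                )
                assert energies, "oracle found no duplex but DP did"
                assert h.energy == pytest.approx(min(energies), abs=1e-9)
                checked += 1
        assert checked >= 5

    def test_role_swap_preserves_hybrid_energy(self):
        mi, m = _seq("GGAGGCAG", kind="miRNA"), _seq("AAUGCCUCCA")
        a = hybrid_energy(mi, m, 1, 7, 3, 9)
        b = hybrid_energy(m, mi, 3, 9, 1, 7)
        assert a.energy == pytest.approx(b.energy)


class TestCombinedEnergy:
    def test_fully_accessible_reduces_to_hybrid_plus_dangles(self):
        mi, m = _seq("GGGAGGA", kind="miRNA"), _seq("ACCUCCC")
        ce = combined_energy(mi, m, 1, 6, 2, 7)
        assert ce.ed_mirna == pytest.approx(0.0)
        assert ce.ed_mrna == pytest.approx(0.0)
        h = hybrid_energy(mi, m, 1, 6, 2, 7)
        assert ce.total == pytest.approx(h.energy + sum(ce.dangle_terms.values()))

    def test_terminal_interval_has_no_outer_dangle(self):
        mi, m = _seq("GGGAGG", kind="miRNA"), _seq("CCUCCC")
        ce = combined_energy(mi, m, 1, 6, 1, 6)
        assert ce.dangle_terms == {}

    def test_total_is_component_sum_exactly(self):
        mi, m = _seq("AGGAGGCAGGA", kind="miRNA"), _seq("AAAUGCCUCCAAAA")
        ce = combined_energy(mi, m, 2, 8, 4, 10)
        manual = (
            ce.e_hybrid + ce.ed_mirna + ce.ed_mrna + sum(ce.dangle_terms.values())
        )
        assert ce.total == manual  # bit-for-bit additivity

    def test_components_match_independent_recomputation(self):
        mi, m = _seq("AGGAGGCAGGA", kind="miRNA"), _seq("AAAUGCCUCCAAAA")
        ce = combined_energy(mi, m, 2, 8, 4, 10)
        assert ce.e_hybrid == pytest.approx(hybrid_energy(mi, m, 2, 8, 4, 10).energy)
        assert ce.ed_mirna == pytest.approx(accessibility_penalty(mi, 2, 8))
        assert ce.ed_mrna == pytest.approx(accessibility_penalty(m, 4, 10))
        pu = unpaired_probability(mi, 2, 8)
        expected_5p = (
            unpaired_probability(mi, 1, 8) / pu * DEFAULT_MODEL.dangle_energy
        )
        assert ce.dangle_terms["mirna_5p"] == pytest.approx(expected_5p)


class TestMinimumEnergyInteraction:
    def test_covers_planted_accessible_site(self):
        mi, utr, truth = generate_mirna_mrna_pair(
            11, complement_span=(2, 9), mirna_length=12
        )
        best = minimum_energy_interaction(mi, utr, max_interval=10, max_loop=3)
        assert best is not None
        j, l = best.mrna_interval
        assert j >= truth["site_start"] - 2 and l <= truth["site_end"] + 2

    def test_sequestered_site_pays_accessibility_penalty(self):
        open_total, closed_total = [], []
        for seed in (11, 13):
            mi, utr_open, t_open = generate_mirna_mrna_pair(
                seed, complement_span=(2, 9), mirna_length=12
            )
            _, utr_closed, t_closed = generate_mirna_mrna_pair(
                seed, complement_span=(2, 9), mirna_length=12, sequester_site=True
            )
            i, k = 2, 9
            co = combined_energy(
                mi, utr_open, i, k, t_open["site_start"], t_open["site_end"], max_loop=3
            )
            cc = combined_energy(
                mi, utr_closed, i, k, t_closed["site_start"], t_closed["site_end"], max_loop=3
            )
            open_total.append(co.total)
            closed_total.append(cc.total)
        assert all(c > o for o, c in zip(open_total, closed_total))

    def test_no_pairable_quadruple_returns_none(self):
        assert (
            minimum_energy_interaction(
                _seq("AAAAAA", kind="miRNA"), _seq("CCCCCC"), max_interval=5
            )
            is None
        )

    def test_interval_cap_validated(self):
        with pytest.raises(ValueError):
            minimum_energy_interaction(
                _seq("GGGGAA", kind="miRNA"), _seq("CCCCAA"), max_interval=3
            )
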