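"""Five-term binding-energy model and the Boltzmann rate law."""

import math

import numpy as np
import pytest

import aptaswitch as ap
from aptaswitch.energy import MrnaRecord, ribosome_final_state, total_binding_energy
from aptaswitch.folding import SequenceError, duplex_fold, fold_mfe

from conftest import INERT_CDS


def mrna(utr: str, cds: str = INERT_CDS, name: str = "m") -> MrnaRecord:
    return MrnaRecord(name, utr + cds, len(utr) + 1)


class TestMrnaRecord:
    def test_valid_start_codons(self):
        for codon in ("AUG", "GUG", "UUG"):
            m = MrnaRecord("m", "A" * 10 + codon + "A" * 12, 11)
            assert m.start_codon == codon

    def test_non_start_codon_rejected(self):
        with pytest.raises(SequenceError):
            MrnaRecord("m", "A" * 10 + "CCC" + "A" * 12, 11)

    def test_footprint_must_fit(self):
        with pytest.raises(SequenceError):
            MrnaRecord("m", "A" * 10 + "AUG" + "A" * 5, 11)

    def test_t_spelling_and_whitespace_tolerated(self):
        m = MrnaRecord("m", " aaaaaaaaaa ATG aaaaaaaaaaaa ", 11)
        assert m.start_codon == "AUG"


class TestRibosomeFinalState:
    def test_unstructured_consensus_sd_all_penalties_vanish(self, calib):
        """Consensus SD, optimal spacing, nothing folded: only the duplex
        and start-codon terms remain."""
        utr = "A" * 12 + "AAGGAGGU" + "AACAA"  # SD span ends 5 nt before AUG
        bd = total_binding_energy(mrna(utr), None, calib)
        assert bd.dg_spacing == 0.0
        assert bd.dg_standby == 0.0
        assert bd.spacing_nt == calib.spacing_optimum
        assert bd.dg_initial == 0.0
        assert bd.dg_final == pytest.approx(bd.dg_mrna_rrna + bd.dg_start)
        assert bd.dg_mrna_rrna < -8 and bd.dg_start < 0

    def test_moved_sd_pays_exactly_the_spacing_difference(self, calib):
        """Same SD 4 nt further from AUG (inert C spacer): dg_final rises by
        the spacing-penalty difference and nothing else."""
        near = "A" * 12 + "AAGGAGGU" + "AACAA"
        far = "A" * 8 + "AAGGAGGU" + "ACAACAACA"  # spacing 9, inert filler
        bd_near = total_binding_energy(mrna(near), None, calib)
        bd_far = total_binding_energy(mrna(far), None, calib)
        assert bd_near.spacing_nt == 5 and bd_far.spacing_nt == 9
        assert bd_far.dg_final - bd_near.dg_final == pytest.approx(
            calib.spacing_penalty(9) - calib.spacing_penalty(5), abs=1e-6
        )

    def test_hairpin_in_footprint_costs_its_unfolding_energy(self, calib):
        """A hairpin fully inside the footprint leaves dg_final unchanged
        (it is forced open) while stabilizing the initial state, so
        dg_total rises by exactly the in-context unfolding cost, derived
        here from an independent with/without paired fold."""
        plain_utr = "A" * 16 + "AAGGAGGU" + "AACAA"
        # 10-nt hairpin at CDS positions 4-13: inside the 13-nt footprint
        cds_hp = "AUG" + "GGGAAAACCC" + "AAAAAAAAAAAA"
        cds_plain = "AUG" + "A" * 22
        m_plain = mrna(plain_utr, cds_plain)
        m_hp = mrna(plain_utr, cds_hp)
        bd_plain = total_binding_energy(m_plain, None, calib)
        bd_hp = total_binding_energy(m_hp, None, calib)
        unfold_cost = (
            fold_mfe(m_plain.sequence).dg_fold - fold_mfe(m_hp.sequence).dg_fold
        )
        assert unfold_cost > 0.5  # the hairpin really folds in context
        assert bd_hp.dg_final == pytest.approx(bd_plain.dg_final, abs=1e-6)
        assert bd_hp.dg_total - bd_plain.dg_total == pytest.approx(
            unfold_cost, abs=1e-6
        )

    def test_structure_outside_footprint_cancels_in_dg_total(self, calib):
        """A stable hairpin entirely 3' of the footprint appears in both
        dg_initial and the outside-footprint term: dg_total is invariant."""
        utr = "A" * 12 + "AAGGAGGU" + "AACAA"
        tail_hp = "GGGGGAAAACCCCC"
        base = mrna(utr, INERT_CDS)
        extended = MrnaRecord("m2", utr + INERT_CDS + tail_hp, len(utr) + 1)
        bd0 = total_binding_energy(base, None, calib)
        bd1 = total_binding_energy(extended, None, calib)
        assert bd1.dg_initial < bd0.dg_initial  # the hairpin does fold
        assert bd1.dg_total == pytest.approx(bd0.dg_total, abs=1e-6)

    def test_no_sd_sentinel_is_flagged_not_raised(self, calib):
        utr = "CACACACACACACACA"  # nothing pairs the G-free anti-SD
        bd = total_binding_energy(mrna(utr), None, calib)
        assert bd.no_sd
        assert bd.dg_mrna_rrna == 0.0 and bd.sd_span is None

    def test_matches_bruteforce_placement_minimum(self, calib):
        """Independent re-enumeration of every SD placement on short UTRs."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            utr = "".join(rng.choice(list("ACGU"), size=24)) + "AGGAG" + "ACAAA"
            try:
                m = mrna(utr)
            except SequenceError:
                continue
            bd = total_binding_energy(m, None, calib)
            assert bd.dg_final == pytest.approx(
                _brute_force_min_final(m, calib), abs=1e-6
            )

    def test_sentinel_total_is_nonnegative(self, calib):
        bd = total_binding_energy(mrna("CACACACACACACACA"), None, calib)
        assert bd.dg_total >= -1e-9


def _brute_force_min_final(m, calib):
    """Naive re-enumeration of all SD placements with all five terms."""
    best = math.inf
    n = len(m.sequence)
    for spacing in range(calib.spacing_max + 1):
        end = m.cds_start - 1 - spacing
        if end < 1:
            break
        start = max(1, end - 8)
        hit = duplex_fold(m.sequence[start - 1 : end], calib.anti_sd)
        if hit is None:
            continue
        sd = (start + hit.span1[0] - 1, start + hit.span1[1] - 1)
        realized = m.cds_start - 1 - sd[1]
        if realized > calib.spacing_max:
            continue
        cons = ["."] * n
        for k in range(sd[0] - 1, min(n, m.cds_start + 12)):
            cons[k] = "x"
        outside = fold_mfe(m.sequence, "".join(cons)).dg_fold
        sb_cons = list(cons)
        for k in range(max(0, sd[0] - 1 - calib.standby_window), sd[0] - 1):
            sb_cons[k] = "x"
        standby = max(0.0, fold_mfe(m.sequence, "".join(sb_cons)).dg_fold - outside)
        total = (
            hit.dg
            + calib.start_codon_energies[m.start_codon]
            + calib.spacing_penalty(realized)
            + standby
            + outside
        )
        best = min(best, total)
    return best


class TestTir:
    def test_zero_energy_gives_k_tir(self, calib):
        assert ap.tir(0.0, calib) == calib.k_tir

    def test_reference_utr_anchor(self, calib):
        """beta = 0.45 with the default k_tir maps -7.52 kcal/mol to
        36,400 au, the reference 5' UTR operating point."""
        assert ap.tir(-7.52, calib) == pytest.approx(36_400.0, rel=1e-9)

    def test_ratio_depends_only_on_ddg(self, calib):
        g1, g2 = -3.1, 4.7
        assert ap.tir(g1, calib) / ap.tir(g2, calib) == pytest.approx(
            math.exp(-calib.beta * (g1 - g2))
        )

    def test_strictly_decreasing(self, calib):
        rates = [ap.tir(g, calib) for g in np.linspace(-10, 10, 30)]
        assert all(a > b > 0 for a, b in zip(rates, rates[1:]))


class TestDecomposition:
    def test_total_is_final_minus_initial(self, calib, hairpin_aptamer):
        from conftest import random_constructs

        for c in random_constructs(hairpin_aptamer, 6, seed=3):
            bd = total_binding_energy(c.mrna(), None, calib)
            assert bd.dg_total == pytest.approx(
                bd.dg_final - bd.dg_initial, abs=1e-6
            )
            assert bd.dg_mrna_rrna <= 0 and bd.dg_start <= 0
            assert bd.dg_spacing >= 0 and bd.dg_standby >= 0
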