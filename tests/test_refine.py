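"""Candidate scoring, the two-filter decision and the refinement loop."""

import pytest

from blockshift import (Config, PairwiseAlignment, extract_blocks, qscore,
                        refine_alignment, zero_energy_matrix)
from blockshift.contacts import build_contact_map
from blockshift.errors import ModeError
from blockshift.refine import (ScoreBundle, annotate_changes, score_candidates,
                               standardize_and_combine, two_filter_decide)
from blockshift.report import render_json_report, render_text_report
from blockshift.structio import map_structure_to_template
from blockshift.variants import GapMode, generate_variants, AlignmentVariant


def _bundle(s_seq, s_str, shift, incumbent=False):
    return ScoreBundle(GapMode.ORIGINAL, shift, s_seq, s_str,
                       is_incumbent=incumbent)


class TestStandardizeAndCombine:
    def test_single_candidate_degenerates_to_zero(self):
        b = _bundle(5.0, -2.0, 0, incumbent=True)
        standardize_and_combine([b])
        assert b.z_seq == b.z_str == b.s_comb_1 == b.s_comb_2 == 0.0

    def test_hand_arithmetic_three_candidates(self):
        """z-scores and equal-weight combinations match hand arithmetic."""
        bundles = [_bundle(1.0, 2.0, 0, incumbent=True),
                   _bundle(2.0, 0.0, 1),
                   _bundle(3.0, 4.0, -1)]
        standardize_and_combine(bundles, w1=0.5, w2=0.5)
        # s_seq: mean 2, sd sqrt(2/3); s_str: mean 2, sd sqrt(8/3)
        sd_seq = (2.0 / 3.0) ** 0.5
        sd_str = (8.0 / 3.0) ** 0.5
        assert bundles[0].z_seq == pytest.approx(-1.0 / sd_seq)
        assert bundles[0].z_str == pytest.approx(0.0)
        assert bundles[2].s_comb_1 == pytest.approx(
            0.5 * (1.0 / sd_seq) + 0.5 * (2.0 / sd_str))
        for b in bundles:
            assert b.s_comb_1 == pytest.approx(b.s_comb_2)


class TestTwoFilterDecide:
    def _decide(self, incumbent, variants):
        class FakeBlock:
            ordinal = 1
            pairs = []
        return two_filter_decide(FakeBlock(), [incumbent] + variants)

    def test_reject_at_filter_one(self):
        inc = _bundle(0.0, 0.0, 0, incumbent=True)
        inc.s_comb_1 = inc.s_comb_2 = 1.0
        worse = _bundle(0, 0, 1)
        worse.s_comb_1, worse.s_comb_2 = 0.5, 2.0
        d = self._decide(inc, [worse])
        assert d.kept and d.chosen is None and d.shift_result == "No shift"

    def test_reject_at_filter_two(self):
        inc = _bundle(0.0, 0.0, 0, incumbent=True)
        inc.s_comb_1, inc.s_comb_2 = 0.0, 1.0
        v = _bundle(0, 0, 2)
        v.s_comb_1, v.s_comb_2 = 1.0, 0.5  # wins filter 1, loses filter 2
        d = self._decide(inc, [v])
        assert d.kept

    def test_accept_when_higher_on_both(self):
        inc = _bundle(0.0, 0.0, 0, incumbent=True)
        inc.s_comb_1 = inc.s_comb_2 = 0.0
        v = _bundle(0, 0, -2)
        v.s_comb_1 = v.s_comb_2 = 1.0
        d = self._decide(inc, [v])
        assert not d.kept
        assert d.chosen == (GapMode.ORIGINAL, -2)

    def test_exact_tie_keeps_original(self):
        inc = _bundle(0.0, 0.0, 0, incumbent=True)
        inc.s_comb_1 = inc.s_comb_2 = 1.0
        v = _bundle(0, 0, 1)
        v.s_comb_1 = v.s_comb_2 = 1.0
        assert self._decide(inc, [v]).kept

    def test_tied_variants_first_in_canonical_order_wins(self):
        inc = _bundle(0.0, 0.0, 0, incumbent=True)
        a = _bundle(0, 0, -1)
        b = _bundle(0, 0, 2)
        for v in (a, b):
            v.s_comb_1 = v.s_comb_2 = 2.0
        d = self._decide(inc, [a, b])
        assert d.chosen == (GapMode.ORIGINAL, -1)


class TestScoreCandidates:
    def test_zero_matrix_ranks_by_sequence_score(self, clean_case, og_config):
        aln = clean_case.true_alignment
        blocks = extract_blocks(aln, clean_case.sse)
        block = blocks[1]
        smap = map_structure_to_template(aln.template, clean_case.chain)
        cmap = build_contact_map(clean_case.chain, smap)
        variants = generate_variants(aln, clean_case.sse, block, mode="O+G")
        incumbent = AlignmentVariant(GapMode.ORIGINAL, 0, list(block.pairs),
                                     aln, True, True)
        bundles = score_candidates(block, incumbent, variants,
                                   clean_case.qprof, clean_case.tprof,
                                   cmap, zero_energy_matrix())
        unique = [b for b in bundles if b.unique]
        by_comb = sorted(unique, key=lambda b: -b.s_comb_1)
        by_seq = sorted(unique, key=lambda b: -b.s_seq)
        assert [(b.gap_mode, b.shift) for b in by_comb] == \
            [(b.gap_mode, b.shift) for b in by_seq]
        assert all(b.s_str == 0.0 for b in bundles)


class TestRefineAlignment:
    def test_idempotent_on_planted_optimum(self, clean_case, og_config):
        rep = refine_alignment(clean_case.starting_alignment, clean_case.chain,
                               clean_case.sse, og_config,
                               qprof=clean_case.qprof, tprof=clean_case.tprof)
        assert rep.refined.query_row == clean_case.starting_alignment.query_row
        assert all(d.kept for d in rep.decisions)

    def test_recovers_planted_shift(self, shifted_case, og_config):
        rep = refine_alignment(shifted_case.starting_alignment,
                               shifted_case.chain, shifted_case.sse, og_config,
                               qprof=shifted_case.qprof,
                               tprof=shifted_case.tprof)
        assert qscore(rep.refined, shifted_case.true_alignment).q == 100.0
        dec = rep.decisions[1]
        assert not dec.kept
        assert dec.chosen[1] == -2  # undoes the planted +2

    def test_identity_gate_blocks_refinement(self, shifted_case):
        cfg = Config(mode="O+G", min_identity=1.0)  # identity 1.0 is not > 1.0
        rep = refine_alignment(shifted_case.starting_alignment,
                               shifted_case.chain, shifted_case.sse, cfg,
                               qprof=shifted_case.qprof,
                               tprof=shifted_case.tprof)
        assert not rep.gate_passed
        assert rep.refined == shifted_case.starting_alignment
        assert all(not d.evaluated for d in rep.decisions)

    def test_max_shift_zero_is_identity(self, shifted_case):
        cfg = Config(mode="O", max_shift=0)
        rep = refine_alignment(shifted_case.starting_alignment,
                               shifted_case.chain, shifted_case.sse, cfg,
                               qprof=shifted_case.qprof,
                               tprof=shifted_case.tprof)
        assert rep.refined == shifted_case.starting_alignment

    def test_monotone_safety_on_peaked_fixture(self, shifted_case, og_config):
        start_q = qscore(shifted_case.starting_alignment,
                         shifted_case.true_alignment).q
        rep = refine_alignment(shifted_case.starting_alignment,
                               shifted_case.chain, shifted_case.sse, og_config,
                               qprof=shifted_case.qprof,
                               tprof=shifted_case.tprof)
        assert qscore(rep.refined, shifted_case.true_alignment).q >= start_q

    def test_reports_are_deterministic(self, shifted_case, og_config):
        runs = []
        for _ in range(2):
            rep = refine_alignment(shifted_case.starting_alignment,
                                   shifted_case.chain, shifted_case.sse,
                                   og_config, qprof=shifted_case.qprof,
                                   tprof=shifted_case.tprof)
            runs.append((render_text_report(rep), render_json_report(rep)))
        assert runs[0] == runs[1]

    def test_svm_mode_rejected(self, shifted_case):
        with pytest.raises(ModeError, match="not implemented"):
            refine_alignment(shifted_case.starting_alignment,
                             shifted_case.chain, shifted_case.sse,
                             Config(mode="O+G+M+S"))

    def test_frozen_state_matches_committed_on_single_error(self, shifted_case):
        """With one misaligned block, scoring against the frozen starting
        state and against the committed state reach the same refinement."""
        reps = []
        for freeze in (False, True):
            cfg = Config(mode="O+G", freeze_state=freeze)
            reps.append(refine_alignment(
                shifted_case.starting_alignment, shifted_case.chain,
                shifted_case.sse, cfg, qprof=shifted_case.qprof,
                tprof=shifted_case.tprof))
        assert set(reps[0].refined.pairs()) == set(reps[1].refined.pairs())
        assert qscore(reps[1].refined, shifted_case.true_alignment).q == 100.0

    def test_query_sse_rendered_for_display(self, shifted_case, og_config):
        qsse = "C" * len(shifted_case.query)
        rep = refine_alignment(shifted_case.starting_alignment,
                               shifted_case.chain, shifted_case.sse,
                               og_config, qprof=shifted_case.qprof,
                               tprof=shifted_case.tprof, query_sse=qsse)
        text = render_text_report(rep)
        assert rep.query_sse == qsse
        assert "SSE" in text

    def test_conservation_under_every_decision(self, shifted_case, og_config):
        rep = refine_alignment(shifted_case.starting_alignment,
                               shifted_case.chain, shifted_case.sse, og_config,
                               qprof=shifted_case.qprof,
                               tprof=shifted_case.tprof)
        assert rep.refined.query_row.replace("-", "") == \
            shifted_case.query.residues
        assert rep.refined.template_row.replace("-", "") == \
            shifted_case.template.residues


class TestAnnotateChanges:
    def test_no_movement_gives_zeros(self):
        aln = PairwiseAlignment.from_rows("q", "t", "MKWV", "MKWV")
        cm1, cm2 = annotate_changes(aln, aln)
        assert cm1 == "    "
        assert cm2 == "0000"

    def test_residue_losing_partner_is_star(self):
        start = PairwiseAlignment.from_rows("q", "t", "MKW", "MKW")
        refined = PairwiseAlignment.from_rows("q", "t", "MKW-", "MK-W")
        cm1, cm2 = annotate_changes(start, refined)
        assert cm2[2] == "*"     # W now aligned to a gap
        assert cm2[3] == " "     # template W aligned to gap: blank

    def test_gap_in_both_is_dash(self):
        start = PairwiseAlignment.from_rows("q", "t", "MKW-", "M-WV")
        refined = PairwiseAlignment.from_rows("q", "t", "MKW-", "M-WV")
        cm1, cm2 = annotate_changes(start, refined)
        assert cm2[1] == "-"     # K aligned to a gap in both

    def test_moved_residue_sign_and_magnitude(self, shifted_case, og_config):
        rep = refine_alignment(shifted_case.starting_alignment,
                               shifted_case.chain, shifted_case.sse, og_config,
                               qprof=shifted_case.qprof,
                               tprof=shifted_case.tprof)
        cm1, cm2 = annotate_changes(rep.starting, rep.refined)
        moved = {(a, b) for a, b in zip(cm1, cm2) if a in "+-" and b.isdigit()}
        # undoing the planted +2 moves block residues 2 toward the N-terminus
        assert ("-", "2") in moved
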