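"""Flank extraction, closure decision rules and patch application."""

import dataclasses

import numpy as np
import pytest

from armcompare.aligner import revcomp
from armcompare.gapfill import (ClosureEvent, ClosureRules, apply_patches,
                                close_gaps, extract_flanks, mean_gap_length,
                                summarize_closures)
from armcompare.genome_io import GapRecord, GappedAssembly, SequenceRecord, scan_gaps


def make_assembly(seq: str) -> GappedAssembly:
    return GappedAssembly.from_record(SequenceRecord("chr", seq))


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# rules sized for the small sequences used in this module
SMALL_RULES = ClosureRules(flank_len=120, min_hit_len=40, anchor_tol=10,
                           max_patch=2_000)


class TestExtractFlanks:
    def test_simple_flanks(self):
        asm = make_assembly("ACGTNNNNACGT")
        pair = extract_flanks(asm, asm.gaps[0], flank_len=4)
        assert (pair.left_seq, pair.right_seq) == ("ACGT", "ACGT")
        assert not pair.left_truncated and not pair.right_truncated

    def test_truncated_near_sequence_start(self, rng):
        seq = random_seq(rng, 100) + "N" * 10 + random_seq(rng, 2000)
        asm = make_assembly(seq)
        pair = extract_flanks(asm, asm.gaps[0], flank_len=1500)
        assert len(pair.left_seq) == 100 and pair.left_truncated
        assert len(pair.right_seq) == 1500 and not pair.right_truncated

    def test_flank_limited_by_adjacent_gap(self, rng):
        seq = (random_seq(rng, 500) + "N" * 20 + random_seq(rng, 200)
               + "N" * 30 + random_seq(rng, 500))
        asm = make_assembly(seq)
        left_of_second = extract_flanks(asm, asm.gaps[1], flank_len=1500)
        assert len(left_of_second.left_seq) == 200
        assert "N" not in left_of_second.left_seq

    def test_terminal_gap_flagged(self):
        asm = make_assembly("NNNNACGTACGT")
        pair = extract_flanks(asm, asm.gaps[0], flank_len=4)
        assert pair.terminal


class TestCloseGaps:
    @pytest.fixture()
    def planted(self, rng):
        """One gap whose 60-bp true fill sits inside a single filler."""
        left = random_seq(rng, 150)
        fill = random_seq(rng, 60)
        right = random_seq(rng, 150)
        truth = left + fill + right
        gapped = left + "N" * 60 + right
        filler = SequenceRecord("f1", random_seq(rng, 40) + truth + random_seq(rng, 40))
        return truth, make_assembly(gapped), filler

    def test_true_fill_recovered(self, planted):
        truth, asm, filler = planted
        patched, events, _ = close_gaps(asm, [("pool", [filler])],
                                        SMALL_RULES, k=11)
        assert events[0].status == "closed"
        assert events[0].patch_seq == truth[150:210]
        assert patched.seq == truth

    def test_reverse_complement_filler_also_closes(self, planted):
        truth, asm, filler = planted
        rc = SequenceRecord("f1rc", revcomp(filler.seq))
        patched, events, _ = close_gaps(asm, [("pool", [rc])], SMALL_RULES, k=11)
        assert events[0].status == "closed" and events[0].strand == "-"
        assert patched.seq == truth

    def test_flanks_on_different_fillers_not_closed(self, rng):
        left = random_seq(rng, 150)
        right = random_seq(rng, 150)
        asm = make_assembly(left + "N" * 50 + right)
        fa = SequenceRecord("fa", random_seq(rng, 30) + left + random_seq(rng, 30))
        fb = SequenceRecord("fb", random_seq(rng, 30) + right + random_seq(rng, 30))
        _, events, _ = close_gaps(asm, [("pool", [fa, fb])], SMALL_RULES, k=11)
        assert events[0].status == "unclosed"
        assert "no common filler" in events[0].reject_reason

    def test_inverted_flank_order_rejected(self, rng):
        left = random_seq(rng, 150)
        right = random_seq(rng, 150)
        asm = make_assembly(left + "N" * 50 + right)
        # filler carries right-flank sequence BEFORE left-flank sequence
        filler = SequenceRecord("f", right + random_seq(rng, 20) + left)
        _, events, _ = close_gaps(asm, [("pool", [filler])], SMALL_RULES, k=11)
        assert events[0].status == "unclosed"
        assert "order/strand" in events[0].reject_reason

    def test_terminal_gap_never_closed(self, rng):
        seq = "N" * 30 + random_seq(rng, 300)
        asm = make_assembly(seq)
        filler = SequenceRecord("f", seq.replace("N", "A"))
        _, events, _ = close_gaps(asm, [("pool", [filler])], SMALL_RULES, k=11)
        assert events[0].status == "unclosed"
        assert events[0].reject_reason == "terminal"

    def test_zero_closures_leaves_sequence_unchanged(self, rng):
        asm = make_assembly(random_seq(rng, 200) + "N" * 40 + random_seq(rng, 200))
        decoy = SequenceRecord("d", random_seq(rng, 400))
        patched, events, lift = close_gaps(asm, [("pool", [decoy])],
                                           SMALL_RULES, k=11)
        assert patched.seq == asm.record.seq
        assert all(e.status == "unclosed" for e in events)
        assert lift(10) == 10

    def test_monotone_in_pools(self, tiny_ancestor, tiny_fragmented):
        rules = ClosureRules()
        asm = tiny_fragmented.assembly
        pools = tiny_fragmented.pools
        _, events_one, _ = close_gaps(asm, pools[:1], rules)
        _, events_all, _ = close_gaps(asm, pools, rules)
        n_one = sum(e.status == "closed" for e in events_one)
        n_all = sum(e.status == "closed" for e in events_all)
        assert n_all >= n_one

    def test_liftover_and_length_arithmetic(self, tiny_ancestor, tiny_fragmented,
                                            rng):
        asm = tiny_fragmented.assembly
        patched, events, lift = close_gaps(asm, tiny_fragmented.pools,
                                           ClosureRules())
        closed = [e for e in events if e.status == "closed"]
        assert closed
        expected = (len(asm.record.seq)
                    - sum(e.gap.length for e in closed)
                    + sum(len(e.patch_seq) for e in closed))
        assert len(patched.seq) == expected
        # positional spot-check: any original non-gap position keeps its base
        gap_set = set()
        for g in asm.gaps:
            gap_set.update(range(g.start, g.end))
        positions = rng.integers(0, len(asm.record.seq), size=500)
        for pos in positions:
            pos = int(pos)
            if pos in gap_set:
                continue
            assert patched.seq[lift(pos)] == asm.record.seq[pos]


class TestSummaries:
    @pytest.mark.parametrize("total,count,mean", [
        (3_491_264, 8_043, 434),
        (28_986, 33, 878),
        (5_798_173, 12_825, 452),
        (0, 0, 0),
    ])
    def test_published_accounting_means(self, total, count, mean):
        assert mean_gap_length(total, count) == mean

    def test_empty_event_list(self):
        table = summarize_closures([])
        assert list(table.source) == ["Total"]
        assert table.iloc[0].n_closed == 0 and table.iloc[0].mean_gap_length == 0

    def test_per_source_accounting_uses_original_gap_length(self):
        gap1 = GapRecord("c", 10, 110)   # 100 bp
        gap2 = GapRecord("c", 500, 800)  # 300 bp
        events = [
            ClosureEvent(gap1, "closed", "poolA", "f1", "A" * 90, "+"),
            ClosureEvent(gap2, "closed", "poolA", "f2", "C" * 310, "+"),
            ClosureEvent(GapRecord("c", 900, 950), "unclosed",
                         reject_reason="single-flank"),
        ]
        table = summarize_closures(events).set_index("source")
        assert table.loc["poolA", "n_closed"] == 2
        assert table.loc["poolA", "gap_length_bp"] == 400
        assert table.loc["poolA", "mean_gap_length"] == 200
        assert table.loc["poolA", "patch_length_bp"] == 400
        assert table.loc["Total", "n_closed"] == 2

    def test_event_invariants(self):
        gap = GapRecord("c", 0, 5)
        with pytest.raises(ValueError):
            ClosureEvent(gap, "closed", "p", "f", "ANA", "+")
        with pytest.raises(ValueError):
            ClosureEvent(gap, "unclosed", patch_seq="ACGT")


def test_apply_patches_conserves_flanking_sequence(rng):
    seq = random_seq(rng, 300) + "N" * 50 + random_seq(rng, 300)
    rec = SequenceRecord("c", seq)
    gap = scan_gaps(rec)[0]
    ev = ClosureEvent(gap, "closed", "p", "f", "G" * 70, "+")
    patched, lift = apply_patches(rec, [ev])
    assert patched.seq == seq[:300] + "G" * 70 + seq[350:]
    assert lift(0) == 0 and lift(350) == 370
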