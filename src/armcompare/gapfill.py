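"""N-gap closure from filler-sequence pools.

For every catalogued N-gap, up to 1500 bp of clean flank is cut on each
side and aligned against ordered filler pools (unplaced contigs,
individual BAC assemblies, long reads...).  A gap closes when one filler
carries both flanks on one strand, in the right order, with the
alignments anchored at the gap-adjacent flank ends; the patch is the
filler subsequence between the two inner alignment boundaries.  Pools
are tried in priority order and a gap closed by an earlier pool is never
re-attempted, so the per-source accounting is disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .aligner import AlignmentHit, KmerIndex, local_align, revcomp
from .genome_io import GapRecord, GappedAssembly, SequenceRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClosureRules:
    """Declared decision thresholds (none are stated by e-PCR style tools)."""

    flank_len: int = 1500
    anchor_tol: int = 10          # bp slack at the gap-adjacent flank end
    max_flank_overlap: int = 200  # most negative implied patch length
    max_patch: int = 20_000
    min_hit_identity: float = 0.95
    min_hit_len: int = 200        # aligned columns


@dataclass(frozen=True)
class FlankPair:
    gap: GapRecord
    left_seq: str
    right_seq: str
    flank_len_requested: int
    left_truncated: bool
    right_truncated: bool

    @property
    def terminal(self) -> bool:
        return not self.left_seq or not self.right_seq


@dataclass
class ClosureEvent:
    gap: GapRecord
    status: str                       # closed | merged_overlap | unclosed
    source_label: str = ""
    filler_id: str = ""
    patch_seq: str = ""
    strand: str = ""
    overlap_trim: int = 0
    reject_reason: str = ""

    def __post_init__(self) -> None:
        if self.status == "closed" and "N" in self.patch_seq:
            raise ValueError("closed patch contains N")
        if self.status == "unclosed" and self.patch_seq:
            raise ValueError("unclosed event carries a patch")


def extract_flanks(assembly: GappedAssembly, gap: GapRecord,
                   flank_len: int = 1500) -> FlankPair:
    """Cut the N-free flanks of ``gap``.

    Flanks are truncated at the sequence ends and at the nearest
    neighbouring gap, so they never contain N.  A missing flank marks
    the gap terminal; terminal gaps are later reported unclosed.
    """
    seq = assembly.record.seq
    left_bound, right_bound = 0, len(seq)
    for other in assembly.gaps:
        if other.end <= gap.start:
            left_bound = max(left_bound, other.end)
        if other.start >= gap.end:
            right_bound = min(right_bound, other.start)
    left_start = max(left_bound, gap.start - flank_len)
    right_end = min(right_bound, gap.end + flank_len)
    left = seq[left_start:gap.start]
    right = seq[gap.end:right_end]
    return FlankPair(
        gap, left, right, flank_len,
        left_truncated=len(left) < flank_len,
        right_truncated=len(right) < flank_len,
    )


def _oriented(hit: AlignmentHit, filler_len: int) -> tuple[int, int, int, int]:
    """Hit coordinates in the strand-oriented filler frame.

    For minus-strand hits the filler is conceptually reverse-complemented
    so the query always runs forward; returns (q_start, q_end, t_start,
    t_end) in that frame.
    """
    if hit.strand == "+":
        return hit.q_start, hit.q_end, hit.t_start, hit.t_end
    return hit.q_start, hit.q_end, filler_len - hit.t_end, filler_len - hit.t_start


def propose_closure(flanks: FlankPair,
                    left_hits: Sequence[AlignmentHit],
                    right_hits: Sequence[AlignmentHit],
                    rules: ClosureRules,
                    fillers: dict[str, str],
                    source_label: str = "") -> ClosureEvent:
    """Decide one gap against one pool's flank hits.

    Acceptance needs one filler and strand carrying both flanks with the
    gap-adjacent alignment ends within ``anchor_tol`` of the flank ends,
    correct mutual order, and an implied patch length within
    [-max_flank_overlap, max_patch]; a negative implied length reports a
    flank overlap (``merged_overlap``) with an empty patch.  Competing
    fillers are ranked by summed hit score, ties by filler id.
    """
    if flanks.terminal:
        return ClosureEvent(flanks.gap, "unclosed", reject_reason="terminal")

    def usable(hits):
        return [h for h in hits
                if h.identity >= rules.min_hit_identity
                and h.aligned_columns >= rules.min_hit_len]

    lh, rh = usable(left_hits), usable(right_hits)
    if not lh or not rh:
        return ClosureEvent(flanks.gap, "unclosed", reject_reason="single-flank")

    left_by = {}
    for h in lh:
        left_by.setdefault((h.target_id, h.strand), []).append(h)
    right_by = {}
    for h in rh:
        right_by.setdefault((h.target_id, h.strand), []).append(h)
    common = sorted(set(left_by) & set(right_by))
    if not common:
        if set(h.target_id for h in lh) & set(h.target_id for h in rh):
            return ClosureEvent(flanks.gap, "unclosed", reject_reason="order/strand")
        return ClosureEvent(flanks.gap, "unclosed", reject_reason="no common filler")

    llen, rlen = len(flanks.left_seq), len(flanks.right_seq)
    best = None
    reasons = set()
    for fid, strand in common:
        flen = len(fillers[fid])
        for hl in left_by[(fid, strand)]:
            for hr in right_by[(fid, strand)]:
                ql0, ql1, tl0, tl1 = _oriented(hl, flen)
                qr0, qr1, tr0, tr1 = _oriented(hr, flen)
                # anchoring at the gap-adjacent flank ends
                if llen - ql1 > rules.anchor_tol or qr0 > rules.anchor_tol:
                    reasons.add("anchor")
                    continue
                inner_left = tl1 + (llen - ql1)
                inner_right = tr0 - qr0
                patch_len = inner_right - inner_left
                if patch_len < -rules.max_flank_overlap:
                    reasons.add("order/strand")
                    continue
                if patch_len > rules.max_patch:
                    reasons.add("patch too long")
                    continue
                key = (hl.score + hr.score, fid)
                if best is None or (key[0], ) > (best[0][0], ) or (
                        key[0] == best[0][0] and key[1] < best[0][1]):
                    best = (key, fid, strand, inner_left, inner_right, patch_len)
    if best is None:
        reason = ",".join(sorted(reasons)) or "order/strand"
        return ClosureEvent(flanks.gap, "unclosed", reject_reason=reason)

    _, fid, strand, inner_left, inner_right, patch_len = best
    oriented_filler = fillers[fid] if strand == "+" else revcomp(fillers[fid])
    if patch_len < 0:
        return ClosureEvent(flanks.gap, "merged_overlap", source_label, fid,
                            "", strand, overlap_trim=-patch_len)
    patch = oriented_filler[inner_left:inner_right]
    if "N" in patch:
        return ClosureEvent(flanks.gap, "unclosed", reject_reason="patch contains N")
    return ClosureEvent(flanks.gap, "closed", source_label, fid, patch, strand)


class Liftover:
    """Original -> patched coordinate map.

    Positions inside replaced intervals (the N run itself, plus any
    overlap-trimmed duplicate bases) have no image and are clamped to
    the patched coordinate of the preceding kept base.
    """

    def __init__(self, segments: list[tuple[int, int, int]], new_length: int):
        # segments: (orig_start, orig_end, offset) for kept intervals
        self.segments = segments
        self.new_length = new_length

    def __call__(self, pos: int) -> int:
        last = 0
        for s, e, off in self.segments:
            if s <= pos < e:
                return pos + off
            if e <= pos:
                last = e - 1 + off
        return last

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.segments,
                            columns=["orig_start", "orig_end", "offset"])


def close_gaps(assembly: GappedAssembly,
               pools: Sequence[tuple[str, Sequence[SequenceRecord]]],
               rules: ClosureRules = ClosureRules(),
               k: int = 15, max_occ: int = 100,
               ) -> tuple[SequenceRecord, list[ClosureEvent], Liftover]:
    """Close every gap of ``assembly`` against priority-ordered pools.

    Returns the patched sequence, one event per gap, and the coordinate
    liftover.  Patches are applied right-to-left so stored coordinates
    remain valid while editing.
    """
    indexes = []
    filler_maps = []
    for label, recs in pools:
        indexes.append((label, KmerIndex(list(recs), k=k, max_occ=max_occ)))
        filler_maps.append({r.id: r.seq for r in recs})

    events: list[ClosureEvent] = []
    for gap in assembly.gaps:
        flanks = extract_flanks(assembly, gap, rules.flank_len)
        if flanks.terminal:
            events.append(ClosureEvent(gap, "unclosed", reject_reason="terminal"))
            continue
        event = None
        pool_reasons = []
        for (label, index), fillers in zip(indexes, filler_maps):
            if min(len(flanks.left_seq), len(flanks.right_seq)) < index.k:
                pool_reasons.append("flank too short")
                continue
            lrec = SequenceRecord(f"{gap.seq_id}_{gap.start}_L", flanks.left_seq)
            rrec = SequenceRecord(f"{gap.seq_id}_{gap.start}_R", flanks.right_seq)
            lh = local_align(lrec, index, min_identity=rules.min_hit_identity,
                             min_len=min(rules.min_hit_len, len(flanks.left_seq)))
            rh = local_align(rrec, index, min_identity=rules.min_hit_identity,
                             min_len=min(rules.min_hit_len, len(flanks.right_seq)))
            cand = propose_closure(flanks, lh, rh, rules, fillers, label)
            if cand.status != "unclosed":
                event = cand
                break
            pool_reasons.append(cand.reject_reason)
        if event is None:
            reason = ";".join(dict.fromkeys(pool_reasons)) or "no pools"
            event = ClosureEvent(gap, "unclosed", reject_reason=reason)
        events.append(event)

    patched, liftover = apply_patches(assembly.record, events)
    return patched, events, liftover


def apply_patches(record: SequenceRecord, events: Sequence[ClosureEvent]
                  ) -> tuple[SequenceRecord, Liftover]:
    """Apply closure events right-to-left and build the liftover map."""
    edits = []  # (orig_start, orig_end_replaced, replacement)
    for ev in events:
        if ev.status == "closed":
            edits.append((ev.gap.start, ev.gap.end, ev.patch_seq))
        elif ev.status == "merged_overlap":
            edits.append((ev.gap.start, ev.gap.end + ev.overlap_trim, ""))
    edits.sort()

    pieces = []
    segments = []
    cursor = 0
    offset = 0
    seq = record.seq
    for s, e, repl in edits:
        pieces.append(seq[cursor:s])
        if s > cursor:
            segments.append((cursor, s, offset))
        pieces.append(repl)
        offset += len(repl) - (e - s)
        cursor = e
    pieces.append(seq[cursor:])
    if len(seq) > cursor:
        segments.append((cursor, len(seq), offset))
    new_seq = "".join(pieces)
    return SequenceRecord(record.id, new_seq), Liftover(segments, len(new_seq))


def _round_half_away(x: float) -> int:
    import math
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def mean_gap_length(total: int, count: int) -> int:
    """Average gap length as printed in closure accounting tables."""
    if count == 0:
        return 0
    return _round_half_away(total / count)


def summarize_closures(events: Iterable[ClosureEvent]) -> pd.DataFrame:
    """Per-source closure table (count, total gap bp, mean, patch bp) + Total.

    Lengths count the ORIGINAL N-run replaced, so rows are comparable to
    the gap census; realized patch length is an extra column.
    """
    rows: dict[str, dict] = {}
    for ev in events:
        if ev.status not in ("closed", "merged_overlap"):
            continue
        r = rows.setdefault(ev.source_label, {"count": 0, "gap_bp": 0, "patch_bp": 0})
        r["count"] += 1
        r["gap_bp"] += ev.gap.length
        r["patch_bp"] += len(ev.patch_seq)
    out = []
    for label, r in rows.items():
        out.append({"source": label, "n_closed": r["count"],
                    "gap_length_bp": r["gap_bp"],
                    "mean_gap_length": mean_gap_length(r["gap_bp"], r["count"]),
                    "patch_length_bp": r["patch_bp"]})
    total = {"source": "Total",
             "n_closed": sum(r["count"] for r in rows.values()),
             "gap_length_bp": sum(r["gap_bp"] for r in rows.values()),
             "patch_length_bp": sum(r["patch_bp"] for r in rows.values())}
    total["mean_gap_length"] = mean_gap_length(total["gap_length_bp"],
                                               total["n_closed"])
    out.append(total)
    return pd.DataFrame(out, columns=["source", "n_closed", "gap_length_bp",
                                      "mean_gap_length", "patch_length_bp"])


def write_closure_report(events: Iterable[ClosureEvent], path: str | Path) -> None:
    rows = [{
        "seq_id": ev.gap.seq_id, "gap_start": ev.gap.start, "gap_end": ev.gap.end,
        "gap_len": ev.gap.length, "status": ev.status, "source": ev.source_label,
        "filler": ev.filler_id, "strand": ev.strand,
        "patch_len": len(ev.patch_seq), "reason": ev.reject_reason,
    } for ev in events]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
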