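"""Seed-and-extend local nucleotide aligner.

A deliberately small BLAT-like aligner used by gap closure, orthology and
marker placement: a k-mer index over the target set, diagonal clustering
of seed matches, and a local dynamic-programming extension around each
cluster.  Scoring is match +1, mismatch -1, gap open -2 and each further
gapped base -1 (a gap of length L costs 2 + (L - 1)).  Hits on the minus
strand are found by reverse-complementing the query; reported coordinates
always refer to the forward strands of query and target.

The extension recovers the single best local alignment per seed cluster
(flank placement needs one best anchor, not an HSP enumeration), and
overlapping hits on the same (target, strand) within 10 bp are collapsed
keeping the higher score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome_io import SequenceRecord

log = logging.getLogger(__name__)

MATCH = 1
MISMATCH = -1
GAP_OPEN = 2      # cost of the first base of a gap
GAP_EXTEND = 1    # cost of each additional gapped base
X_DROP = 20       # retained for API compatibility; extension is window-bounded

_NEG = np.int32(-(10 ** 8))

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Map a sequence string to uint8 codes A=0 C=1 G=2 T=3 N=4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    matches: int
    mismatches: int
    gap_opens: int
    aligned_columns: int
    identity: float
    score: int

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.t_start < self.t_end):
            raise ValueError("degenerate hit interval")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity out of range")


def _kmer_codes(u: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (codes, valid positions) for every N-free k-mer window."""
    n = len(u) - k + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    v = u.astype(np.int64)
    c = np.zeros(n, np.int64)
    for j in range(k):
        c = (c << 2) | (v[j:j + n] & 3)
    is_n = np.concatenate(([0], np.cumsum(u == 4)))
    valid = (is_n[k:] - is_n[:-k]) == 0
    pos = np.nonzero(valid)[0]
    return c[pos], pos


class KmerIndex:
    """Sorted k-mer -> (target, position) index with a repeat-seed cap.

    Seeds occurring more than ``max_occ`` times across the whole target
    set are dropped: a deterministic, dependency-free surrogate for
    soft-masking repeats.
    """

    def __init__(self, targets: Sequence[SequenceRecord], k: int = 15,
                 max_occ: int = 100):
        if not 8 <= k <= 31:
            raise ValueError(f"k={k} outside [8, 31]")
        self.k = k
        self.max_occ = max_occ
        self.names = [t.id for t in targets]
        self.seqs = [t.seq for t in targets]
        self.encoded = [encode(t.seq) for t in targets]

        codes_all, tidx_all, tpos_all = [], [], []
        for ti, u in enumerate(self.encoded):
            codes, pos = _kmer_codes(u, k)
            codes_all.append(codes)
            tpos_all.append(pos)
            tidx_all.append(np.full(len(pos), ti, np.int32))
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, np.int64)
        tidx = np.concatenate(tidx_all) if tidx_all else np.empty(0, np.int32)
        tpos = np.concatenate(tpos_all) if tpos_all else np.empty(0, np.int64)

        order = np.argsort(codes, kind="stable")
        codes, tidx, tpos = codes[order], tidx[order], tpos[order]
        if len(codes):
            # drop over-frequent seeds
            uniq, starts, counts = np.unique(codes, return_index=True,
                                             return_counts=True)
            keep_runs = counts <= max_occ
            keep = np.zeros(len(codes), bool)
            for s, c in zip(starts[keep_runs], counts[keep_runs]):
                keep[s:s + c] = True
            n_dropped = int((~keep_runs).sum())
            if n_dropped:
                log.debug("k-mer index: %d over-frequent seeds dropped", n_dropped)
            codes, tidx, tpos = codes[keep], tidx[keep], tpos[keep]
        self._codes, self._tidx, self._tpos = codes, tidx, tpos

    def occurrences(self, kmer: str) -> int:
        """Number of indexed positions of one k-mer (0 if capped out)."""
        if len(kmer) != self.k:
            raise ValueError("kmer length != k")
        code, pos = _kmer_codes(encode(kmer), self.k)
        if len(code) == 0:
            return 0
        lo = np.searchsorted(self._codes, code[0], "left")
        hi = np.searchsorted(self._codes, code[0], "right")
        return int(hi - lo)

    def lookup(self, qcodes: np.ndarray, qpos: np.ndarray):
        """Vectorized seed lookup: arrays (query pos, target idx, target pos)."""
        if len(qcodes) == 0 or len(self._codes) == 0:
            e = np.empty(0, np.int64)
            return e, e.astype(np.int32), e
        lo = np.searchsorted(self._codes, qcodes, "left")
        hi = np.searchsorted(self._codes, qcodes, "right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            e = np.empty(0, np.int64)
            return e, e.astype(np.int32), e
        qrep = np.repeat(qpos, counts)
        idx = np.concatenate([np.arange(l, h) for l, h in zip(lo, hi) if h > l])
        return qrep, self._tidx[idx], self._tpos[idx]


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _njit = None

if _njit is not None:
    @_njit(cache=True)
    def _dp_kernel(qu, tu, H, match, mismatch, gap_open, gap_extend):  # pragma: no cover
        n = qu.shape[0]
        m = tu.shape[0]
        neg = -(10 ** 8)
        F = np.full(m + 1, neg, np.int32)
        for i in range(1, n + 1):
            qb = qu[i - 1]
            e = neg
            for j in range(1, m + 1):
                f = H[i - 1, j] - gap_open
                f2 = F[j] - gap_extend
                if f2 > f:
                    f = f2
                F[j] = f
                e -= gap_extend
                e1 = H[i, j - 1] - gap_open
                if e1 > e:
                    e = e1
                tb = tu[j - 1]
                if qb == tb and qb != 4:
                    h = H[i - 1, j - 1] + match
                else:
                    h = H[i - 1, j - 1] + mismatch
                if f > h:
                    h = f
                if e > h:
                    h = e
                if h < 0:
                    h = 0
                H[i, j] = h


def _local_dp_matrix(qu: np.ndarray, tu: np.ndarray) -> np.ndarray:
    """Full Smith–Waterman (Gotoh) matrix with the package scoring scheme.

    Uses a compiled scalar kernel when numba is available; otherwise a
    row-parallel numpy formulation where vertical gaps follow the Gotoh
    recurrence over the previous row and horizontal gaps are resolved by
    a running-maximum scan (valid because GAP_OPEN >= GAP_EXTEND, so a
    gap never profits from reopening inside another gap).
    """
    if _njit is not None:
        H = np.zeros((len(qu) + 1, len(tu) + 1), np.int32)
        _dp_kernel(qu, tu, H, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND)
        return H
    return _local_dp_matrix_numpy(qu, tu)


def _local_dp_matrix_numpy(qu: np.ndarray, tu: np.ndarray) -> np.ndarray:
    n, m = len(qu), len(tu)
    H = np.zeros((n + 1, m + 1), np.int32)
    F = np.full(m + 1, _NEG, np.int32)
    jj = np.arange(1, m + 1, dtype=np.int32)
    t_is_n = tu == 4
    for i in range(1, n + 1):
        qb = qu[i - 1]
        sub = np.where((tu == qb) & ~t_is_n & (qb != 4), MATCH, MISMATCH).astype(np.int32)
        F = np.maximum(H[i - 1] - GAP_OPEN, F - GAP_EXTEND)
        h0 = np.maximum(H[i - 1, :-1] + sub, F[1:])
        np.maximum(h0, 0, out=h0)
        g = h0 + jj * GAP_EXTEND
        run = np.maximum.accumulate(g)
        e = np.full(m, _NEG, np.int32)
        if m > 1:
            e[1:] = run[:-1] - GAP_OPEN - (jj[1:] - 1) * GAP_EXTEND
        H[i, 1:] = np.maximum(h0, e)
    return H


def _gap_cost(length: int) -> int:
    return GAP_OPEN + (length - 1) * GAP_EXTEND


def _traceback(H: np.ndarray, qu: np.ndarray, tu: np.ndarray,
               i: int, j: int):
    """Walk back from cell (i, j); return interval + column statistics."""
    matches = mismatches = gap_opens = gap_bases = 0
    while H[i, j] > 0:
        v = int(H[i, j])
        qb, tb = qu[i - 1], tu[j - 1]
        s = MATCH if (qb == tb and qb != 4 and tb != 4) else MISMATCH
        if v == H[i - 1, j - 1] + s:
            if s == MATCH:
                matches += 1
            else:
                mismatches += 1
            i, j = i - 1, j - 1
            continue
        stepped = False
        for L in range(1, i + 1):  # vertical gap (consumes query)
            if v == H[i - L, j] - _gap_cost(L):
                gap_opens += 1
                gap_bases += L
                i -= L
                stepped = True
                break
            if H[i - L, j] - _gap_cost(L) > v:
                break
        if stepped:
            continue
        for L in range(1, j + 1):  # horizontal gap (consumes target)
            if v == H[i, j - L] - _gap_cost(L):
                gap_opens += 1
                gap_bases += L
                j -= L
                stepped = True
                break
        if not stepped:  # pragma: no cover - recurrence is exact on ints
            raise AssertionError("traceback failed")
    columns = matches + mismatches + gap_bases
    return i, j, matches, mismatches, gap_opens, columns


def _cluster_seeds(qpos, tidx, tpos, band: int):
    """Group seed matches by target and diagonal band."""
    diag = tpos - qpos
    order = np.lexsort((qpos, diag, tidx))
    qpos, tidx, tpos, diag = qpos[order], tidx[order], tpos[order], diag[order]
    clusters = []
    start = 0
    for i in range(1, len(qpos) + 1):
        if (i == len(qpos) or tidx[i] != tidx[start]
                or diag[i] - diag[i - 1] > band):
            sl = slice(start, i)
            clusters.append({
                "tidx": int(tidx[start]),
                "n_seeds": int(len(np.unique(qpos[sl]))),
                "dmin": int(diag[sl].min()),
                "dmax": int(diag[sl].max()),
            })
            start = i
    return clusters


def local_align(query: SequenceRecord, index: KmerIndex,
                min_identity: float = 0.90, min_len: int = 50,
                band: int = 48, max_candidates: int = 20,
                seed_prune_ratio: float = 0.1) -> list[AlignmentHit]:
    """Local alignment of ``query`` against every indexed target.

    Both strands are searched (the query is reverse-complemented for the
    minus strand); hits shorter than ``min_len`` aligned columns or below
    ``min_identity`` are suppressed.  Hits are sorted by score descending,
    ties by (target_id, t_start).  Seed clusters supporting fewer than
    ``seed_prune_ratio`` times the best cluster's seeds are not extended
    (they cannot plausibly yield the best anchor).
    """
    if len(query.seq) < index.k:
        raise ValueError("query shorter than index k")
    qlen = len(query.seq)
    raw_hits: dict[tuple, AlignmentHit] = {}

    candidates = []
    encoded_q = {}
    for strand in ("+", "-"):
        qseq = query.seq if strand == "+" else revcomp(query.seq)
        qu = encode(qseq)
        encoded_q[strand] = qu
        qcodes, qp = _kmer_codes(qu, index.k)
        qpos, tidx, tpos = index.lookup(qcodes, qp)
        if len(qpos) == 0:
            continue
        for cl in _cluster_seeds(qpos, tidx, tpos, band):
            candidates.append((strand, cl))
    if candidates:
        candidates.sort(key=lambda sc: (-sc[1]["n_seeds"], sc[0],
                                        sc[1]["tidx"], sc[1]["dmin"]))
        top_seeds = candidates[0][1]["n_seeds"]
        candidates = [sc for sc in candidates
                      if sc[1]["n_seeds"] >= seed_prune_ratio * top_seeds]
        for strand, cl in candidates[:max_candidates]:
            qu = encoded_q[strand]
            tu_full = index.encoded[cl["tidx"]]
            t_lo = max(0, cl["dmin"] - band)
            t_hi = min(len(tu_full), cl["dmax"] + qlen + band)
            tu = tu_full[t_lo:t_hi]
            if len(tu) == 0:
                continue
            H = _local_dp_matrix(qu, tu)
            best = int(H.max())
            if best <= 0:
                continue
            i, j = np.unravel_index(int(H.argmax()), H.shape)
            qi, tj, matches, mismatches, gap_opens, columns = _traceback(
                H, qu, tu, int(i), int(j))
            if columns == 0:
                continue
            q_start, q_end = qi, int(i)
            if strand == "-":
                q_start, q_end = qlen - int(i), qlen - qi
            hit = AlignmentHit(
                query_id=query.id,
                target_id=index.names[cl["tidx"]],
                q_start=q_start, q_end=q_end,
                t_start=t_lo + tj, t_end=t_lo + int(j),
                strand=strand,
                matches=matches, mismatches=mismatches,
                gap_opens=gap_opens, aligned_columns=columns,
                identity=matches / columns, score=best,
            )
            key = (hit.target_id, hit.strand, hit.t_start, hit.t_end,
                   hit.q_start, hit.q_end)
            if key not in raw_hits or raw_hits[key].score < hit.score:
                raw_hits[key] = hit

    hits = [h for h in raw_hits.values()
            if h.identity >= min_identity and h.aligned_columns >= min_len]
    hits.sort(key=lambda h: (-h.score, h.target_id, h.t_start))

    # merge overlapping/nearby hits on the same (target, strand): keep best
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = any(
            k.target_id == h.target_id and k.strand == h.strand
            and h.t_start <= k.t_end + 10 and k.t_start <= h.t_end + 10
            for k in kept
        )
        if not redundant:
            kept.append(h)
    return kept


def write_hit_table(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """12-column tab-separated hit dump (common pairwise-hit layout)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(str(x) for x in (
                h.query_id, h.target_id, f"{100 * h.identity:.2f}",
                h.aligned_columns, h.mismatches, h.gap_opens,
                h.q_start, h.q_end, h.t_start, h.t_end, h.score, h.strand,
            )) + "\n")
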