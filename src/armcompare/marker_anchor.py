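"""Electronic-PCR marker placement, QTL anchoring and gene/QTL linking.

A primer-pair marker places where the forward primer matches one strand
(with at most ``max_mismatch`` mismatches and an exact 3'-terminal
stretch, where extension starts) and the reverse primer's reverse
complement matches downstream on the same molecule; the predicted
product spans both primers.  QTL intervals are the span of their placed
flanking markers, and genes are linked to a QTL when they fall within
the anchored interval expanded by a configurable window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .aligner import encode, revcomp
from .genome_io import SequenceRecord

log = logging.getLogger(__name__)

DEFAULT_MAX_PRODUCT = 10_000
DEFAULT_LINK_WINDOW = 3_000_000   # "closely linked" span used for gene/QTL reports
DEFAULT_POINT_RADIUS = 1_000_000  # half-width given to single-marker QTLs


@dataclass(frozen=True)
class MarkerHit:
    marker_id: str
    seq_id: str
    product_start: int
    product_end: int
    strand: str            # strand carrying the forward primer
    mismatches_fwd: int
    mismatches_rev: int

    @property
    def product_len(self) -> int:
        return self.product_end - self.product_start

    @property
    def midpoint(self) -> int:
        return (self.product_start + self.product_end) // 2


@dataclass(frozen=True)
class QTLAnchor:
    qtl_id: str
    trait: str
    seq_id: str
    start: int
    end: int
    n_markers: int
    anchored: bool


def _scan_primer(genome_u8: np.ndarray, primer: str, max_mismatch: int,
                 exact_prefix: int = 0, exact_suffix: int = 0,
                 chunk: int = 2_000_000) -> tuple[np.ndarray, np.ndarray]:
    """Positions (and mismatch counts) where ``primer`` matches the + strand."""
    p = encode(primer)
    L = len(p)
    n = len(genome_u8) - L + 1
    if n <= 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    pos_out, mm_out = [], []
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        win = sliding_window_view(genome_u8[lo:hi + L - 1], L)
        neq = win != p          # N in the genome never matches a primer base
        mm = neq.sum(axis=1)
        ok = mm <= max_mismatch
        if exact_suffix:
            ok &= ~neq[:, L - exact_suffix:].any(axis=1)
        if exact_prefix:
            ok &= ~neq[:, :exact_prefix].any(axis=1)
        idx = np.nonzero(ok)[0]
        pos_out.append(idx + lo)
        mm_out.append(mm[idx])
    return np.concatenate(pos_out), np.concatenate(mm_out)


def epcr_place(primer_fwd: str, primer_rev: str, genome: SequenceRecord,
               marker_id: str = "?", max_mismatch: int = 1,
               three_prime_exact: int = 3,
               size_window: Optional[tuple[int, int]] = None,
               max_product: int = DEFAULT_MAX_PRODUCT,
               _genome_u8: Optional[np.ndarray] = None) -> list[MarkerHit]:
    """All valid in-silico amplicons of one primer pair, sorted by position.

    Both mutual orientations are searched; the 3'-terminal
    ``three_prime_exact`` bases of each primer must match exactly.  The
    product length must fall inside ``size_window`` when given, and is
    capped at ``max_product`` regardless.
    """
    if min(len(primer_fwd), len(primer_rev)) < 15:
        raise ValueError("primers must be >= 15 bp")
    g = _genome_u8 if _genome_u8 is not None else encode(genome.seq)
    if size_window is not None:
        max_product = min(max_product, size_window[1])

    hits: list[MarkerHit] = []
    l1, l2 = len(primer_fwd), len(primer_rev)
    for strand in ("+", "-"):
        if strand == "+":
            left, right = primer_fwd, revcomp(primer_rev)
            # fwd 3' end is its right end; rev 3' end faces inward (left end
            # of the reverse-complement match)
            lpos, lmm = _scan_primer(g, left, max_mismatch,
                                     exact_suffix=three_prime_exact)
            rpos, rmm = _scan_primer(g, right, max_mismatch,
                                     exact_prefix=three_prime_exact)
            llen, rlen = l1, l2
        else:
            left, right = primer_rev, revcomp(primer_fwd)
            lpos, lmm = _scan_primer(g, left, max_mismatch,
                                     exact_suffix=three_prime_exact)
            rpos, rmm = _scan_primer(g, right, max_mismatch,
                                     exact_prefix=three_prime_exact)
            llen, rlen = l2, l1
        if len(lpos) == 0 or len(rpos) == 0:
            continue
        for lp, lm in zip(lpos, lmm):
            lo = np.searchsorted(rpos, lp + llen)
            hi = np.searchsorted(rpos, lp + max_product - rlen, "right")
            for rp, rm in zip(rpos[lo:hi], rmm[lo:hi]):
                plen = int(rp) + rlen - int(lp)
                if size_window is not None and not (
                        size_window[0] <= plen <= size_window[1]):
                    continue
                mm_f, mm_r = (int(lm), int(rm)) if strand == "+" else (int(rm), int(lm))
                hits.append(MarkerHit(marker_id, genome.id, int(lp),
                                      int(rp) + rlen, strand, mm_f, mm_r))
    hits.sort(key=lambda h: (h.product_start, h.product_end, h.strand))
    return hits


def place_marker_table(markers: pd.DataFrame, genome: SequenceRecord,
                       max_mismatch: int = 1, three_prime_exact: int = 3,
                       size_tolerance: Optional[float] = None
                       ) -> dict[str, list[MarkerHit]]:
    """e-PCR the whole marker table; optional +/- fractional size window."""
    g = encode(genome.seq)
    out = {}
    for row in markers.itertuples(index=False):
        window = None
        expected = getattr(row, "expected_size", None)
        if size_tolerance is not None and expected and not pd.isna(expected):
            window = (int(expected * (1 - size_tolerance)),
                      int(expected * (1 + size_tolerance)))
        out[row.marker_id] = epcr_place(
            row.fwd_primer, row.rev_primer, genome, row.marker_id,
            max_mismatch=max_mismatch, three_prime_exact=three_prime_exact,
            size_window=window, _genome_u8=g)
    return out


def anchor_qtls(marker_hits: Mapping[str, Sequence[MarkerHit]],
                qtl_table: pd.DataFrame,
                point_radius: int = DEFAULT_POINT_RADIUS) -> list[QTLAnchor]:
    """Interval per QTL from the midpoints of its placed flanking markers.

    Single-marker QTLs get a point interval expanded by ``point_radius``;
    QTLs with no placed marker are reported unanchored.
    """
    anchors = []
    for row in qtl_table.itertuples(index=False):
        ids = [m.strip() for m in str(row.marker_ids).split(",") if m.strip()]
        if not ids:
            raise ValueError(f"QTL {row.qtl_id} lists no markers")
        mids = []
        seq_id = ""
        for mid in ids:
            for h in marker_hits.get(mid, ()):
                mids.append(h.midpoint)
                seq_id = h.seq_id
        if not mids:
            anchors.append(QTLAnchor(row.qtl_id, row.trait, "", 0, 0, 0, False))
            continue
        lo, hi = min(mids), max(mids)
        if lo == hi:
            lo, hi = max(0, lo - point_radius), hi + point_radius
        anchors.append(QTLAnchor(row.qtl_id, row.trait, seq_id, lo, hi,
                                 len(mids), True))
    return anchors


def link_genes_to_qtls(gene_positions: Mapping[str, tuple[int, int]],
                       anchors: Sequence[QTLAnchor],
                       window: int = DEFAULT_LINK_WINDOW) -> pd.DataFrame:
    """Genes whose midpoint falls in an anchor interval expanded by ``window``.

    Distance is 0 inside the unexpanded interval, else base pairs to the
    nearest interval edge.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    rows = []
    for gid, (s, e) in sorted(gene_positions.items()):
        mid = (s + e) // 2
        for a in anchors:
            if not a.anchored:
                continue
            if a.start - window <= mid <= a.end + window:
                if a.start <= mid <= a.end:
                    dist = 0
                else:
                    dist = min(abs(mid - a.start), abs(mid - a.end))
                rows.append({"gene_id": gid, "qtl_id": a.qtl_id,
                             "trait": a.trait, "distance": dist})
    return pd.DataFrame(rows, columns=["gene_id", "qtl_id", "trait", "distance"])
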