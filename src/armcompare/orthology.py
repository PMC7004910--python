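"""Reciprocal-best-hit orthology and the lost-gene classification cascade.

A donor-arm gene set (the diploid progenitor) is compared against the
corresponding polyploid arm: genes pair by reciprocal best hit (RBH) of
their coding sequences through the internal aligner.  Donor genes with
no RBH partner fall through a cascade — presence in the homoeologous
subgenome sets, presence anywhere else in the genome, otherwise lost —
so the four classes partition the donor set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import AlignmentHit, KmerIndex, local_align
from .synthetic_data import GeneModel

log = logging.getLogger(__name__)

CLASSES = ("ortholog_on_focal_arm", "homoeologue", "paralog_elsewhere", "lost")


@dataclass(frozen=True)
class OrthologyThresholds:
    min_identity: float = 0.70
    min_query_coverage: float = 0.50
    k: int = 12


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    score: int
    identity: float
    ambiguous: bool


@dataclass(frozen=True)
class LossRecord:
    gene_id: str
    classification: str
    evidence_hit: str = ""

    def __post_init__(self) -> None:
        if self.classification not in CLASSES:
            raise ValueError(f"unknown classification {self.classification}")


def _cds_record(g: GeneModel):
    from .genome_io import SequenceRecord
    return SequenceRecord(g.gene_id, g.cds)


def _best_hits(queries: Sequence[GeneModel], index: KmerIndex,
               thresholds: OrthologyThresholds
               ) -> dict[str, tuple[AlignmentHit | None, bool]]:
    """Per query: (best passing hit or None, tie-for-best flag)."""
    out: dict[str, tuple[AlignmentHit | None, bool]] = {}
    for g in queries:
        if len(g.cds) < index.k:
            out[g.gene_id] = (None, False)
            continue
        hits = local_align(_cds_record(g), index,
                           min_identity=thresholds.min_identity, min_len=index.k)
        passing = [h for h in hits
                   if (h.q_end - h.q_start) / len(g.cds) >= thresholds.min_query_coverage]
        if not passing:
            out[g.gene_id] = (None, False)
            continue
        best = passing[0]
        tie = any(h.score == best.score and h.target_id != best.target_id
                  for h in passing[1:])
        out[g.gene_id] = (best, tie)
    return out


def reciprocal_best_hits(set_a: Sequence[GeneModel], set_b: Sequence[GeneModel],
                         thresholds: OrthologyThresholds = OrthologyThresholds()
                         ) -> list[OrthologPair]:
    """Mutual best-scoring CDS matches between two gene sets.

    Identity/coverage thresholds apply before best-hit selection; a tie
    for best in either direction flags the pair ambiguous (ambiguous
    pairs are excluded from downstream selection scanning).
    """
    if not set_a or not set_b:
        return []
    index_b = KmerIndex([_cds_record(g) for g in set_b], k=thresholds.k)
    index_a = KmerIndex([_cds_record(g) for g in set_a], k=thresholds.k)
    fwd = _best_hits(set_a, index_b, thresholds)
    rev = _best_hits(set_b, index_a, thresholds)

    pairs = []
    for a, (hit_ab, tie_a) in fwd.items():
        if hit_ab is None:
            continue
        b = hit_ab.target_id
        hit_ba, tie_b = rev.get(b, (None, False))
        if hit_ba is None or hit_ba.target_id != a:
            continue
        pairs.append(OrthologPair(a, b, hit_ab.score, hit_ab.identity,
                                  ambiguous=tie_a or tie_b))
    pairs.sort(key=lambda p: p.gene_a)
    return pairs


def _has_presence_hit(gene: GeneModel, index: KmerIndex,
                      thresholds: OrthologyThresholds) -> AlignmentHit | None:
    """Any (non-reciprocal) hit passing the thresholds."""
    if len(gene.cds) < index.k:
        return None
    hits = local_align(_cds_record(gene), index,
                       min_identity=thresholds.min_identity, min_len=index.k)
    for h in hits:
        if (h.q_end - h.q_start) / len(gene.cds) >= thresholds.min_query_coverage:
            return h
    return None


def classify_absent_genes(donor_genes: Sequence[GeneModel],
                          focal_arm_genes: Sequence[GeneModel],
                          homoeologue_sets: Sequence[Sequence[GeneModel]] = (),
                          rest_of_genome_sets: Sequence[Sequence[GeneModel]] = (),
                          thresholds: OrthologyThresholds = OrthologyThresholds()
                          ) -> list[LossRecord]:
    """Run the loss cascade for every donor gene.

    (1) RBH partner on the focal arm -> ortholog_on_focal_arm; else
    (2) presence hit in a homoeologue set -> homoeologue; else
    (3) presence hit elsewhere -> paralog_elsewhere; else lost.
    The classes partition the donor gene set.
    """
    paired = {p.gene_a for p in reciprocal_best_hits(donor_genes, focal_arm_genes,
                                                     thresholds)}
    homoeo_indexes = [KmerIndex([_cds_record(g) for g in s], k=thresholds.k)
                      for s in homoeologue_sets if s]
    rest_indexes = [KmerIndex([_cds_record(g) for g in s], k=thresholds.k)
                    for s in rest_of_genome_sets if s]

    records = []
    for g in donor_genes:
        if g.gene_id in paired:
            records.append(LossRecord(g.gene_id, "ortholog_on_focal_arm"))
            continue
        hit = None
        for idx in homoeo_indexes:
            hit = _has_presence_hit(g, idx, thresholds)
            if hit:
                records.append(LossRecord(g.gene_id, "homoeologue", hit.target_id))
                break
        if hit:
            continue
        for idx in rest_indexes:
            hit = _has_presence_hit(g, idx, thresholds)
            if hit:
                records.append(LossRecord(g.gene_id, "paralog_elsewhere",
                                          hit.target_id))
                break
        if hit:
            continue
        records.append(LossRecord(g.gene_id, "lost"))
    assert len(records) == len(donor_genes)
    return records


def loss_density_profile(loss_records: Sequence[LossRecord],
                         gene_coords: Mapping[str, tuple[int, int]],
                         bin_size: int,
                         arm_length: int | None = None,
                         telomere_first: bool = False) -> pd.DataFrame:
    """Lost-gene counts per coordinate bin, centromere -> telomere.

    ``telomere_first`` flips the bin order for arms stored with the
    telomere at coordinate zero.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if arm_length is None:
        arm_length = max((e for _, e in gene_coords.values()), default=0)
    n_bins = max(1, -(-arm_length // bin_size))
    counts = np.zeros(n_bins, int)
    for rec in loss_records:
        if rec.classification != "lost":
            continue
        s, e = gene_coords[rec.gene_id]
        mid = (s + e) // 2
        counts[min(n_bins - 1, mid // bin_size)] += 1
    if telomere_first:
        counts = counts[::-1]
    return pd.DataFrame({"bin": np.arange(n_bins),
                         "start": np.arange(n_bins) * bin_size,
                         "lost_genes": counts})
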