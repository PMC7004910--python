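"""Generator truth tables, determinism and realized-divergence properties."""

import dataclasses
from itertools import permutations

import numpy as np
import pytest

from armcompare._genetic_code import AA_OF, STOP_CODONS, translate
from armcompare.aligner import revcomp
from armcompare.synthetic_data import (ConfigError, SimulationConfig,
                                       _evolve_cds, _random_orf,
                                       evolve_derived, fragment_assembly,
                                       simulate_ancestor, simulate_markers)
from tests.conftest import TINY


def pathway_pn_ps(cds_a: str, cds_b: str) -> tuple[float, float]:
    """Test-local exhaustive counting of differences per codon pathway."""
    sd = nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        pos = [p for p in range(3) if ca[p] != cb[p]]
        if not pos:
            continue
        totals = []
        for order in permutations(pos):
            cur, s, n, ok = ca, 0, 0, True
            for p in order:
                nxt = cur[:p] + cb[p] + cur[p + 1:]
                if nxt in STOP_CODONS:
                    ok = False
                    break
                if AA_OF[nxt] == AA_OF[cur]:
                    s += 1
                else:
                    n += 1
                cur = nxt
            if ok:
                totals.append((s, n))
        if totals:
            sd += sum(t[0] for t in totals) / len(totals)
            nd += sum(t[1] for t in totals) / len(totals)
    return sd, nd


class TestSimulateAncestor:
    def test_deterministic_byte_identical(self):
        cfg = dataclasses.replace(TINY, seed=1)
        a, b = simulate_ancestor(cfg), simulate_ancestor(cfg)
        assert a.record == b.record
        assert a.genes == b.genes and a.tes == b.tes

    def test_te_fraction_zero_means_no_tes(self):
        cfg = dataclasses.replace(TINY, te_fraction=0.0, arm_length=100_000)
        anc = simulate_ancestor(cfg)
        assert anc.tes == []

    def test_all_orfs_translate_cleanly(self):
        cfg = dataclasses.replace(TINY, n_genes=100, arm_length=500_000)
        anc = simulate_ancestor(cfg)
        assert len(anc.genes) == 100
        for g in anc.genes:
            protein = translate(g.cds)
            assert protein[0] == "M" and protein[-1] == "*"
            assert "*" not in protein[:-1]

    def test_minus_strand_genes_emitted_reverse_complemented(self, tiny_ancestor):
        minus = [g for g in tiny_ancestor.genes if g.strand == "-"]
        assert minus, "fixture should contain minus-strand genes"
        g = minus[0]
        assert revcomp(tiny_ancestor.record.seq[g.start:g.end]) == g.cds

    def test_ltr_pairs_identical_at_insertion(self, tiny_ancestor):
        seq = tiny_ancestor.record.seq
        for te in tiny_ancestor.tes[:10]:
            assert seq[slice(*te.ltr5)] == seq[slice(*te.ltr3)]

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ConfigError):
            simulate_ancestor(dataclasses.replace(
                TINY, arm_length=10_000, n_genes=100))

    def test_bad_probability_rejected(self):
        with pytest.raises(ConfigError):
            simulate_ancestor(dataclasses.replace(TINY, loss_prob=1.5))


class TestEvolveDerived:
    def test_no_loss_no_reloc_all_retained(self):
        cfg = dataclasses.replace(TINY, loss_prob=0.0, reloc_prob=0.0,
                                  rga_loss_multiplier=1.0)
        anc = simulate_ancestor(cfg)
        der = evolve_derived(anc, cfg)
        assert set(anc.truth.gene_fate.values()) == {"retained"}
        assert len(der.focal_genes) == cfg.n_genes
        assert der.homoeologue_genes == []

    def test_omega_zero_preserves_protein(self):
        cfg = dataclasses.replace(
            TINY, per_gene_omega={f"g{i:04d}": 0.0 for i in range(TINY.n_genes)},
            loss_prob=0.0, reloc_prob=0.0, rga_loss_multiplier=1.0)
        anc = simulate_ancestor(cfg)
        der = evolve_derived(anc, cfg)
        by_id = {g.gene_id: g for g in anc.genes}
        changed = 0
        for d in der.focal_genes:
            src = by_id[anc.truth.derived_of[d.gene_id]]
            assert translate(d.cds) == translate(src.cds)
            changed += d.cds != src.cds
        assert changed > 0  # synonymous changes still happen

    def test_realized_dnds_rank_orders_with_assigned_omega(self, rng):
        """Counted pN/pS (exhaustive pathway oracle) follows the target omega."""
        rates = {}
        for omega in (0.2, 1.0, 5.0):
            ratios = []
            for rep in range(25):
                cds = _random_orf(200, rng)
                der = _evolve_cds(cds, omega, 0.08, rng)
                sd, nd = pathway_pn_ps(cds[:-3], der[:-3])
                if sd > 0:
                    ratios.append(nd / sd)
            rates[omega] = np.mean(ratios)
        assert rates[0.2] < rates[1.0] < rates[5.0]

    def test_ltr_divergence_scales_with_age(self, tiny_ancestor, tiny_derived):
        truth = tiny_ancestor.truth
        ps = {}
        for pair in tiny_derived.ltr_pairs:
            p = np.mean([a != b for a, b in zip(pair.ltr5, pair.ltr3)])
            ps[pair.element_id] = p
        young = [e for e, k in truth.ltr_age_truth.items() if k < 0.01]
        old = [e for e, k in truth.ltr_age_truth.items() if k > 0.04]
        if young and old:
            assert np.mean([ps[e] for e in young]) < np.mean([ps[e] for e in old])


class TestFragmentAssembly:
    def test_planted_gaps_match_truth_fills(self, tiny_ancestor, tiny_fragmented):
        truth = tiny_ancestor.truth
        rec = tiny_fragmented.assembly.record
        assert len(tiny_fragmented.assembly.gaps) == TINY.n_gaps
        for g in tiny_fragmented.assembly.gaps:
            assert set(rec.seq[g.start:g.end]) == {"N"}
            fill = truth.gap_truth[(g.start, g.end)]
            assert len(fill) == g.length and "N" not in fill
            assert tiny_ancestor.record.seq[g.start:g.end] == fill

    def test_gaps_do_not_overlap_genes(self, tiny_ancestor, tiny_fragmented):
        for g in tiny_fragmented.assembly.gaps:
            for gene in tiny_ancestor.genes:
                assert g.end <= gene.start or gene.end <= g.start

    def test_every_gap_spanned_by_a_filler_when_nothing_withheld(
            self, tiny_ancestor, tiny_fragmented):
        """Interval-cover check done independently via substring search."""
        truth = tiny_ancestor.truth
        genome = tiny_ancestor.record.seq
        all_fillers = [r.seq for _, recs in tiny_fragmented.pools for r in recs]
        for (s, e), fill in truth.gap_truth.items():
            window = genome[s - 200:e + 200]
            found = any(window in f or revcomp(window) in f for f in all_fillers)
            assert found, f"gap ({s},{e}) has no spanning filler"
            assert truth.gap_closable[(s, e)]

    def test_withheld_fraction_one_leaves_no_spanning_fillers(self):
        cfg = dataclasses.replace(TINY, withheld_fraction=1.0, n_gaps=5)
        anc = simulate_ancestor(cfg)
        frag = fragment_assembly(anc.record, cfg, anc.genes, anc.truth)
        assert not any(anc.truth.gap_closable.values())
        genome = anc.record.seq
        fillers = [r.seq for _, recs in frag.pools for r in recs]
        for (s, e) in anc.truth.gap_truth:
            window = genome[s - 200:e + 200]
            assert not any(window in f or revcomp(window) in f for f in fillers)

    def test_gap_overlapping_filler_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(gap_len_dist=(100, 6_000)).validate()


class TestSimulateMarkers:
    def test_unique_placements_verified_by_exhaustive_scan(
            self, tiny_ancestor, tiny_markers):
        marker_df, _, truth = tiny_markers
        genome = tiny_ancestor.record.seq
        rc = revcomp(genome)
        assert len(marker_df) == TINY.n_markers
        for row in marker_df.itertuples(index=False):
            tr = truth.marker_truth[row.marker_id]
            # exhaustive forward-strand scan for the forward primer
            hits = [i for i in range(len(genome) - len(row.fwd_primer) + 1)
                    if genome[i:i + len(row.fwd_primer)] == row.fwd_primer]
            assert hits == [tr["position"]]
            assert row.fwd_primer not in rc
            s, e = tr["position"], tr["position"] + tr["product_len"]
            assert revcomp(genome[e - len(row.rev_primer):e]) == row.rev_primer

    def test_gap_spanning_flag_consistent(self, tiny_fragmented, tiny_markers):
        _, _, truth = tiny_markers
        gaps = tiny_fragmented.assembly.gaps
        for tr in truth.marker_truth.values():
            s, e = tr["position"], tr["position"] + tr["product_len"]
            spans = any(s < g.end and g.start < e for g in gaps)
            assert tr["gap_spanning"] == spans

    def test_seed_repeat_identical_table(self, tiny_ancestor):
        a, _, _ = simulate_markers(tiny_ancestor.record, TINY)
        b, _, _ = simulate_markers(tiny_ancestor.record, TINY)
        assert a.equals(b)

    def test_short_primers_rejected(self, tiny_ancestor):
        with pytest.raises(ConfigError):
            simulate_markers(tiny_ancestor.record,
                             dataclasses.replace(TINY, primer_len=10))
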