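"""Synthetic chromosome-arm generator with full truth tables.

Emulates the data a donor-vs-polyploid chromosome arm study consumes,
at desk scale and with every planted feature recorded, so the whole
pipeline can be exercised and scored without any external download:

* an ancestral arm carrying protein-coding ORFs and LTR retrotransposon
  copies whose two LTRs are identical at insertion;
* a derived (polyploid-like) gene set produced by per-codon substitution
  with a per-gene dN/dS target, gene losses and relocations into a decoy
  homoeologue set, and LTR pairs diverged to a recorded age;
* a gapped copy of the arm (planted N-runs) plus filler pools tiling the
  true sequence, so gap closure has a known answer per gap;
* primer-pair markers copied from unique loci, grouped into QTLs.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._genetic_code import SENSE_CODONS, STOP_CODONS, is_stop, translate
from .aligner import revcomp
from .genome_io import GapRecord, GappedAssembly, SequenceRecord

log = logging.getLogger(__name__)

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


class ConfigError(ValueError):
    """Raised when a simulation request cannot be satisfied."""


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic arm.

    Defaults describe the standard desk-scale study arm: a 5-Mb
    gene-bearing region with ~55% retrotransposon cover, 200 genes,
    ~5% neutral coding divergence between donor and derived sets, and
    100 planted N-gaps all of whose true fills are present in the
    filler pools.
    """

    seed: int = 42
    arm_length: int = 5_000_000
    n_genes: int = 200
    gene_len_codons: tuple[int, int] = (100, 400)

    te_fraction: float = 0.55
    n_te_families: int = 4
    ltr_len: int = 300
    te_internal_len: tuple[int, int] = (2_000, 6_000)
    te_copy_divergence: float = 0.05
    mean_ltr_age_k: float = 0.02

    # derived-set evolution
    omega_values: tuple[float, ...] = (0.2, 1.0, 5.0)
    omega_weights: tuple[float, ...] = (0.7, 0.2, 0.1)
    per_gene_omega: Optional[dict[str, float]] = None
    loss_prob: float = 0.03
    reloc_prob: float = 0.03
    subst_rate_neutral: float = 0.05
    rga_fraction: float = 0.08
    rga_loss_multiplier: float = 5.0
    n_decoy_categories: int = 4

    # gapping / filler pools
    n_gaps: int = 100
    gap_len_dist: tuple[int, int] = (100, 1_500)
    gap_min_spacing: int = 4_000
    gap_edge_margin: int = 3_000
    protect_genes: bool = True
    filler_tile_len: int = 5_000
    filler_overlap: int = 2_500
    filler_error: float = 0.0
    withheld_fraction: float = 0.0
    revcomp_prob: float = 0.5
    pool_labels: tuple[str, ...] = ("unmapped", "singleton_bac", "pacbio")
    pool_weights: tuple[float, ...] = (0.05, 0.35, 0.60)
    min_anchor: int = 200  # flank anchor needed inside a spanning filler

    # markers
    n_markers: int = 20
    primer_len: int = 20
    product_len: tuple[int, int] = (150, 800)
    n_qtls: int = 8

    def validate(self) -> None:
        for name in ("loss_prob", "reloc_prob", "withheld_fraction",
                     "revcomp_prob", "rga_fraction", "te_copy_divergence",
                     "filler_error"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if not 0.0 <= self.te_fraction < 1.0:
            raise ConfigError("te_fraction must be in [0, 1)")
        if self.gap_len_dist[1] >= self.filler_tile_len:
            raise ConfigError("max gap length must be < filler_tile_len")
        if self.primer_len < 15:
            raise ConfigError("primer_len must be >= 15")
        if self.filler_overlap >= self.filler_tile_len:
            raise ConfigError("filler_overlap must be < filler_tile_len")


@dataclass
class TruthTables:
    """Planted ground truth, one entry per planted entity."""

    gap_truth: dict[tuple[int, int], str] = field(default_factory=dict)
    gap_withheld: set[tuple[int, int]] = field(default_factory=set)
    gap_closable: dict[tuple[int, int], bool] = field(default_factory=dict)
    gene_fate: dict[str, str] = field(default_factory=dict)
    derived_of: dict[str, str] = field(default_factory=dict)
    omega_truth: dict[str, float] = field(default_factory=dict)
    ltr_age_truth: dict[str, float] = field(default_factory=dict)
    marker_truth: dict[str, dict] = field(default_factory=dict)
    qtl_truth: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    start: int
    end: int
    strand: str
    cds: str  # coding strand, starts ATG, ends with a stop codon


@dataclass(frozen=True)
class TEAnnotation:
    element_id: str
    family: str
    start: int
    end: int
    ltr_len: int

    @property
    def ltr5(self) -> tuple[int, int]:
        return (self.start, self.start + self.ltr_len)

    @property
    def ltr3(self) -> tuple[int, int]:
        return (self.end - self.ltr_len, self.end)


@dataclass
class Ancestor:
    record: SequenceRecord
    genes: list[GeneModel]
    tes: list[TEAnnotation]
    categories: dict[str, list[str]]  # gene -> category labels
    truth: TruthTables
    config: SimulationConfig


@dataclass(frozen=True)
class LTRPair:
    element_id: str
    ltr5: str
    ltr3: str


@dataclass
class Derived:
    focal_genes: list[GeneModel]      # retained genes, evolved
    homoeologue_genes: list[GeneModel]  # relocated genes (decoy 7A/7B stand-in)
    ltr_pairs: list[LTRPair]
    truth: TruthTables


@dataclass
class Fragmented:
    assembly: GappedAssembly
    pools: list[tuple[str, list[SequenceRecord]]]
    truth: TruthTables


# ---------------------------------------------------------------------------
# low-level sequence helpers (numpy codes 0..3, N=4)
# ---------------------------------------------------------------------------

def _to_str(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def _to_arr(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def _random_arr(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def _mutate_bernoulli(arr: np.ndarray, rate: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``."""
    out = arr.copy()
    if rate <= 0:
        return out
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    jumps = rng.integers(1, 4, size=len(hit)).astype(np.uint8)
    out[hit] = (out[hit] + jumps) % 4
    return out


def _mutate_poisson(arr: np.ndarray, expected_subs: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Apply a Poisson(expected_subs) number of jumps per site.

    Multiple hits chain through intermediate states, so observed
    divergence saturates exactly as the Jukes–Cantor correction assumes.
    """
    out = arr.copy()
    if expected_subs <= 0:
        return out
    hits = rng.poisson(expected_subs, size=len(arr))
    for site in np.nonzero(hits)[0]:
        b = int(out[site])
        for _ in range(int(hits[site])):
            b = (b + int(rng.integers(1, 4))) % 4
        out[site] = b
    return out


def _random_orf(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + (n_codons - 2) random sense codons + random stop codon."""
    if n_codons < 3:
        raise ConfigError("gene length must be >= 3 codons")
    body = rng.choice(len(SENSE_CODONS), size=n_codons - 2)
    stop = sorted(STOP_CODONS)[int(rng.integers(0, len(STOP_CODONS)))]
    return "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop


# ---------------------------------------------------------------------------
# [OP] simulate_ancestor
# ---------------------------------------------------------------------------

def simulate_ancestor(config: SimulationConfig) -> Ancestor:
    """Build the ancestral arm: ORFs + LTR elements + intergenic space.

    Each TE copy is a family consensus mutated by ``te_copy_divergence``
    with its two LTRs still identical (they diverge only with age, which
    is applied by :func:`evolve_derived` and recorded in the truth).
    Deterministic given (config, seed).
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    truth = TruthTables()

    # TE family library
    families = []
    for fi in range(config.n_te_families):
        internal_len = int(rng.integers(config.te_internal_len[0],
                                        config.te_internal_len[1] + 1))
        families.append({
            "name": f"fam{fi}",
            "ltr": _random_arr(config.ltr_len, rng),
            "internal": _random_arr(internal_len, rng),
        })

    # plan TE copies up to the requested arm fraction
    te_budget = config.te_fraction * config.arm_length
    te_plan = []
    total_te = 0
    while config.te_fraction > 0 and total_te < te_budget:
        fam = families[int(rng.integers(0, len(families)))]
        age_k = float(rng.exponential(config.mean_ltr_age_k))
        length = 2 * config.ltr_len + len(fam["internal"])
        te_plan.append((fam, age_k))
        total_te += length

    # plan genes
    gene_lens = rng.integers(config.gene_len_codons[0],
                             config.gene_len_codons[1] + 1,
                             size=config.n_genes)
    gene_strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")

    features: list[tuple] = [("te", i) for i in range(len(te_plan))]
    features += [("gene", i) for i in range(config.n_genes)]
    rng.shuffle(features)

    feat_len = total_te + int(gene_lens.sum()) * 3
    min_spacer = 50
    spacer_total = config.arm_length - feat_len - min_spacer * (len(features) + 1)
    if spacer_total < 0:
        raise ConfigError(
            f"requested content ({feat_len} bp features) exceeds arm_length "
            f"{config.arm_length}")
    spacers = rng.multinomial(spacer_total,
                              np.full(len(features) + 1, 1.0 / (len(features) + 1)))
    spacers = spacers + min_spacer

    chunks: list[np.ndarray] = []
    genes: list[GeneModel] = []
    tes: list[TEAnnotation] = []
    pos = 0
    for idx, (kind, i) in enumerate(features):
        sp = _random_arr(int(spacers[idx]), rng)
        chunks.append(sp)
        pos += len(sp)
        if kind == "te":
            fam, age_k = te_plan[i]
            ltr_copy = _mutate_bernoulli(fam["ltr"], config.te_copy_divergence, rng)
            internal_copy = _mutate_bernoulli(fam["internal"],
                                              config.te_copy_divergence, rng)
            element = np.concatenate([ltr_copy, internal_copy, ltr_copy])
            eid = f"te{i:04d}"
            tes.append(TEAnnotation(eid, fam["name"], pos, pos + len(element),
                                    config.ltr_len))
            truth.ltr_age_truth[eid] = age_k
            chunks.append(element)
            pos += len(element)
        else:
            cds = _random_orf(int(gene_lens[i]), rng)
            gid = f"g{i:04d}"
            emitted = cds if gene_strands[i] == "+" else revcomp(cds)
            genes.append(GeneModel(gid, pos, pos + len(cds), gene_strands[i], cds))
            chunks.append(_to_arr(emitted))
            pos += len(cds)
    chunks.append(_random_arr(int(spacers[-1]), rng))
    arr = np.concatenate(chunks)
    assert len(arr) == config.arm_length

    # per-gene omega truth
    for g in genes:
        if config.per_gene_omega and g.gene_id in config.per_gene_omega:
            w = float(config.per_gene_omega[g.gene_id])
        else:
            w = float(rng.choice(config.omega_values, p=config.omega_weights))
        truth.omega_truth[g.gene_id] = w

    # category annotation: RGA flags plus decoy categories
    categories: dict[str, list[str]] = {g.gene_id: [] for g in genes}
    rga = rng.random(len(genes)) < config.rga_fraction
    for g, flag in zip(genes, rga):
        if flag:
            categories[g.gene_id].append("RGA")
    for ci in range(config.n_decoy_categories):
        members = rng.random(len(genes)) < 0.10
        for g, flag in zip(genes, members):
            if flag:
                categories[g.gene_id].append(f"CAT{ci:02d}")

    record = SequenceRecord("arm7DL_sim", _to_str(arr))
    return Ancestor(record, genes, tes, categories, truth, config)


# ---------------------------------------------------------------------------
# [OP] evolve_derived
# ---------------------------------------------------------------------------

def _evolve_cds(cds: str, omega: float, rate: float,
                rng: np.random.Generator) -> str:
    """Per-codon substitution by rejection sampling.

    Proposals are uniform over all single-nucleotide changes in the
    coding region (terminal stop excluded); proposals creating a stop are
    purged; synonymous proposals are accepted with probability
    min(1, 1/omega) and nonsynonymous with min(1, omega), so the realized
    nonsynonymous/synonymous rate ratio per mutational opportunity is
    omega and stays auditable by counting.
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    n_coding_nt = 3 * (len(codons) - 1)  # final stop held fixed
    if n_coding_nt <= 0:
        return cds
    acc_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    acc_non = min(1.0, omega)
    n_events = rng.poisson(rate * n_coding_nt)
    for _ in range(n_events):
        site = int(rng.integers(0, n_coding_nt))
        ci, pos = divmod(site, 3)
        codon = codons[ci]
        jump = int(rng.integers(1, 4))
        base = "ACGT"[("ACGT".index(codon[pos]) + jump) % 4]
        new = codon[:pos] + base + codon[pos + 1:]
        if is_stop(new):
            continue
        syn = translate(new) == translate(codon)
        p = acc_syn if syn else acc_non
        if rng.random() < p:
            codons[ci] = new
    return "".join(codons)


def evolve_derived(ancestor: Ancestor, config: SimulationConfig | None = None
                   ) -> Derived:
    """Evolve the derived gene set and diverge LTR pairs.

    Lost genes are removed outright; relocated genes are emitted in a
    decoy homoeologue set (standing in for chromosomes 7A/7B); every
    other gene evolves in place.  LTR pairs diverge to the per-element
    age K recorded at simulation time.
    """
    config = config or ancestor.config
    rng = np.random.default_rng([config.seed, 23])
    truth = ancestor.truth

    focal: list[GeneModel] = []
    homoeo: list[GeneModel] = []
    for g in ancestor.genes:
        loss_p = config.loss_prob
        if "RGA" in ancestor.categories.get(g.gene_id, []):
            loss_p = min(1.0, loss_p * config.rga_loss_multiplier)
        u = rng.random()
        if u < loss_p:
            truth.gene_fate[g.gene_id] = "lost"
            continue
        if u < loss_p + config.reloc_prob:
            fate, did = "relocated", g.gene_id + "_H"
        else:
            fate, did = "retained", g.gene_id + "_D"
        truth.gene_fate[g.gene_id] = fate
        truth.derived_of[did] = g.gene_id
        cds = _evolve_cds(g.cds, truth.omega_truth[g.gene_id],
                          config.subst_rate_neutral, rng)
        model = GeneModel(did, g.start, g.start + len(cds), g.strand, cds)
        (homoeo if fate == "relocated" else focal).append(model)

    # LTR pairs: each LTR accumulates K/2 expected substitutions/site
    ltr_pairs = []
    arr = _to_arr(ancestor.record.seq)
    for te in ancestor.tes:
        k = truth.ltr_age_truth[te.element_id]
        l5 = arr[te.ltr5[0]:te.ltr5[1]]
        l3 = arr[te.ltr3[0]:te.ltr3[1]]
        ltr_pairs.append(LTRPair(
            te.element_id,
            _to_str(_mutate_poisson(l5, k / 2, rng)),
            _to_str(_mutate_poisson(l3, k / 2, rng)),
        ))
    return Derived(focal, homoeo, ltr_pairs, truth)


# ---------------------------------------------------------------------------
# [OP] fragment_assembly
# ---------------------------------------------------------------------------

def fragment_assembly(genome: SequenceRecord, config: SimulationConfig,
                      genes: list[GeneModel] | None = None,
                      truth: TruthTables | None = None) -> Fragmented:
    """Plant N-gaps in a copy of ``genome`` and tile filler pools.

    Filler tiles derive from the TRUE genome (optionally with substitution
    error and random reverse-complementing), so every non-withheld gap is
    spanned by at least one filler.  A ``withheld_fraction`` of gaps has
    all spanning tiles removed to exercise the rejection paths.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 37])
    truth = truth if truth is not None else TruthTables()
    L = len(genome.seq)
    lo, hi = config.gap_len_dist

    import bisect

    gene_iv = sorted((g.start, g.end) for g in (genes or []))

    def overlaps_gene(s: int, e: int) -> bool:
        # genes are non-overlapping and sorted: only the last interval
        # starting before `e` can reach past `s`
        i = bisect.bisect_left(gene_iv, (e,))
        return i > 0 and gene_iv[i - 1][1] > s

    gaps: list[tuple[int, int]] = []
    tries = 0
    max_tries = 500 * max(1, config.n_gaps)
    while len(gaps) < config.n_gaps:
        tries += 1
        if tries > max_tries:
            raise ConfigError("could not place requested gaps (packing too tight)")
        glen = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(config.gap_edge_margin,
                                 L - config.gap_edge_margin - glen))
        end = start + glen
        if any(start < e + config.gap_min_spacing and s - config.gap_min_spacing < end
               for s, e in gaps):
            continue
        if config.protect_genes and genes and overlaps_gene(start, end):
            continue
        gaps.append((start, end))
    gaps.sort()

    arr = _to_arr(genome.seq)
    for s, e in gaps:
        truth.gap_truth[(s, e)] = genome.seq[s:e]
        arr[s:e] = 4
    gapped = SequenceRecord(genome.id, _to_str(arr))
    gap_records = tuple(GapRecord(genome.id, s, e) for s, e in gaps)

    # withheld gaps: their spanning tiles are dropped from every pool
    n_withheld = int(round(config.withheld_fraction * len(gaps)))
    if n_withheld:
        chosen = rng.choice(len(gaps), size=n_withheld, replace=False)
        truth.gap_withheld = {gaps[i] for i in chosen}

    step = config.filler_tile_len - config.filler_overlap
    starts = list(range(0, L - config.filler_tile_len + 1, step))
    if starts and starts[-1] != L - config.filler_tile_len:
        starts.append(L - config.filler_tile_len)

    pools: dict[str, list[SequenceRecord]] = {lab: [] for lab in config.pool_labels}
    tile_spans: list[tuple[int, int]] = []
    weights = np.asarray(config.pool_weights, float)
    weights = weights / weights.sum()
    for i, ts in enumerate(starts):
        te = ts + config.filler_tile_len
        if any(ts < ge and gs < te for gs, ge in truth.gap_withheld):
            continue
        tile = _to_arr(genome.seq[ts:te])
        if config.filler_error > 0:
            tile = _mutate_bernoulli(tile, config.filler_error, rng)
        seq = _to_str(tile)
        if rng.random() < config.revcomp_prob:
            seq = revcomp(seq)
        lab = config.pool_labels[int(rng.choice(len(weights), p=weights))]
        pools[lab].append(SequenceRecord(f"fill_{i:05d}", seq))
        tile_spans.append((ts, te))

    # truth: a gap is closable iff some surviving tile contains the gap
    # plus one anchor of min_anchor on each side
    a = config.min_anchor
    for s, e in gaps:
        truth.gap_closable[(s, e)] = any(
            ts <= s - a and e + a <= te for ts, te in tile_spans)

    ordered = [(lab, pools[lab]) for lab in config.pool_labels]
    return Fragmented(GappedAssembly(gapped, gap_records), ordered, truth)


# ---------------------------------------------------------------------------
# [OP] simulate_markers
# ---------------------------------------------------------------------------

def _count_occurrences(genome: str, genome_rc: str, pattern: str) -> int:
    count, start = 0, 0
    for hay in (genome, genome_rc):
        start = 0
        while True:
            i = hay.find(pattern, start)
            if i < 0:
                break
            count += 1
            start = i + 1
    return count


def simulate_markers(genome: SequenceRecord, config: SimulationConfig,
                     gaps: list[GapRecord] | None = None,
                     truth: TruthTables | None = None
                     ) -> tuple[pd.DataFrame, pd.DataFrame, TruthTables]:
    """Copy primer pairs from unique loci and group them into QTLs.

    Uniqueness of each primer is verified by exhaustive exact matching on
    both strands (count must be exactly 1).  Returns (marker table, QTL
    table, truth); the marker truth records position, product length and
    whether the product straddles a planted gap.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 53])
    truth = truth if truth is not None else TruthTables()
    L = len(genome.seq)
    plen = config.primer_len
    g_rc = revcomp(genome.seq)

    markers = []
    attempts = 0
    while len(markers) < config.n_markers:
        attempts += 1
        if attempts > 200 * config.n_markers:
            raise ConfigError("could not find unique marker loci")
        prod = int(rng.integers(config.product_len[0], config.product_len[1] + 1))
        s = int(rng.integers(0, L - prod))
        e = s + prod
        fwd = genome.seq[s:s + plen]
        rev = revcomp(genome.seq[e - plen:e])
        if "N" in fwd or "N" in rev:
            continue
        if _count_occurrences(genome.seq, g_rc, fwd) != 1:
            continue
        if _count_occurrences(genome.seq, g_rc, rev) != 1:
            continue
        mid = f"mk{len(markers):03d}"
        spans_gap = bool(gaps) and any(s < g.end and g.start < e for g in gaps)
        markers.append({"marker_id": mid, "fwd_primer": fwd, "rev_primer": rev,
                        "expected_size": prod})
        truth.marker_truth[mid] = {"position": s, "product_len": prod,
                                   "gap_spanning": spans_gap}
    marker_df = pd.DataFrame(markers)

    # QTLs over position-sorted markers, 1-3 markers each, cycling traits
    traits = ["grain_length", "grain_width", "grain_diameter",
              "thousand_grain_weight", "spike_length"]
    order = sorted(markers, key=lambda m: truth.marker_truth[m["marker_id"]]["position"])
    qtls = []
    i = 0
    qi = 0
    while i < len(order) and qi < config.n_qtls:
        take = int(rng.integers(1, 4))
        group = order[i:i + take]
        i += take
        qid = f"qtl{qi:02d}"
        pos = [truth.marker_truth[m["marker_id"]]["position"] for m in group]
        truth.qtl_truth[qid] = (min(pos), max(pos))
        qtls.append({"qtl_id": qid, "trait": traits[qi % len(traits)],
                     "marker_ids": ",".join(m["marker_id"] for m in group)})
        qi += 1
    qtl_df = pd.DataFrame(qtls)
    return marker_df, qtl_df, truth


# ---------------------------------------------------------------------------
# convenience: run the whole generator
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig) -> tuple[Ancestor, Derived, Fragmented,
                                                    pd.DataFrame, pd.DataFrame]:
    """Ancestor -> derived -> gapped assembly -> markers, sharing one truth."""
    anc = simulate_ancestor(config)
    der = evolve_derived(anc, config)
    frag = fragment_assembly(anc.record, config, anc.genes, anc.truth)
    marker_df, qtl_df, _ = simulate_markers(
        anc.record, config, list(frag.assembly.gaps), anc.truth)
    return anc, der, frag, marker_df, qtl_df
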