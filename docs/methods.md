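# Methods

This note records the models, conventions and design choices behind
`armcompare`, and what the synthetic benchmark does and does not show.

## Coordinates and formats

All coordinates are 0-based half-open internally; GFF3 is written
1-based inclusive and BED 0-based half-open.  FASTA is read through
Biopython, upper-cased, with non-ACGTN IUPAC ambiguity codes mapped to
N (counted and logged) rather than rejected — real assemblies contain
them.  Terminal N-runs are catalogued as genuine gaps; closure later
refuses them because they lack one flank.

## Internal aligner

A small BLAT-like seed-and-extend local aligner backs gap closure,
orthology and presence searches.  k-mer index (default k = 15) over
the target set; seeds occurring more than 100 times are dropped — a
deterministic stand-in for soft-masking repeats.  Seed matches are
clustered by (target, strand, diagonal band of 48 bp) and each cluster
is extended by an exact Smith–Waterman/Gotoh pass over a window around
the cluster's diagonals, so within its window the reported optimum is
the true local-DP optimum (this is asserted against an independent
quadratic oracle in the tests).  Scoring: match +1, mismatch −1, a gap
of length L costs 2 + (L − 1).  No score scheme is canonical for this
task; this one approximates percent-identity behaviour and keeps
integer arithmetic exact.  Clusters supporting fewer than 10% of the
best cluster's seeds are not extended (they cannot plausibly win), and
overlapping hits on one (target, strand) within 10 bp collapse to the
higher score: flank placement needs one best anchor, not an HSP
enumeration.  Minus-strand hits reverse-complement the query; reported
coordinates always refer to forward strands.

## Gap closure

Per gap, up to 1500 bp of N-free flank is cut on each side (truncated
at sequence ends and neighbouring gaps).  Pools are tried in the order
supplied; a gap closed by an earlier pool is not re-attempted, keeping
per-source accounting disjoint.  A closure needs one filler and strand
carrying both flanks with each gap-adjacent alignment end within 10 bp
of its flank end, correct mutual order, and an implied patch length in
[−200 bp, 20 kb]; negative lengths are reported as flank overlaps with
the trim amount recorded.  Competing fillers rank by summed hit score,
ties by pool priority then filler id.  One-flank evidence never
closes.  Flank hits must reach 95% identity over ≥200 columns; these
are declared defaults — no thresholds are canonical for the procedure.
Patches apply right-to-left so stored coordinates stay valid, and a
liftover maps original to patched coordinates (positions inside a
replaced or trimmed interval clamp to the preceding kept base).
Summary tables count the original N-run length, making them comparable
to the gap census; realized patch length is an extra column.

## Orthology and the loss cascade

RBH runs nucleotide CDS-vs-CDS through the internal aligner (identity
≥0.70, query coverage ≥0.50 before best-hit selection).  At the
simulated ~5% divergence nucleotide search is ample; at much larger
divergences a protein-level search would be needed — a documented
limitation.  Ties for best flag the pair ambiguous and exclude it from
the selection scan (ω on a wrong pair is noise).  Donor genes without
an RBH partner cascade: any passing hit in a homoeologue set, then in
any remaining set, else lost; presence thresholds equal the RBH
thresholds.  The four classes partition the donor set by construction.

## dN/dS estimation

The Nei–Gojobori counting method with Jukes–Cantor correction.  Site
counts: each codon position contributes one site, split by the
synonymous fraction of its *viable* single-nucleotide changes —
changes creating a stop codon are excluded from the mutational
opportunities (S + N = 3 × codons always holds).  Differences at
codons differing in >1 position are averaged uniformly over all
shortest substitution pathways, discarding pathways through stops.
pS = Sd/S and pN = Nd/N are corrected by d = −(3/4)·ln(1 − 4p/3);
p ≥ 3/4 raises a saturation error; ω is undefined when dS = 0 and such
pairs stay out of the PSG/NSG counts.  The estimator is exactly
symmetric in its inputs.  Under the generator's neutral process the
mean estimate centres near 1 with a small upward bias (typically
3–15% at 5% divergence and 500 codons: mostly the Jensen skew of the
dN/dS ratio when Sd is modest, plus stop-adjacent sites realizing
slightly fewer substitutions than their site weight implies); the
ω>1 / ω<1 classification is insensitive to this.  Orthologous pairs arrive
codon-aligned from the generator (no indels); indel-containing real
pairs would be codon-aligned by stripping gap codons, with a logged
count.

## Codon bias

Wright's effective number of codons,
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, with
F̂ = (nΣp̂² − 1)/(n − 1) per amino acid (n ≥ 2 observations), class
means over the standard-code degeneracy classes (2 singleton, 9
twofold, 1 threefold, 5 fourfold, 3 sixfold), the threefold class
imputed from the two- and fourfold means when Ile is absent, other
missing classes from the global F̂ average, and the result capped to
[20, 61].  CAI is the geometric mean of relative adaptiveness over
non-Met/Trp sense codons; the pipeline derives weights from the pooled
codon usage of the donor gene set when no reference set is supplied.
Spearman correlations (average ranks, t-approximation p-values) come
from scipy; constant features are reported missing.

## Exact 2×2 tests

Point probabilities are computed in log space from log-gamma factorials,
conditioning on both margins; the two-sided p sums point probabilities
≤ the observed one, with a 1e-7 relative tolerance guarding floating
ties.  A zero margin returns p = 1 with a warning.  Category
enrichment uses the subset construction — the foreground is removed
from the background rows — which is also what reproduces the published
lost-gene RGA p-value (the disjoint-rows reading gives ≈8×10⁻⁶
instead of 4×10⁻⁶).  Benjamini–Hochberg adjustment runs across the
categories actually tested (≥1 foreground hit).

## LTR dating

K is the Jukes–Cantor-corrected mismatch proportion between the two
LTRs of one element (gap/N columns dropped with a logged count), the
standard insertion-dating practice; raw p is exposed alongside.
T = K/(2r) with r defaulting to the conventional grass rate
1.3×10⁻⁸ substitutions/site/year, overridable per run.

## e-PCR and QTL anchoring

A placement needs the forward primer on either strand with at most
`max_mismatch` (default 1) mismatches and an exact 3′-terminal 3 bases
(where polymerase extension starts), and the reverse primer's reverse
complement downstream on the same molecule; products are capped at
10 kb and optionally filtered by a size window.  No mismatch or size
tolerances are canonical; these are declared defaults.  QTL intervals
span the midpoints of their placed markers (single-marker QTLs widen
by 1 Mb); genes link to a QTL when their midpoint falls within the
interval expanded by a 3-Mb window — the span of the worked grain-
morphology example region — with distance 0 inside the raw interval.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
at desk scale: a 5-Mb gene-bearing arm (200 ORFs of 100–400 codons,
~55% LTR-retrotransposon cover from four families, copies mutated 5%
from their consensus so repeats are realistic but resolvable), ~5%
neutral coding divergence to the derived set with per-gene target
ω ∈ {0.2, 1, 5} (weights 0.7/0.2/0.1), 3% loss and 3% relocation per
gene (relocated genes form a decoy homoeologue set), a 5× higher loss
rate for the ~8% of genes tagged RGA (so the enrichment stage has a
planted signal), exponential LTR ages (mean K = 0.02) applied as
Poisson substitution processes so JC correction is exact in
expectation, 100 non-overlapping planted N-gaps of 100–1500 bp kept
clear of CDS, filler tiles of 5 kb at 2.5-kb step drawn from the true
sequence (reverse-complemented with probability 0.5, optional error
rate, optional withheld fraction to exercise rejection paths), and 20
primer-pair markers copied from loci verified unique by exhaustive
scan.  Codon evolution is per-site rejection sampling — proposals
uniform over single-nucleotide changes, stops purged, synonymous
changes accepted with min(1, 1/ω) and nonsynonymous with min(1, ω) —
rather than a rate-matrix exponential: simpler, adequate at this
scale, and the realized ω stays auditable by counting.  Everything is
reproducible bit-for-bit from (config, seed); stage streams derive
from the root seed by fixed constants.

What the generator does **not** emulate: sequencing error at the read
level, indels, realistic TE family phylogenies or nested insertions,
segmental duplication, recombination, and real codon-usage landscapes.
Passing the planted-truth benchmarks therefore demonstrates the
correctness of the decision rules and estimators under their stated
assumptions — not performance on raw wheat data, whose scale and
repeat structure are far harsher.

## Problem sizes and numerics

The default benchmark (5 Mb, 100 gaps, 200 genes, ~450 TEs, 20
markers) was chosen so a complete run finishes in a few minutes on one
CPU while every per-stage score is estimated from ≥100 planted events.
Integer alignment scores make DP results exactly reproducible; the
Fisher test's log-space evaluation is stable far beyond the table
sizes used here; ENC is capped to its theoretical range; ties in
closure candidates break deterministically (score, then pool priority,
then filler id) so runs are byte-identical across repeats.
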