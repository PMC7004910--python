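"""Pairwise dN/dS by the Nei–Gojobori counting method, with codon-bias features.

The estimator counts synonymous (S) and nonsynonymous (N) sites per
codon from the mutational opportunities of the standard genetic code,
counts observed synonymous/nonsynonymous differences (Sd, Nd) by
averaging uniformly over all shortest substitution pathways between
differing codons (pathways through stop codons discarded), and corrects
the proportions with the one-parameter Jukes–Cantor formula
``d = -(3/4) ln(1 - 4p/3)``.  Changes that would create a stop codon
are excluded from the mutational opportunities on both the site and the
difference side, so a neutral substitution process that purges premature
stops is estimated at omega = 1 without bias.

Genes with dS = 0 have undefined omega and are left out of the
positively/negatively selected classes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._genetic_code import AA_OF, is_stop

log = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Raised when a difference proportion reaches the Jukes–Cantor pole."""


@dataclass(frozen=True)
class CodingPair:
    gene_a: str
    gene_b: str
    codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: Optional[float]


@dataclass(frozen=True)
class GeneFeatures:
    gene_id: str
    gc: float
    gc3: float
    length: int
    enc: float
    cai: Optional[float]
    expression: Optional[float] = None


def jukes_cantor(p: float) -> float:
    """JC69 distance; raises :class:`SaturationError` at p >= 3/4."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(f"p={p:.4f} >= 3/4: distance saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=None)
def _site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes 1 site split by the synonymous fraction of
    its viable (non-stop) single-nucleotide changes.
    """
    if is_stop(codon):
        raise ValueError("stop codon has no site counts")
    syn_sites = 0.0
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1:]
                for b in "ACGT" if b != codon[pos]]
        viable = [c for c in alts if not is_stop(c)]
        if viable:
            syn = sum(AA_OF[c] == AA_OF[codon] for c in viable)
            syn_sites += syn / len(viable)
    return syn_sites, 3.0 - syn_sites


@lru_cache(maxsize=None)
def _pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) between two codons, averaged over shortest pathways.

    Pathways that pass through a stop codon are discarded; if every
    pathway does (never the case for sense-codon pairs under the
    standard code), steps are classified directly without intermediates.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = non = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if is_stop(nxt):
                ok = False
                break
            if AA_OF[nxt] == AA_OF[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            totals.append((syn, non))
    if not totals:  # pragma: no cover - unreachable for sense codons
        return 0.0, float(len(diff_pos))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def ng86_counts(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """Site and difference counts (S, N, Sd, Nd) for one pre-aligned pair.

    Sequences must be equal length, divisible by 3, gap/N free, with no
    internal stops (strip the terminal stop first).
    """
    if len(cds_a) != len(cds_b):
        raise ValueError("coding sequences differ in length")
    if len(cds_a) % 3:
        raise ValueError("length not divisible by 3")
    for cds in (cds_a, cds_b):
        if any(ch not in "ACGT" for ch in cds):
            raise ValueError("CDS contains gaps/ambiguity symbols")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i:i + 3], cds_b[i:i + 3]
        if is_stop(ca) or is_stop(cb):
            raise ValueError(f"internal stop codon at nt {i}")
        sa, na = _site_counts(ca)
        sb, nb = _site_counts(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        sd, nd = _pathway_diffs(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


def ng86_dnds(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b"
              ) -> CodingPair:
    """Nei–Gojobori counting estimate for one pre-aligned codon pair.

    Symmetric in its inputs; raises :class:`SaturationError` when either
    difference proportion reaches the Jukes–Cantor pole.
    """
    S, N, Sd, Nd = ng86_counts(cds_a, cds_b)
    n_codons = len(cds_a) // 3
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    omega = (dN / dS) if dS > 0 else None
    return CodingPair(gene_a, gene_b, n_codons, S, N, Sd, Nd, pS, pN, dS, dN, omega)


def classify_selection(pairs: Iterable[CodingPair]
                       ) -> tuple[list[CodingPair], list[CodingPair], list[CodingPair]]:
    """Split pairs into (PSG, NSG, unclassified) by omega vs 1."""
    psg, nsg, unclassified = [], [], []
    for p in pairs:
        if p.omega is None or p.omega == 1.0:
            unclassified.append(p)
        elif p.omega > 1.0:
            psg.append(p)
        else:
            nsg.append(p)
    return psg, nsg, unclassified


# ---------------------------------------------------------------------------
# codon bias metrics
# ---------------------------------------------------------------------------

# amino-acid degeneracy classes of the standard code (Ser/Leu/Arg are
# sixfold; Ile threefold; Met/Trp singletons)
_FAMILY: dict[str, list[str]] = {}
for _codon, _aa in AA_OF.items():
    if _aa != "*":
        _FAMILY.setdefault(_aa, []).append(_codon)
_DEGENERACY = {aa: len(cods) for aa, cods in _FAMILY.items()}
_CLASS_WEIGHT = {2: 9, 3: 1, 4: 5, 6: 3}  # (count of amino acids per class)


def effective_number_of_codons(cds: str) -> float:
    """Wright's ENC in [20, 61]; 20 = one codon per amino acid, 61 = none.

    Per amino acid with n >= 2 observations, F-hat = (n * sum p^2 - 1)/(n - 1);
    class means over amino acids; a class with no estimate is imputed
    from the average of the observed F values (the threefold class from
    the mean of the two- and fourfold classes, as is standard); result
    capped to [20, 61].
    """
    if len(cds) % 3:
        raise ValueError("length not divisible by 3")
    counts: dict[str, dict[str, int]] = {}
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        aa = AA_OF.get(codon)
        if aa is None or aa == "*":
            continue
        counts.setdefault(aa, {}).setdefault(codon, 0)
        counts[aa][codon] += 1

    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    all_f: list[float] = []
    for aa, cc in counts.items():
        deg = _DEGENERACY[aa]
        if deg == 1:
            continue
        n = sum(cc.values())
        if n < 2:
            continue
        sum_p2 = sum((c / n) ** 2 for c in cc.values())
        f_hat = (n * sum_p2 - 1) / (n - 1)
        if f_hat <= 0:
            continue
        f_by_class[deg].append(f_hat)
        all_f.append(f_hat)

    means: dict[int, float] = {}
    for deg in (2, 3, 4, 6):
        if f_by_class[deg]:
            means[deg] = sum(f_by_class[deg]) / len(f_by_class[deg])
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    global_mean = (sum(all_f) / len(all_f)) if all_f else 1.0
    for deg in (2, 3, 4, 6):
        means.setdefault(deg, global_mean)

    enc = 2.0 + sum(_CLASS_WEIGHT[d] / means[d] for d in (2, 3, 4, 6))
    return min(61.0, max(20.0, enc))


def codon_adaptation_index(cds: str, weights: Mapping[str, float]) -> float:
    """Geometric mean of relative adaptiveness w over non-Met/Trp sense codons."""
    logs = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        aa = AA_OF.get(codon)
        if aa in (None, "*", "M", "W"):
            continue
        w = weights.get(codon)
        if w is None or w <= 0:
            raise ValueError(f"missing/invalid weight for codon {codon}")
        logs.append(math.log(w))
    if not logs:
        return 1.0
    return math.exp(sum(logs) / len(logs))


def codon_metrics(cds: str, gene_id: str = "?",
                  reference_weights: Optional[Mapping[str, float]] = None,
                  expression: Optional[float] = None,
                  want_cai: bool = False) -> GeneFeatures:
    """GC, GC3, length, ENC and (optionally) CAI for one CDS."""
    if len(cds) % 3:
        raise ValueError("length not divisible by 3")
    gc = sum(c in "GC" for c in cds) / len(cds) if cds else 0.0
    third = cds[2::3]
    gc3 = sum(c in "GC" for c in third) / len(third) if third else 0.0
    cai = None
    if want_cai or reference_weights is not None:
        if reference_weights is None:
            raise ValueError("CAI requested but no reference weights supplied")
        cai = codon_adaptation_index(cds, reference_weights)
    return GeneFeatures(gene_id, gc, gc3, len(cds),
                        effective_number_of_codons(cds), cai, expression)


def feature_correlation(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank-correlation matrix with two-sided p-values.

    Average ranks on ties; p from the t-approximation.  Constant columns
    have undefined rho and are reported as NaN.
    """
    numeric = features.select_dtypes("number")
    if len(numeric) < 5:
        raise ValueError("need at least 5 genes")
    cols = list(numeric.columns)
    k = len(cols)
    rho = np.full((k, k), np.nan)
    pval = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            x, y = numeric.iloc[:, i], numeric.iloc[:, j]
            mask = x.notna() & y.notna()
            if mask.sum() < 5 or x[mask].nunique() < 2 or y[mask].nunique() < 2:
                continue
            r, p = stats.spearmanr(x[mask], y[mask])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    for i in range(k):
        if numeric.iloc[:, i].nunique() > 1:
            rho[i, i], pval[i, i] = 1.0, 0.0
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


def pairs_to_frame(pairs: Sequence[CodingPair]) -> pd.DataFrame:
    psg, nsg, unclassified = classify_selection(pairs)
    cls = {id(p): "PSG" for p in psg}
    cls.update({id(p): "NSG" for p in nsg})
    cls.update({id(p): "unclassified" for p in unclassified})
    return pd.DataFrame([{
        "gene_a": p.gene_a, "gene_b": p.gene_b, "codons": p.codons,
        "S": p.S, "N": p.N, "Sd": p.Sd, "Nd": p.Nd,
        "dS": p.dS, "dN": p.dN,
        "omega": p.omega if p.omega is not None else float("nan"),
        "class": cls[id(p)],
    } for p in pairs])
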