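"""Insertion dating of LTR retrotransposons from paired-LTR divergence.

The two long terminal repeats of a retrotransposon are identical at
insertion and diverge afterwards at the neutral rate, so the corrected
inter-LTR distance K dates the insertion through ``T = K / (2 r)`` with
r the substitution rate per site per year.  The raw mismatch proportion
p is corrected by Jukes–Cantor, the standard practice for
insertion-time estimates; p is exposed alongside K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .selection import SaturationError, jukes_cantor

log = logging.getLogger(__name__)

#: conventional grass synonymous substitution rate (subs/site/year)
DEFAULT_RATE = 1.3e-8


@dataclass(frozen=True)
class LTRElement:
    element_id: str
    columns: int          # compared alignment columns
    p: float              # mismatch proportion
    K: float              # JC-corrected divergence, subs/site
    T: Optional[float]    # insertion time, years (None until dated)
    r: Optional[float]    # rate used for T


def ltr_divergence(ltr5: str, ltr3: str) -> tuple[float, float]:
    """Mismatch proportion and JC-corrected divergence of one LTR pair.

    The inputs are the two aligned LTRs of one element (equal length,
    >= 50 columns); alignment columns containing a gap character or N
    are dropped with a logged count.
    """
    if len(ltr5) != len(ltr3):
        raise ValueError("aligned LTRs differ in length")
    if len(ltr5) < 50:
        raise ValueError("alignment shorter than 50 columns")
    skip = {"-", "N", "n", "."}
    compared = mismatches = 0
    for x, y in zip(ltr5.upper(), ltr3.upper()):
        if x in skip or y in skip:
            continue
        compared += 1
        if x != y:
            mismatches += 1
    dropped = len(ltr5) - compared
    if dropped:
        log.info("ltr_divergence: %d gap/N columns dropped", dropped)
    if compared == 0:
        raise ValueError("no comparable columns")
    p = mismatches / compared
    return p, jukes_cantor(p)


def insertion_time(K: float, r: float = DEFAULT_RATE) -> float:
    """Years since insertion: T = K / (2 r)."""
    if r <= 0:
        raise ValueError("substitution rate must be positive")
    if K < 0:
        raise ValueError("divergence must be nonnegative")
    return K / (2.0 * r)


def date_elements(pairs: Iterable[tuple[str, str, str]],
                  r: float = DEFAULT_RATE) -> pd.DataFrame:
    """Date a cohort of (element_id, ltr5, ltr3) pairs.

    Elements whose divergence is saturated are reported with NaN K/T
    rather than aborting the cohort.
    """
    rows = []
    for eid, l5, l3 in pairs:
        try:
            p, K = ltr_divergence(l5, l3)
            T = insertion_time(K, r)
        except SaturationError:
            skip = {"-", "N", "n", "."}
            comp = [(x, y) for x, y in zip(l5.upper(), l3.upper())
                    if x not in skip and y not in skip]
            p = sum(x != y for x, y in comp) / len(comp)
            K = T = float("nan")
        rows.append({"element_id": eid, "columns": len(l5), "p": p,
                     "K": K, "T": T})
    return pd.DataFrame(rows, columns=["element_id", "columns", "p", "K", "T"])
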