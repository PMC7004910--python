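"""Standard genetic code tables shared by the simulator and the selection scan."""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]

CODONS = ["".join(c) for c in product("TCAG", repeat=3)]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)

AA_OF = dict(_TABLE.forward_table)
for _stop in STOP_CODONS:
    AA_OF[_stop] = "*"

BASES = "ACGT"


def translate(cds: str) -> str:
    """Translate an in-frame CDS (length divisible by 3, ACGT only)."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(AA_OF[cds[i:i + 3]] for i in range(0, len(cds), 3))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


@lru_cache(maxsize=None)
def single_step_changes(codon: str) -> tuple[tuple[int, str, str], ...]:
    """All nine single-nucleotide neighbours of ``codon``.

    Returns tuples (position, new_base, new_codon), including neighbours
    that are stop codons (callers decide how to treat them).
    """
    out = []
    for pos in range(3):
        for b in BASES:
            if b != codon[pos]:
                out.append((pos, b, codon[:pos] + b + codon[pos + 1:]))
    return tuple(out)
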