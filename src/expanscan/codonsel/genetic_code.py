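"""Standard genetic code tables for the 61 sense codons.

Precomputes, once at import, the index maps and pairwise relations
(single-nucleotide neighbours, transition vs transversion, synonymous vs
non-synonymous) that the codon substitution model needs.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
NT_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: The 61 sense codons of the standard code, lexicographic (ACGT) order.
CODONS: tuple[str, ...] = tuple(
    c
    for c in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in STOP_CODONS
)
N_CODONS = len(CODONS)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

#: Amino acid (one-letter) encoded by each sense codon, same order as CODONS.
CODON_AA: tuple[str, ...] = tuple(standard_dna_table.forward_table[c] for c in CODONS)

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the nucleotide change a<->b is a transition (purine<->purine
    or pyrimidine<->pyrimidine)."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _pairwise_relations():
    n = N_CODONS
    neighbour = np.zeros((n, n), dtype=bool)
    transition = np.zeros((n, n), dtype=bool)
    synonymous = np.zeros((n, n), dtype=bool)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            neighbour[i, j] = True
            transition[i, j] = is_transition(ci[k], cj[k])
            synonymous[i, j] = CODON_AA[i] == CODON_AA[j]
    return neighbour, transition, synonymous


#: Boolean 61x61 matrices: single-nucleotide neighbours, and among those,
#: transitions and synonymous changes.
IS_NEIGHBOUR, IS_TRANSITION, IS_SYNONYMOUS = _pairwise_relations()

GAP_CODON = "---"


def codon_state(codon: str) -> int:
    """Map a codon string to its state index; -1 for gap or any codon that is
    not one of the 61 unambiguous sense codons (treated as missing data)."""
    return CODON_INDEX.get(codon.upper(), -1)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for stop, 'X' otherwise."""
    c = codon.upper()
    if c in CODON_INDEX:
        return CODON_AA[CODON_INDEX[c]]
    if c in STOP_CODONS:
        return "*"
    return "X"
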