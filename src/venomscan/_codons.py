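"""Universal genetic-code tables and codon indexing helpers.

Sense codons are ordered lexicographically over the alphabet ACGT with the
three stop codons removed, giving the 61-state space used by the codon
substitution model throughout the package.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
ALL_CODONS = tuple("".join(c) for c in product(NUCLEOTIDES, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
N_SENSE = len(SENSE_CODONS)  # 61 for the universal code

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACID = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

#: (61, 3) array of nucleotide indices at the three codon positions.
CODON_NUC = np.array(
    [[NUC_INDEX[n] for n in codon] for codon in SENSE_CODONS], dtype=np.intp
)

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change ``a -> b`` is a transition."""
    return a != b and ((a in _PURINES) == (b in _PURINES))


def _neighbor_arrays():
    """Enumerate single-nucleotide-difference sense-codon pairs.

    Returns index arrays (i, j) plus boolean transition / nonsynonymous
    flags, one entry per ordered pair.
    """
    ii, jj, ts, ns = [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            ii.append(i)
            jj.append(j)
            ts.append(is_transition(ci[k], cj[k]))
            ns.append(AMINO_ACID[i] != AMINO_ACID[j])
    return (
        np.array(ii, dtype=np.intp),
        np.array(jj, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(ns, dtype=bool),
    )


NEIGHBOR_I, NEIGHBOR_J, NEIGHBOR_TS, NEIGHBOR_NS = _neighbor_arrays()

GAP_CHARS = set("-.")
AMBIGUOUS_NUCS = set("NRYSWKMBDHVX")


def codon_state(codon: str) -> int:
    """Map a codon string to its sense-codon index.

    Returns -1 (missing) for gap-containing or IUPAC-ambiguous codons.
    Raises ``ValueError`` for stop codons or unrecognized characters.
    """
    cu = codon.upper()
    if any(ch in GAP_CHARS or ch in AMBIGUOUS_NUCS for ch in cu):
        return -1
    idx = CODON_INDEX.get(cu)
    if idx is None:
        if cu in STOP_CODONS:
            raise ValueError(f"stop codon {cu!r}")
        raise ValueError(f"unrecognized codon {cu!r}")
    return idx
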