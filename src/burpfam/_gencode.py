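"""Standard genetic code tables shared across the codon-level modules.

Everything here is derived once, at import time, from Biopython's standard
codon table so the codon ordering is fixed and reproducible: the 61 sense
codons in lexicographic (T, C, A, G ordering is *not* used — plain A<C<G<T
lexicographic order keeps indexing obvious).
"""

from __future__ import annotations

import itertools

from Bio.Data import CodonTable

NUCS = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_standard.stop_codons)

#: the 61 sense codons, lexicographic order, fixed for the whole package
SENSE_CODONS = tuple(
    c for c in ("".join(t) for t in itertools.product(NUCS, repeat=3))
    if c not in STOP_CODONS
)
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

CODON_TO_AA = dict(_standard.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: two-base prefixes whose four completions all encode the same amino acid
FOURFOLD_PREFIXES = frozenset(
    p for p in ("".join(t) for t in itertools.product(NUCS, repeat=2))
    if len({CODON_TO_AA[p + n] for n in NUCS}) == 1
    and all(p + n not in STOP_CODONS for n in NUCS)
)


def is_transition(a: str, b: str) -> bool:
    """True for A<->G or C<->T; False for transversions and identities."""
    if a == b:
        return False
    pair = {a, b}
    return pair <= PURINES or pair <= PYRIMIDINES


def is_transversion(a: str, b: str) -> bool:
    return a != b and not is_transition(a, b)


def translate_codon(codon: str) -> str:
    """Translate one codon; any N/ambiguity yields 'X'."""
    codon = codon.upper()
    if codon in CODON_TO_AA:
        return CODON_TO_AA[codon]
    return "X"


def translate_cds(seq: str) -> str:
    """Translate a CDS in frame 0 (no stop trimming)."""
    return "".join(translate_codon(seq[i : i + 3]) for i in range(0, len(seq) - 2, 3))


def revcomp(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]
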