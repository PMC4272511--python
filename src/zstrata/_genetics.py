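"""Genetic-code helpers shared by the codon-evolution and simulation modules.

Standard (NCBI table 1) code only; codons containing N or gaps are excluded
from all counts by the callers.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid; stop codons map to '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS = tuple(sorted(c for c in CODON_TO_AA if c not in STOP_CODONS))

#: amino acid -> tuple of synonymous codons (sense codons only)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    SYNONYMOUS_FAMILIES.setdefault(CODON_TO_AA[_codon], ())
SYNONYMOUS_FAMILIES = {
    aa: tuple(c for c in SENSE_CODONS if CODON_TO_AA[c] == aa)
    for aa in SYNONYMOUS_FAMILIES
}


def is_transition(a: str, b: str) -> bool:
    """True if a<->b is a purine-purine or pyrimidine-pyrimidine change."""
    return (a in PURINES) == (b in PURINES) and a != b


@lru_cache(maxsize=None)
def single_mutants(codon: str, position: int) -> tuple[str, ...]:
    """The three codons reachable by changing `position` of `codon`."""
    return tuple(
        codon[:position] + b + codon[position + 1 :]
        for b in NUCLEOTIDES
        if b != codon[position]
    )


@lru_cache(maxsize=None)
def synonymous_site_fractions(codon: str) -> tuple[float, float]:
    """Nei-Gojobori fractional (synonymous, nonsynonymous) sites of a codon.

    Each of the three positions contributes the fraction of its non-stop
    single-nucleotide changes that are synonymous. Changes into stop codons
    are excluded from the denominator; a position whose every change creates
    a stop contributes nothing.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    syn = 0.0
    total = 0.0
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        mutants = [m for m in single_mutants(codon, pos) if m not in STOP_CODONS]
        if not mutants:
            continue
        frac = sum(1 for m in mutants if CODON_TO_AA[m] == aa) / len(mutants)
        syn += frac
        total += 1.0
    return syn, total - syn
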