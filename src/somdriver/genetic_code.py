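"""Single-nucleotide mutation space of the standard genetic code.

Every non-stop codon can mutate in 9 ways (3 positions x 3 alternative
nucleotides).  Classifying each possible mutation as silent, missense or
nonsense yields the expected class proportions under the simplifying
assumption that all single-nucleotide substitutions are equally likely.
These proportions drive the per-gene background-correction factors and
the nonsense-mutation probability used by the truncation test.

The counts are recomputed from the enumeration at import time rather than
hard-coded, so downstream constants always reflect the actual code table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Data import CodonTable

BASES = "ACGT"


@dataclass(frozen=True)
class CodonMutationTable:
    """Counts of all possible single-nucleotide codon mutations by consequence.

    Attributes
    ----------
    n_non_stop_codons
        Number of codons that encode an amino acid (61 for the standard code).
    n_missense, n_nonsense, n_silent
        Mutation counts per consequence class.
    """

    n_non_stop_codons: int
    n_missense: int
    n_nonsense: int
    n_silent: int

    @property
    def n_total(self) -> int:
        return self.n_missense + self.n_nonsense + self.n_silent

    @property
    def expected_sil_to_mis(self) -> float:
        """Expected silent/missense ratio in a gene under neutrality."""
        return self.n_silent / self.n_missense

    @property
    def expected_sil_to_non(self) -> float:
        """Expected silent/nonsense ratio in a gene under neutrality."""
        return self.n_silent / self.n_nonsense

    @property
    def p_nonsense(self) -> float:
        """Probability that a random substitution creates a stop codon."""
        return self.n_nonsense / self.n_total


def _all_codons() -> list[str]:
    return [a + b + c for a in BASES for b in BASES for c in BASES]


def enumerate_codon_mutation_space(
    codon_order: Sequence[str] | None = None,
) -> CodonMutationTable:
    """Exhaustively classify every single-nucleotide codon mutation.

    Parameters
    ----------
    codon_order
        Optional iteration order over the 64 codons; the result is
        independent of it (exposed for property testing).

    Returns
    -------
    CodonMutationTable
        Class counts plus the derived neutral ratios.
    """
    code = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
    stop_codons = set(code.stop_codons)
    translate = code.forward_table

    codons: Iterable[str] = codon_order if codon_order is not None else _all_codons()
    n_non_stop = n_mis = n_non = n_sil = 0
    for codon in codons:
        if codon in stop_codons:
            continue
        n_non_stop += 1
        aa = translate[codon]
        for pos in range(3):
            for base in BASES:
                if base == codon[pos]:
                    continue
                mutant = codon[:pos] + base + codon[pos + 1 :]
                if mutant in stop_codons:
                    n_non += 1
                elif translate[mutant] == aa:
                    n_sil += 1
                else:
                    n_mis += 1
    return CodonMutationTable(
        n_non_stop_codons=n_non_stop,
        n_missense=n_mis,
        n_nonsense=n_non,
        n_silent=n_sil,
    )


#: Module-level table for the standard genetic code, computed at import.
STANDARD_CODE: CodonMutationTable = enumerate_codon_mutation_space()
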