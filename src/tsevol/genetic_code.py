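"""Standard genetic code tables shared across modules.

Codon/amino-acid mappings come from Biopython's NCBI table 1 (the standard
code); everything downstream (site counting, Fop, translation checks) reads
from these frozen structures so all modules agree on what a sense codon is.
"""

from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"

_TABLE = unambiguous_dna_by_id[1]

#: sense codon -> one-letter amino acid (61 entries, standard code)
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)

#: the three stop codons of the standard code
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> tuple of codons encoding it (lexicographic)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _aa = CODON_TO_AA[_codon]
    AA_TO_CODONS[_aa] = AA_TO_CODONS.get(_aa, ()) + (_codon,)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


def split_codons(nucleotides: str) -> list[str]:
    """Split a nucleotide string into consecutive triplets.

    Raises ValueError if the length is not a multiple of 3.
    """
    if len(nucleotides) % 3 != 0:
        raise ValueError(
            f"sequence length {len(nucleotides)} is not a multiple of 3"
        )
    return [nucleotides[i : i + 3] for i in range(0, len(nucleotides), 3)]
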