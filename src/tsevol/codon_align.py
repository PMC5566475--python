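"""Codon-level pairwise alignment by protein alignment and back-translation.

Each duplicate pair is translated, the proteins are globally aligned
(BLOSUM62, affine gaps), and the alignment is mapped back onto the source
codons so that every aligned column is either a codon triplet or a full gap
triplet "---". Downstream substitution-rate estimation uses only the gapless
columns, following the usual convention of dropping gapped codon sites.

Alignment is deterministic: the two proteins are aligned in a canonical
order (sorted), so align(a, b) and align(b, a) are exact mirror images.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio.Align import PairwiseAligner, substitution_matrices

from tsevol.duplicates import CodingSequence, is_full_length
from tsevol.genetic_code import CODON_TO_AA, STOP_CODONS, split_codons

GAP_CODON = "---"


@dataclass
class CodonAlignment:
    gene_a: str
    gene_b: str
    #: aligned codon columns; each entry is (codon_a, codon_b), "---" for gaps
    columns: list[tuple[str, str]]

    def gapless_columns(self) -> list[tuple[str, str]]:
        return [c for c in self.columns if GAP_CODON not in c]

    def row(self, which: int) -> str:
        return "".join(col[which] for col in self.columns)

    def ungapped(self, which: int) -> str:
        return self.row(which).replace("-", "")


def translate(cds: CodingSequence, table: int = 1) -> str:
    """Translate a full-length CDS, dropping the terminal stop.

    Raises ValueError on ambiguous bases, internal stops, missing start/stop
    or a length not divisible by 3.
    """
    if table != 1:
        raise ValueError("only the standard genetic code (table 1) is supported")
    seq = cds.nucleotides
    if "N" in seq:
        raise ValueError(f"{cds.gene_id}: ambiguous base in CDS")
    codons = split_codons(seq)
    if codons[0] != "ATG":
        raise ValueError(f"{cds.gene_id}: CDS does not start with ATG")
    if codons[-1] not in STOP_CODONS:
        raise ValueError(f"{cds.gene_id}: CDS does not end with a stop codon")
    body = codons[:-1]
    residues = []
    for k, codon in enumerate(body):
        if codon in STOP_CODONS:
            raise ValueError(f"{cds.gene_id}: internal stop codon at codon {k}")
        residues.append(CODON_TO_AA[codon])
    return "".join(residues)


@lru_cache(maxsize=1)
def _protein_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # first gap residue costs open + extend, later residues extend
    aligner.open_gap_score = gap_open + gap_extend
    aligner.extend_gap_score = gap_extend
    return aligner


def align_proteins(
    a: str, b: str, gap_open: float = -10.0, gap_extend: float = -1.0
) -> tuple[str, str]:
    """Optimal global pairwise protein alignment (BLOSUM62, affine gaps).

    Returns the two gapped rows. Deterministic: inputs are aligned in sorted
    order and swapped back, so the result is symmetric up to row exchange.
    """
    if not a or not b:
        raise ValueError("cannot align an empty protein")
    swap = b < a
    x, y = (b, a) if swap else (a, b)
    aligner = _protein_aligner(gap_open, gap_extend)
    aln = aligner.align(x, y)[0]
    row_x, row_y = str(aln[0]), str(aln[1])
    return (row_y, row_x) if swap else (row_x, row_y)


def _backtranslate_row(row: str, cds: CodingSequence, gene: str, other: str) -> list[str]:
    body = split_codons(cds.nucleotides)[:-1]  # strip the stop codon
    out: list[str] = []
    k = 0
    for pos, residue in enumerate(row):
        if residue == "-":
            out.append(GAP_CODON)
            continue
        if k >= len(body) or CODON_TO_AA[body[k]] != residue:
            raise ValueError(
                f"protein/CDS mismatch for {gene} at alignment column {pos}: "
                f"residue {residue!r} does not match codon "
                f"{body[k] if k < len(body) else '<end>'}"
            )
        out.append(body[k])
        k += 1
    if k != len(body):
        raise ValueError(f"protein row for {gene} shorter than CDS ({k} of {len(body)} codons)")
    return out


def backtranslate(
    alignment: tuple[str, str], cds_a: CodingSequence, cds_b: CodingSequence
) -> CodonAlignment:
    """Map a protein alignment back onto its source codons.

    The ungapped protein rows must equal translate(cds) exactly; the first
    discordant position is named otherwise.
    """
    row_a, row_b = alignment
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows have different lengths")
    codons_a = _backtranslate_row(row_a, cds_a, cds_a.gene_id, cds_b.gene_id)
    codons_b = _backtranslate_row(row_b, cds_b, cds_b.gene_id, cds_a.gene_id)
    return CodonAlignment(
        gene_a=cds_a.gene_id,
        gene_b=cds_b.gene_id,
        columns=list(zip(codons_a, codons_b)),
    )


def align_pair(cds_a: CodingSequence, cds_b: CodingSequence) -> CodonAlignment:
    """Translate, align and back-translate one duplicate pair."""
    for cds in (cds_a, cds_b):
        if not is_full_length(cds):
            raise ValueError(f"{cds.gene_id}: not a full-length CDS")
    return backtranslate(
        align_proteins(translate(cds_a), translate(cds_b)), cds_a, cds_b
    )
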