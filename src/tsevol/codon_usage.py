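"""Codon usage bias (Fop) and amino-acid length.

Fop is the fraction of a gene's codons that are the designated optimal codon,
counted only over codons whose amino acid has a designated optimal codon.
Amino acids with a single codon (Met, Trp) and stop codons never enter the
numerator or denominator. A CDS enters the analysis only if it starts with
ATG, ends with TAA/TAG/TGA, and contains no premature stop or ambiguous
codon.

The optimal-codon set can be supplied from a table or derived from the data:
for each degenerate amino acid, the codon with the highest relative frequency
among the most highly expressed genes (top fraction, default 5%), ties broken
lexicographically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from tsevol.duplicates import CodingSequence
from tsevol.genetic_code import AA_TO_CODONS, CODON_TO_AA, STOP_CODONS, split_codons

SINGLE_CODON_AAS = frozenset(aa for aa, codons in AA_TO_CODONS.items() if len(codons) == 1)

#: Default optimal codons in the dicot style (largely C/T-ending); prefer
#: deriving the set from your own expression data when a matrix is available.
BUILTIN_DICOT_OPTIMAL = {
    "A": "GCT", "R": "AGA", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAA", "E": "GAG", "G": "GGA", "H": "CAC", "I": "ATC",
    "L": "CTT", "K": "AAG", "F": "TTC", "P": "CCA", "S": "TCT",
    "T": "ACT", "Y": "TAC", "V": "GTT",
}


@dataclass
class OptimalCodonSet:
    """Amino acid -> designated optimal codon, for degenerate amino acids."""

    codons: dict[str, str]
    provenance: str = "derived"

    def __post_init__(self) -> None:
        for aa, codon in self.codons.items():
            if CODON_TO_AA.get(codon) != aa:
                raise ValueError(f"codon {codon!r} does not encode {aa!r}")
            if aa in SINGLE_CODON_AAS:
                raise ValueError(f"{aa!r} has a single codon and cannot have an optimal one")


def builtin_optimal_codons() -> OptimalCodonSet:
    return OptimalCodonSet(dict(BUILTIN_DICOT_OPTIMAL), provenance="builtin:dicot")


@dataclass
class CodonUsageRecord:
    gene_id: str
    valid: bool
    reason: str | None
    fop: float  # NaN when invalid or no countable codon
    aa_length: int  # -1 when invalid


def validate_for_codon_analysis(cds: CodingSequence) -> tuple[bool, str | None]:
    """Validity checks in order: length, start, stop, ambiguity, internal stop.

    Returns (valid, first failing reason or None).
    """
    seq = cds.nucleotides
    if len(seq) % 3 != 0 or len(seq) < 6:
        return False, "length"
    codons = split_codons(seq)
    if codons[0] != "ATG":
        return False, "start"
    if codons[-1] not in STOP_CODONS:
        return False, "stop"
    for codon in codons[:-1]:
        if "N" in codon:
            return False, "ambiguous"
    for codon in codons[1:-1]:
        if codon in STOP_CODONS:
            return False, "internal_stop"
    return True, None


def aa_length(cds: CodingSequence) -> int:
    """Protein length of a valid CDS: codon count minus the stop codon."""
    valid, reason = validate_for_codon_analysis(cds)
    if not valid:
        raise ValueError(f"{cds.gene_id}: invalid CDS ({reason})")
    return len(cds.nucleotides) // 3 - 1


def compute_fop(cds: CodingSequence, opt: OptimalCodonSet) -> float:
    """Frequency of optimal codons of a valid CDS.

    Counts codons (start included, stop excluded) whose amino acid appears in
    the optimal set; NaN if no codon is countable.
    """
    valid, reason = validate_for_codon_analysis(cds)
    if not valid:
        raise ValueError(f"{cds.gene_id}: invalid CDS ({reason})")
    body = split_codons(cds.nucleotides)[:-1]
    countable = 0
    optimal = 0
    for codon in body:
        aa = CODON_TO_AA[codon]
        designated = opt.codons.get(aa)
        if designated is None:
            continue
        countable += 1
        if codon == designated:
            optimal += 1
    if countable == 0:
        return math.nan
    return optimal / countable


def derive_optimal_codons(
    cdss: list[CodingSequence],
    expression: dict[str, float],
    top_fraction: float = 0.05,
) -> OptimalCodonSet:
    """Derive the optimal codon per degenerate amino acid from highly
    expressed genes.

    Uses the top_fraction most highly expressed valid CDSs (at least one);
    for each amino acid with >= 2 codons, the most frequent codon wins, ties
    broken lexicographically.
    """
    if not expression:
        raise ValueError(
            "no expression data: supply an expression level per gene or use a "
            "built-in optimal-codon table"
        )
    if not 0 < top_fraction <= 0.5:
        raise ValueError("top_fraction must be in (0, 0.5]")
    valid = [c for c in cdss if validate_for_codon_analysis(c)[0] and c.gene_id in expression]
    if len(valid) < 10:
        raise ValueError(f"need >= 10 valid CDSs with expression data, got {len(valid)}")
    valid.sort(key=lambda c: (-expression[c.gene_id], c.gene_id))
    k = max(1, int(math.floor(top_fraction * len(valid))))
    counts: dict[str, int] = {}
    for cds in valid[:k]:
        for codon in split_codons(cds.nucleotides)[:-1]:
            counts[codon] = counts.get(codon, 0) + 1
    chosen: dict[str, str] = {}
    for aa, codons in AA_TO_CODONS.items():
        if len(codons) < 2:
            continue
        # deterministic: highest count, ties -> lexicographically smallest
        best = sorted(codons, key=lambda c: (-counts.get(c, 0), c))[0]
        chosen[aa] = best
    return OptimalCodonSet(chosen, provenance="derived")


def usage_table(
    cdss: list[CodingSequence], opt: OptimalCodonSet
) -> pd.DataFrame:
    """Per-gene validity, Fop and amino-acid length table."""
    rows = []
    for cds in cdss:
        valid, reason = validate_for_codon_analysis(cds)
        if valid:
            rows.append(
                CodonUsageRecord(cds.gene_id, True, None, compute_fop(cds, opt), aa_length(cds))
            )
        else:
            rows.append(CodonUsageRecord(cds.gene_id, False, reason, math.nan, -1))
    return pd.DataFrame([vars(r) for r in rows])
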