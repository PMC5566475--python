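"""Duplicate gene-pair detection from all-vs-all CDS similarity.

Candidate pairs are found by a shared-word (k-mer, default 11) prefilter and
then locally aligned (match +1, mismatch -2, affine gaps). A pair is retained
as a duplicate when identity > 80%, aligned length > 80% of the longer
sequence, and the alignment significance (a Karlin-Altschul style E-value on
the ungapped scoring system, database size = total residues searched) is at
most 1e-10. The significance criterion can be disabled, since exact E-values
are scoring-dialect dependent; identity and coverage then decide alone.

Retained pairs whose two members are both tissue-specific are labeled
homogeneous (same expressing tissue) or heterogeneous (different tissues) and
by composition: somatic/somatic, sex/sex, or somatic/sex.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from Bio import SeqIO
from Bio.Align import PairwiseAligner
from scipy.optimize import brentq

from tsevol.expression import (
    GROUP_SEX,
    STATUS_TISSUE_SPECIFIC,
    GeneClassification,
)
from tsevol.genetic_code import CODON_TO_AA, STOP_CODONS, split_codons

logger = logging.getLogger(__name__)

CDS_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True)
class CodingSequence:
    gene_id: str
    nucleotides: str

    def __post_init__(self) -> None:
        if not self.nucleotides:
            raise ValueError(f"{self.gene_id}: empty sequence")
        extra = set(self.nucleotides) - CDS_ALPHABET
        if extra:
            raise ValueError(f"{self.gene_id}: invalid characters {sorted(extra)}")

    def __len__(self) -> int:
        return len(self.nucleotides)


@dataclass
class DuplicatePair:
    """An unordered gene pair passing the duplicate criteria."""

    gene_a: str
    gene_b: str
    identity: float  # percent of aligned columns that match
    coverage: float  # aligned columns as percent of the longer sequence
    significance: float  # E-value style score (math.nan when disabled)
    score: float = 0.0
    aligned_length: int = 0
    expression_class: str | None = None  # homogeneous | heterogeneous
    composition: str | None = None  # somatic_somatic | sex_sex | somatic_sex

    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.gene_a, self.gene_b)))  # type: ignore[return-value]


@dataclass(frozen=True)
class AlignmentParams:
    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0  # opening cost; first gap residue costs gap_open + gap_extend
    gap_extend: float = -2.0
    word_size: int = 11
    evalue_k: float = 0.1  # Karlin-Altschul K for the ungapped system
    use_significance: bool = True


def read_cds_fasta(path) -> list[CodingSequence]:
    """Read coding sequences from a FASTA file (uppercased)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(CodingSequence(gene_id=rec.id, nucleotides=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def is_full_length(cds: CodingSequence) -> bool:
    """True iff the CDS is a complete reading frame.

    Length divisible by 3, starts ATG, ends with a stop codon, no internal
    stop and no ambiguous base.
    """
    seq = cds.nucleotides
    if len(seq) % 3 != 0 or len(seq) < 6:
        return False
    if "N" in seq:
        return False
    codons = split_codons(seq)
    if codons[0] != "ATG" or codons[-1] not in STOP_CODONS:
        return False
    return all(c in CODON_TO_AA for c in codons[1:-1])


def _karlin_altschul_lambda(match: float, mismatch: float) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for uniform base frequencies."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * match) + 0.75 * math.exp(lam * mismatch) - 1.0

    return brentq(f, 1e-6, 10.0)


def _evalue(score: float, query_len: int, db_len: int, params: AlignmentParams) -> float:
    lam = _karlin_altschul_lambda(params.match, params.mismatch)
    return params.evalue_k * query_len * db_len * math.exp(-lam * score)


def _kmer_candidates(cdss: list[CodingSequence], word_size: int) -> set[tuple[int, int]]:
    """Index sequences by k-mers; candidate pairs share at least one word."""
    index: dict[str, list[int]] = {}
    for i, cds in enumerate(cdss):
        seq = cds.nucleotides
        seen = set()
        for p in range(len(seq) - word_size + 1):
            word = seq[p : p + word_size]
            if word not in seen:
                seen.add(word)
                index.setdefault(word, []).append(i)
    pairs: set[tuple[int, int]] = set()
    for members in index.values():
        if len(members) > 1:
            for x in range(len(members)):
                for y in range(x + 1, len(members)):
                    pairs.add((members[x], members[y]))
    return pairs


def _make_aligner(params: AlignmentParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def all_vs_all(
    cdss: list[CodingSequence], params: AlignmentParams = AlignmentParams()
) -> list[DuplicatePair]:
    """All-vs-all candidate duplicate hits.

    Self-hits are excluded; each unordered pair yields at most one hit (the
    best-scoring local alignment, aligned in canonical gene-ID order so the
    result is invariant to input order). Sequences not sharing any word of
    ``params.word_size`` are never aligned and produce no hit.
    """
    if len(cdss) < 2:
        raise ValueError("need at least 2 sequences for all-vs-all comparison")
    ids = [c.gene_id for c in cdss]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene IDs in CDS set")

    order = sorted(range(len(cdss)), key=lambda i: cdss[i].gene_id)
    cdss = [cdss[i] for i in order]

    aligner = _make_aligner(params)
    db_len = sum(len(c) for c in cdss)
    hits: list[DuplicatePair] = []
    for i, j in sorted(_kmer_candidates(cdss, params.word_size)):
        a, b = cdss[i], cdss[j]
        alignments = aligner.align(a.nucleotides, b.nucleotides)
        aln = alignments[0]
        counts = aln.counts()
        columns = aln.length
        if columns == 0:
            continue
        identity = 100.0 * counts.identities / columns
        coverage = 100.0 * columns / max(len(a), len(b))
        sig = (
            _evalue(aln.score, len(a), db_len, params)
            if params.use_significance
            else math.nan
        )
        hits.append(
            DuplicatePair(
                gene_a=a.gene_id,
                gene_b=b.gene_id,
                identity=identity,
                coverage=coverage,
                significance=sig,
                score=float(aln.score),
                aligned_length=int(columns),
            )
        )
    return hits


def apply_criteria(
    hits: list[DuplicatePair],
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
    max_significance: float | None = 1e-10,
) -> list[DuplicatePair]:
    """Retain hits with identity > min_identity, coverage > min_coverage
    (strict inequalities) and significance <= max_significance.

    Passing ``max_significance=None`` (or hits with NaN significance) skips
    the significance criterion. One pair per unordered key, best hit kept
    (score, then aligned length, then gene IDs).
    """
    best: dict[tuple[str, str], DuplicatePair] = {}
    for hit in hits:
        if not (hit.identity > min_identity and hit.coverage > min_coverage):
            continue
        if (
            max_significance is not None
            and not math.isnan(hit.significance)
            and hit.significance > max_significance
        ):
            continue
        key = hit.key()
        prev = best.get(key)
        if prev is None or (hit.score, hit.aligned_length) > (prev.score, prev.aligned_length):
            best[key] = hit
    return [best[k] for k in sorted(best)]


def label_pair(
    pair: DuplicatePair, classifications: dict[str, GeneClassification]
) -> DuplicatePair | None:
    """Attach expression_class and composition; None if a member is not
    tissue-specific (the reason is logged)."""
    for gid in (pair.gene_a, pair.gene_b):
        cls = classifications.get(gid)
        if cls is None or cls.status != STATUS_TISSUE_SPECIFIC:
            logger.info(
                "pair (%s, %s) excluded: %s is not tissue-specific",
                pair.gene_a, pair.gene_b, gid,
            )
            return None
    ca = classifications[pair.gene_a]
    cb = classifications[pair.gene_b]
    expression_class = (
        "homogeneous" if ca.specific_tissue == cb.specific_tissue else "heterogeneous"
    )
    n_sex = sum(1 for c in (ca, cb) if c.group == GROUP_SEX)
    composition = {0: "somatic_somatic", 1: "somatic_sex", 2: "sex_sex"}[n_sex]
    return replace(pair, expression_class=expression_class, composition=composition)
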