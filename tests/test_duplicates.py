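"""Full-length CDS predicate, all-vs-all hits, duplicate criteria, pair labels."""

import numpy as np
import pytest

from tsevol.duplicates import (
    AlignmentParams,
    CodingSequence,
    DuplicatePair,
    all_vs_all,
    apply_criteria,
    is_full_length,
    label_pair,
)
from tsevol.expression import GROUP_SEX, GROUP_SOMATIC, GeneClassification
from tsevol.genetic_code import CODON_TO_AA, STOP_CODONS
from tsevol.synthetic import gen_cds


# --- full-length predicate -----------------------------------------------------


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ATGAAATAA", True),
        ("ATGAAA", False),  # no stop
        ("ATGTAAAAATAA", False),  # internal stop
        ("TTGAAATAA", False),  # bad start
        ("ATGAAATAAT", False),  # frame-shifted length
        ("ATGANATAA", False),  # ambiguous base
    ],
)
def test_full_length_predicate(seq, expected):
    assert is_full_length(CodingSequence("g", seq)) is expected


# --- local smith-waterman oracle (plain DP, linear gaps irrelevant here) --------


def _sw_score(a, b, match=1.0, mismatch=-2.0, gap_open=-7.0, gap_extend=-2.0):
    """Affine-gap local alignment score by straightforward Gotoh DP."""
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.zeros((n + 1, m + 1))
    X = np.full((n + 1, m + 1), neg)  # gap in b
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend)
            M[i, j] = max(0.0, s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            best = max(best, M[i, j], X[i, j], Y[i, j])
    return best


# --- all-vs-all -----------------------------------------------------------------


def test_identical_sequences_give_full_identity_hit():
    cds = gen_cds(100, 1, "a")
    twin = CodingSequence("b", cds.nucleotides)
    hits = all_vs_all([cds, twin])
    assert len(hits) == 1
    assert hits[0].identity == pytest.approx(100.0)
    assert hits[0].coverage == pytest.approx(100.0)


def test_unrelated_sequences_without_shared_word_give_no_hit():
    a = CodingSequence("a", "ATG" + "AC" * 30 + "TAA")
    b = CodingSequence("b", "ATG" + "GT" * 30 + "TAA")
    assert all_vs_all([a, b]) == []


def test_planted_identity_is_recovered_within_two_points():
    rng = np.random.default_rng(4)
    cds = gen_cds(100, rng, "a")
    seq = list(cds.nucleotides)
    # mutate exactly 10% of codon third positions synonymously-or-not,
    # avoiding stops, for a planted identity of 90%
    positions = rng.choice(np.arange(3, len(seq) - 3), size=round(0.1 * len(seq)), replace=False)
    for p in positions:
        for base in "ACGT":
            if base == seq[p]:
                continue
            codon_start = 3 * (p // 3)
            codon = "".join(seq[codon_start : codon_start + 3])
            mutant = codon[: p % 3] + base + codon[p % 3 + 1 :]
            if mutant not in STOP_CODONS:
                seq[p] = base
                break
    other = CodingSequence("b", "".join(seq))
    hits = all_vs_all([cds, other])
    assert len(hits) == 1
    planted = 100.0 * (1 - len(positions) / len(seq))
    assert abs(hits[0].identity - planted) <= 2.0
    # score agrees with an independent Gotoh local-alignment DP
    assert hits[0].score == pytest.approx(_sw_score(cds.nucleotides, other.nucleotides))


def test_output_invariant_under_input_order(small_bundle):
    cdss = small_bundle.cdss[:40]
    forward = {(h.gene_a, h.gene_b, round(h.score, 6)) for h in all_vs_all(cdss)}
    backward = {(h.gene_a, h.gene_b, round(h.score, 6)) for h in all_vs_all(cdss[::-1])}
    assert forward == backward


def test_all_vs_all_needs_two_sequences():
    with pytest.raises(ValueError):
        all_vs_all([gen_cds(50, 0, "only")])


# --- criteria -------------------------------------------------------------------


def _hit(identity, coverage, significance=1e-20, a="a", b="b"):
    return DuplicatePair(a, b, identity=identity, coverage=coverage, significance=significance)


def test_criteria_thresholds_are_strict():
    assert apply_criteria([_hit(90, 85)]) != []
    assert apply_criteria([_hit(80.0, 95)]) == []
    assert apply_criteria([_hit(95, 80.0)]) == []
    assert apply_criteria([_hit(95, 95, significance=1e-9)]) == []
    assert apply_criteria([_hit(95, 95, significance=1e-10)]) != []


def test_criteria_output_shrinks_as_thresholds_tighten():
    rng = np.random.default_rng(9)
    hits = [
        _hit(rng.uniform(70, 100), rng.uniform(70, 100), 10.0 ** -rng.uniform(5, 30),
             a=f"a{i}", b=f"b{i}")
        for i in range(200)
    ]
    loose = {p.key() for p in apply_criteria(hits, 80, 80, 1e-10)}
    tight = {p.key() for p in apply_criteria(hits, 85, 85, 1e-15)}
    assert tight <= loose


def test_best_hit_kept_per_unordered_pair():
    hits = [
        _hit(90, 85),
        DuplicatePair("b", "a", identity=95, coverage=90, significance=1e-30, score=50),
    ]
    kept = apply_criteria(hits)
    assert len(kept) == 1
    assert kept[0].identity == 95


# --- labels ---------------------------------------------------------------------


def _cls(gene, tissue, group):
    return GeneClassification(gene, "tissue_specific", tissue, group)


def test_pair_labels_follow_tissue_and_group():
    lookup = {
        "r1": _cls("r1", "root", GROUP_SOMATIC),
        "r2": _cls("r2", "root", GROUP_SOMATIC),
        "g1": _cls("g1", "gynoecium", GROUP_SEX),
        "a1": _cls("a1", "androecium", GROUP_SEX),
    }
    same = label_pair(_hit(90, 90, a="r1", b="r2"), lookup)
    assert (same.expression_class, same.composition) == ("homogeneous", "somatic_somatic")
    mixed = label_pair(_hit(90, 90, a="g1", b="r1"), lookup)
    assert (mixed.expression_class, mixed.composition) == ("heterogeneous", "somatic_sex")
    sexes = label_pair(_hit(90, 90, a="g1", b="a1"), lookup)
    assert (sexes.expression_class, sexes.composition) == ("heterogeneous", "sex_sex")


def test_pair_with_non_specific_member_is_excluded():
    lookup = {
        "r1": _cls("r1", "root", GROUP_SOMATIC),
        "c1": GeneClassification("c1", "common"),
    }
    assert label_pair(_hit(90, 90, a="r1", b="c1"), lookup) is None
    assert label_pair(_hit(90, 90, a="r1", b="missing"), lookup) is None
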