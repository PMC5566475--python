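"""NG86 site/pathway counting, Jukes-Cantor correction, filters and grouping."""

import math
from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tsevol.codon_align import CodonAlignment
from tsevol.evolution import (
    classify_selection,
    codon_differences,
    codon_sites,
    estimate,
    group_means,
    jukes_cantor,
    ks_filter,
)
from tsevol.genetic_code import CODON_TO_AA, SENSE_CODONS

# --- independent oracle: enumerate neighbours and pathways explicitly -------


def oracle_sites(codon):
    """Fraction of the nine single-nucleotide neighbours that are synonymous,
    expressed as synonymous sites (changes into stops are nonsynonymous)."""
    synonymous_changes = 0
    for pos, original in enumerate(codon):
        for base in "ACGT":
            if base == original:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TO_AA.get(neighbour) == CODON_TO_AA[codon]:
                synonymous_changes += 1
    s = synonymous_changes / 3.0
    return s, 3.0 - s


def oracle_differences(a, b):
    """Average syn/nonsyn step counts over every ordering of the differing
    positions, excluding stop-traversing pathways when any stop-free pathway
    exists."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    stop_free, everything = [], []
    for order in permutations(positions):
        steps = []
        current = a
        hits_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if nxt not in CODON_TO_AA:
                hits_stop = True
                steps.append("nonsyn")
            elif CODON_TO_AA.get(current) == CODON_TO_AA[nxt]:
                steps.append("syn")
            else:
                steps.append("nonsyn")
            current = nxt
        record = (steps.count("syn"), steps.count("nonsyn"))
        everything.append(record)
        if not hits_stop:
            stop_free.append(record)
    pool = stop_free or everything
    return (
        sum(r[0] for r in pool) / len(pool),
        sum(r[1] for r in pool) / len(pool),
    )


# --- site counting ----------------------------------------------------------


@pytest.mark.parametrize(
    "codon,s",
    [("AAA", 1 / 3), ("ATG", 0.0), ("TGG", 0.0)],
)
def test_codon_sites_known_values(codon, s):
    got_s, got_n = codon_sites(codon)
    assert got_s == pytest.approx(s, abs=1e-12)
    assert got_s + got_n == pytest.approx(3.0, abs=1e-12)


def test_codon_sites_conserve_three_per_codon():
    for codon in SENSE_CODONS:
        s, n = codon_sites(codon)
        assert s + n == pytest.approx(3.0, abs=1e-12)
        assert s >= 0 and n >= 0


def test_codon_sites_rejects_stop_and_ambiguous():
    with pytest.raises(ValueError):
        codon_sites("TAA")
    with pytest.raises(ValueError):
        codon_sites("ANA")


# --- pathway-averaged differences -------------------------------------------


@pytest.mark.parametrize(
    "a,b,sd,nd",
    [
        ("AAA", "AAG", 1.0, 0.0),  # Lys -> Lys, single step
        ("AAA", "AAC", 0.0, 1.0),  # Lys -> Asn, single step
        ("TTA", "CTG", 2.0, 0.0),  # both two-step pathways stay within Leu
    ],
)
def test_codon_differences_known_values(a, b, sd, nd):
    assert codon_differences(a, b) == (pytest.approx(sd), pytest.approx(nd))


def test_codon_differences_conserve_and_commute():
    rng = np.random.default_rng(0)
    for _ in range(200):
        a, b = rng.choice(SENSE_CODONS, size=2)
        sd, nd = codon_differences(a, b)
        k = sum(1 for i in range(3) if a[i] != b[i])
        assert sd + nd == pytest.approx(k, abs=1e-12)
        assert codon_differences(b, a) == (pytest.approx(sd), pytest.approx(nd))


def test_codon_differences_rejects_stop():
    with pytest.raises(ValueError):
        codon_differences("TAA", "AAA")


# --- whole-alignment estimation ---------------------------------------------


def _alignment(cols):
    return CodonAlignment("x", "y", cols)


def test_ten_codon_worked_example():
    cols = [("AAA", "AAA")] * 9 + [("AAA", "AAG")]
    e = estimate(_alignment(cols))
    assert e.S == pytest.approx(10 / 3)
    assert e.N == pytest.approx(80 / 3)
    assert e.Sd == 1.0 and e.Nd == 0.0
    assert e.pS == pytest.approx(0.3)
    assert e.Ks == pytest.approx(-0.75 * math.log(0.6), abs=1e-9)
    assert e.Ka == 0.0
    assert e.omega == 0.0
    assert e.status == "ok"


def test_identical_sequences_have_undefined_omega():
    e = estimate(_alignment([("AAA", "AAA"), ("TGG", "TGG")]))
    assert e.Ka == 0.0 and e.Ks == 0.0
    assert math.isnan(e.omega)
    assert e.status == "omega_undefined"


def test_estimate_symmetric_in_sequences():
    rng = np.random.default_rng(1)
    cols = [tuple(rng.choice(SENSE_CODONS, size=2)) for _ in range(40)]
    e = estimate(_alignment(cols))
    f = estimate(_alignment([(b, a) for a, b in cols]))
    for name in ("S", "N", "Sd", "Nd", "pS", "pN"):
        assert getattr(e, name) == pytest.approx(getattr(f, name), abs=1e-12)


def test_estimate_conservation_on_random_alignments():
    rng = np.random.default_rng(2)
    for _ in range(20):
        cols = [tuple(rng.choice(SENSE_CODONS, size=2)) for _ in range(30)]
        e = estimate(_alignment(cols))
        assert e.S + e.N == pytest.approx(3 * 30, abs=1e-9)
        ndiff = sum(
            1 for a, b in cols for i in range(3) if a[i] != b[i]
        )
        assert e.Sd + e.Nd == pytest.approx(ndiff, abs=1e-9)


def test_extra_synonymous_difference_raises_ks_only():
    base = [("AAA", "AAA")] * 18 + [("AAA", "AAG")]
    more = [("AAA", "AAA")] * 17 + [("AAA", "AAG")] * 2
    e0, e1 = estimate(_alignment(base)), estimate(_alignment(more))
    assert e1.Ks > e0.Ks
    assert e1.Ka == e0.Ka == 0.0


def test_saturated_proportion_flags_estimate():
    # all third positions of four-fold codons changed: pS >> 0.75
    cols = [("GGA", "GGC"), ("GGA", "GGG"), ("GGA", "GGT")] * 5
    e = estimate(_alignment(cols))
    assert e.status == "saturated"
    assert math.isnan(e.Ks) or math.isnan(e.Ka)


def test_empty_alignment_is_an_error():
    with pytest.raises(ValueError):
        estimate(_alignment([("---", "AAA")]))


# --- JC correction, filter and selection classes -----------------------------


def test_jukes_cantor_saturates_at_three_quarters():
    assert jukes_cantor(0.0) == 0.0
    assert math.isnan(jukes_cantor(0.75))
    assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(0.6))


@pytest.mark.parametrize(
    "ks,retained,reason",
    [
        (0.005, False, "ks_too_low"),
        (0.01, True, None),
        (0.21, True, None),
        (0.30, True, None),
        (0.35, False, "ks_too_high"),
    ],
)
def test_ks_filter_boundaries(ks, retained, reason):
    e = estimate(_alignment([("AAA", "AAG")] + [("AAA", "AAA")] * 99))
    e.Ks = ks
    keep, why = ks_filter(e)
    assert keep is retained
    assert why == reason


@pytest.mark.parametrize(
    "omega,label",
    [(0.56, "purifying"), (1.0, "neutral"), (1.0 + 5e-10, "neutral"), (1.2, "positive")],
)
def test_selection_classes(omega, label):
    assert classify_selection(omega) == label


def test_selection_rejects_undefined_omega():
    with pytest.raises(ValueError):
        classify_selection(math.nan)


def test_group_means_match_direct_recomputation():
    rng = np.random.default_rng(3)
    frame = pd.DataFrame(
        {
            "Ka": rng.uniform(0, 0.2, 30),
            "Ks": rng.uniform(0.05, 0.3, 30),
            "omega": rng.uniform(0, 1.5, 30),
            "expression_class": rng.choice(["homogeneous", "heterogeneous"], 30),
        }
    )
    out = group_means(frame).set_index("expression_class")
    for cls in ("homogeneous", "heterogeneous"):
        subset = frame[frame["expression_class"] == cls]
        assert out.loc[cls, "mean_ka"] == pytest.approx(sum(subset["Ka"]) / len(subset))
        assert out.loc[cls, "mean_omega"] == pytest.approx(sum(subset["omega"]) / len(subset))


@given(st.sampled_from(SENSE_CODONS), st.sampled_from(SENSE_CODONS))
def test_pathway_counts_match_oracle(a, b):
    assert codon_differences(a, b) == (
        pytest.approx(oracle_differences(a, b)[0], abs=1e-12),
        pytest.approx(oracle_differences(a, b)[1], abs=1e-12),
    )
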