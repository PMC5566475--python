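"""Ka/Ks estimation by Nei-Gojobori (1986) counting with Jukes-Cantor correction.

Site counting: each codon position contributes (number of the 3 possible
single-nucleotide changes that are synonymous)/3 synonymous sites; changes
that create a stop codon count as nonsynonymous. Difference counting: for a
codon pair differing at k positions, synonymous/nonsynonymous differences are
averaged over all k! single-step mutational pathways, excluding pathways that
pass through a stop codon (if every pathway does, all are averaged anyway).

Proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with the
Jukes-Cantor formula d = -(3/4) ln(1 - (4/3) p); a proportion >= 0.75 is
saturated and yields no finite distance. omega = Ka/Ks is undefined when
Ks = 0 (reported as such rather than infinity); such pairs also fail the Ks
admissibility filter, which retains 0.01 <= Ks <= 0.30 by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import pandas as pd

from tsevol.codon_align import CodonAlignment
from tsevol.genetic_code import BASES, CODON_TO_AA, is_sense

SATURATION_P = 0.75
KS_LOW = 0.01
KS_HIGH = 0.30

STATUS_OK = "ok"
STATUS_KS_TOO_LOW = "ks_too_low"
STATUS_KS_TOO_HIGH = "ks_too_high"
STATUS_SATURATED = "saturated"
STATUS_OMEGA_UNDEFINED = "omega_undefined"


@dataclass
class SubstitutionEstimate:
    gene_a: str
    gene_b: str
    S: float  # synonymous sites (averaged over the two sequences)
    N: float  # nonsynonymous sites
    Sd: float  # synonymous differences
    Nd: float  # nonsynonymous differences
    pS: float
    pN: float
    Ks: float  # NaN when saturated
    Ka: float
    omega: float  # NaN when undefined
    status: str


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Per position, the synonymous fraction is (# synonymous single-nucleotide
    changes)/3; changes into stop codons are nonsynonymous. s + n = 3.
    """
    if not is_sense(codon):
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TO_AA.get(mutant) == aa:  # stop codons map to None
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def codon_differences(a: str, b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Averages over all orderings of the differing positions; pathways passing
    through a stop codon are excluded unless every pathway does.
    """
    for c in (a, b):
        if not is_sense(c):
            raise ValueError(f"not a sense codon: {c!r}")
    diff_positions = [i for i in range(3) if a[i] != b[i]]
    if not diff_positions:
        return 0.0, 0.0

    valid: list[tuple[float, float]] = []
    all_paths: list[tuple[float, float]] = []
    for order in permutations(diff_positions):
        current = a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            nxt = current[:pos] + b[pos] + current[pos + 1 :]
            if not is_sense(nxt):
                through_stop = True
                # count the step as nonsynonymous for the all-stop fallback
                nd += 1.0
            elif CODON_TO_AA.get(current) == CODON_TO_AA.get(nxt):
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        all_paths.append((sd, nd))
        if not through_stop:
            valid.append((sd, nd))

    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 distance for a raw proportion p; NaN at/above saturation (0.75)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= SATURATION_P:
        return math.nan
    if p == 0:
        return 0.0
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def estimate(alignment: CodonAlignment) -> SubstitutionEstimate:
    """NG86 substitution estimate over the gapless codon columns of a pair."""
    cols = alignment.gapless_columns()
    if not cols:
        raise ValueError(
            f"({alignment.gene_a}, {alignment.gene_b}): no gapless codon columns"
        )
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for codon_a, codon_b in cols:
        sa, na = codon_sites(codon_a)
        sb, nb = codon_sites(codon_b)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        d_s, d_n = codon_differences(codon_a, codon_b)
        sd += d_s
        nd += d_n
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    Ks = jukes_cantor(pS)
    Ka = jukes_cantor(pN)

    if math.isnan(Ks) or math.isnan(Ka):
        status = STATUS_SATURATED
        omega = math.nan
    elif Ks == 0.0:
        status = STATUS_OMEGA_UNDEFINED
        omega = math.nan
    else:
        status = STATUS_OK
        omega = Ka / Ks
    return SubstitutionEstimate(
        gene_a=alignment.gene_a,
        gene_b=alignment.gene_b,
        S=S,
        N=N,
        Sd=sd,
        Nd=nd,
        pS=pS,
        pN=pN,
        Ks=Ks,
        Ka=Ka,
        omega=omega,
        status=status,
    )


def ks_filter(
    e: SubstitutionEstimate, low: float = KS_LOW, high: float = KS_HIGH
) -> tuple[bool, str | None]:
    """Admissibility filter on Ks: retained iff low <= Ks <= high.

    Exclusion is strict (< low or > high); the boundaries are retained.
    Saturated estimates (no finite Ks) are excluded as saturated.
    """
    if math.isnan(e.Ks):
        return False, STATUS_SATURATED
    if e.Ks < low:
        return False, STATUS_KS_TOO_LOW
    if e.Ks > high:
        return False, STATUS_KS_TOO_HIGH
    return True, None


def classify_selection(omega: float, tol: float = 1e-9) -> str:
    """purifying (omega < 1), neutral (omega = 1 within tol), positive (> 1)."""
    if omega is None or math.isnan(omega):
        raise ValueError("omega is undefined")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    if abs(omega - 1.0) <= tol:
        return "neutral"
    return "purifying" if omega < 1.0 else "positive"


def estimates_to_frame(estimates: list[SubstitutionEstimate]) -> pd.DataFrame:
    return pd.DataFrame([vars(e) for e in estimates])


def group_means(estimates: pd.DataFrame, by: str = "expression_class") -> pd.DataFrame:
    """Arithmetic mean Ka, Ks and omega per group over retained estimates.

    ``estimates`` is the per-pair table (one row per retained pair) carrying
    the grouping column (expression_class or composition). Empty groups are
    simply absent from the output.
    """
    if by not in estimates.columns:
        raise ValueError(f"missing grouping column {by!r}")
    grouped = estimates.groupby(by)[["Ka", "Ks", "omega"]].mean()
    grouped.columns = ["mean_ka", "mean_ks", "mean_omega"]
    return grouped.reset_index()
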