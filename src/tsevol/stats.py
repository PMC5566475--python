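"""Rank-based two-group and k-group comparisons.

Mann-Whitney U: two-sided, mid-ranks for ties. Exact p-values are obtained by
full enumeration of rank splits (used automatically when both samples have at
most 8 observations); otherwise a normal approximation with tie correction
and, by default, continuity correction. Kruskal-Wallis: H with tie
correction, p from a chi-square with k-1 degrees of freedom. Significance is
judged at alpha = 0.05 and no multiple-testing adjustment is applied across
the report's comparisons (raw p-values are reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_ALPHA = 0.05
EXACT_LIMIT = 8


@dataclass
class ComparisonResult:
    test: str  # mann_whitney_u | kruskal_wallis
    statistic: float  # U (min of U1, U2) or H
    p_value: float
    group_sizes: tuple[int, ...]
    significant: bool
    alpha: float = DEFAULT_ALPHA


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumeration of all rank splits.

    Handles ties through mid-ranks: p = P(|U - nm/2| >= |u_obs - nm/2|) over
    all C(n+m, n) equally likely assignments of the pooled ranks to x.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    center = n * m / 2.0
    t_obs = abs(u_obs - center)
    hits = 0
    total = 0
    for sel in combinations(range(n + m), n):
        u = ranks[list(sel)].sum() - n * (n + 1) / 2.0
        if abs(u - center) >= t_obs - 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total


def _approx_mwu_p(
    x: np.ndarray, y: np.ndarray, use_continuity: bool = True
) -> tuple[float, float]:
    """Normal approximation with tie correction (and optional continuity)."""
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=use_continuity
    )
    n, m = len(x), len(y)
    u1 = float(res.statistic)
    return u1, float(res.pvalue)


def mann_whitney_u(
    x,
    y,
    mode: str = "auto",
    alpha: float = DEFAULT_ALPHA,
    use_continuity: bool = True,
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    mode: "exact" (full enumeration), "approximate" (normal approximation
    with tie correction), or "auto" (exact when both n, m <= 8).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if mode not in {"exact", "approximate", "auto"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "auto":
        mode = "exact" if max(len(x), len(y)) <= EXACT_LIMIT else "approximate"
    if mode == "exact":
        u1, p = _exact_mwu_p(x, y)
    else:
        u1, p = _approx_mwu_p(x, y, use_continuity=use_continuity)
    u = min(u1, len(x) * len(y) - u1)
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return ComparisonResult(
        test="mann_whitney_u",
        statistic=float(u),
        p_value=float(p),
        group_sizes=(len(x), len(y)),
        significant=p < alpha,
        alpha=alpha,
    )


def kruskal_wallis(groups, alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square p with k-1 df)."""
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = sps.kruskal(*groups)
    p = min(max(float(p), np.nextafter(0.0, 1.0)), 1.0)
    return ComparisonResult(
        test="kruskal_wallis",
        statistic=float(h),
        p_value=p,
        group_sizes=tuple(len(g) for g in groups),
        significant=p < alpha,
        alpha=alpha,
    )


def _direction(label_a: str, a, label_b: str, b) -> str:
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if med_a > med_b:
        return f"{label_a} > {label_b}"
    if med_a < med_b:
        return f"{label_a} < {label_b}"
    return f"{label_a} = {label_b}"


def _row(name: str, result: ComparisonResult | None, direction: str) -> dict:
    if result is None:  # an empty group: no test possible for this dataset
        return {
            "comparison": name,
            "test": None,
            "statistic": math.nan,
            "p_value": math.nan,
            "direction": "n/a",
            "significant": False,
        }
    return {
        "comparison": name,
        "test": result.test,
        "statistic": result.statistic,
        "p_value": result.p_value,
        "direction": direction,
        "significant": result.significant,
    }


def _mwu_row(name: str, label_a: str, a, label_b: str, b, alpha: float) -> dict:
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        return _row(name, None, "n/a")
    return _row(name, mann_whitney_u(a, b, alpha=alpha), _direction(label_a, a, label_b, b))


def _kw_row(name: str, groups, alpha: float) -> dict:
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2 or sum(len(g) for g in groups) < 3:
        return _row(name, None, "n/a")
    return _row(name, kruskal_wallis(groups, alpha=alpha), "n/a")


def rate_comparisons(estimates: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.DataFrame:
    """Homogeneous-vs-heterogeneous contrasts of Ka, Ks and omega."""
    rows = []
    homo = estimates[estimates["expression_class"] == "homogeneous"]
    het = estimates[estimates["expression_class"] == "heterogeneous"]
    for metric in ("Ka", "Ks", "omega"):
        a = homo[metric].dropna()
        b = het[metric].dropna()
        if len(a) == 0 or len(b) == 0:
            continue
        res = mann_whitney_u(a, b, alpha=alpha)
        rows.append(
            _row(
                f"{metric.lower()}_homogeneous_vs_heterogeneous",
                res,
                _direction("homogeneous", a, "heterogeneous", b),
            )
        )
    return pd.DataFrame(rows)


def compare_report(
    classification: pd.DataFrame,
    usage: pd.DataFrame,
    estimates: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """The nine headline comparisons.

    1. expression, tissue-specific vs common (MWU)
    2. expression of tissue-specific genes across tissues (KW)
    3. expression, sex-specific vs somatic-specific (MWU)
    4. expression, gynoecium- vs androecium-specific (MWU)
    5. Ka, homogeneous vs heterogeneous pairs (MWU)
    6. Fop across tissues (KW)
    7. Fop, sex- vs somatic-specific (MWU)
    8. amino-acid length across tissues (KW)
    9. amino-acid length, sex- vs somatic-specific (MWU)

    ``classification`` is the per-gene table (status, group, specific_tissue,
    expression_level); ``usage`` the per-gene Fop/length table; ``estimates``
    the labeled per-pair substitution table. Raises ValueError naming any
    missing table.
    """
    for name, table in (
        ("classification", classification),
        ("usage", usage),
        ("estimates", estimates),
    ):
        if table is None or len(table) == 0:
            raise ValueError(f"missing upstream table: {name}")

    cls = classification
    specific = cls[cls["status"] == "tissue_specific"]
    common = cls[cls["status"] == "common"]
    sex = specific[specific["group"] == "sex_specific"]
    somatic = specific[specific["group"] == "somatic_specific"]
    gyn = specific[specific["specific_tissue"] == "gynoecium"]
    andro = specific[specific["specific_tissue"] == "androecium"]

    merged = specific.merge(usage[usage["valid"]], on="gene_id", how="inner")
    m_sex = merged[merged["group"] == "sex_specific"]
    m_som = merged[merged["group"] == "somatic_specific"]

    rows: list[dict] = [
        _mwu_row(
            "expression_specific_vs_common",
            "specific", specific["expression_level"].dropna(),
            "common", common["expression_level"].dropna(),
            alpha,
        ),
        _kw_row(
            "expression_by_tissue",
            [g["expression_level"].dropna() for _, g in specific.groupby("specific_tissue")],
            alpha,
        ),
        _mwu_row(
            "expression_sex_vs_somatic",
            "sex", sex["expression_level"].dropna(),
            "somatic", somatic["expression_level"].dropna(),
            alpha,
        ),
        _mwu_row(
            "expression_gynoecium_vs_androecium",
            "gynoecium", gyn["expression_level"].dropna(),
            "androecium", andro["expression_level"].dropna(),
            alpha,
        ),
        _mwu_row(
            "ka_homogeneous_vs_heterogeneous",
            "homogeneous",
            estimates.loc[estimates["expression_class"] == "homogeneous", "Ka"].dropna(),
            "heterogeneous",
            estimates.loc[estimates["expression_class"] == "heterogeneous", "Ka"].dropna(),
            alpha,
        ),
        _kw_row(
            "fop_by_tissue",
            [g["fop"].dropna() for _, g in merged.groupby("specific_tissue")],
            alpha,
        ),
        _mwu_row(
            "fop_sex_vs_somatic",
            "sex", m_sex["fop"].dropna(), "somatic", m_som["fop"].dropna(), alpha,
        ),
        _kw_row(
            "aa_length_by_tissue",
            [g["aa_length"].dropna() for _, g in merged.groupby("specific_tissue")],
            alpha,
        ),
        _mwu_row(
            "aa_length_sex_vs_somatic",
            "sex", m_sex["aa_length"].dropna(), "somatic", m_som["aa_length"].dropna(), alpha,
        ),
    ]
    return pd.DataFrame(rows)
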