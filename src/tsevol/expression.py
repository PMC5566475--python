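"""Expression-based gene classification from an FPKM matrix.

A gene is *tissue-specific* when its FPKM reaches the expressed threshold in
exactly one tissue and stays below it everywhere else; *common* when it is
expressed in every profiled tissue; *intermediate* otherwise. Tissue-specific
genes are further grouped as *sex-specific* (expressing tissue is gynoecium or
androecium) or *somatic-specific*. Developmental stages of one organ count as
distinct tissues.

Expression levels are log2-transformed FPKM. With a pseudocount of 0 (the
default), FPKM 0 maps to an explicit not-expressed sentinel (NaN) rather than
-inf.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_SEX_TISSUES = frozenset({"gynoecium", "androecium"})
DEFAULT_EXPRESSED_THRESHOLD = 1.0

STATUS_TISSUE_SPECIFIC = "tissue_specific"
STATUS_COMMON = "common"
STATUS_INTERMEDIATE = "intermediate"

GROUP_SEX = "sex_specific"
GROUP_SOMATIC = "somatic_specific"
GROUP_NA = "not_applicable"


@dataclass
class ExpressionMatrix:
    """Gene x tissue FPKM matrix with per-gene subgenome labels.

    fpkm: DataFrame indexed by gene id, columns are tissue names; values are
        finite and non-negative.
    subgenome: Series indexed like fpkm, values in {"A", "B", "unknown"}.
    """

    fpkm: pd.DataFrame
    subgenome: pd.Series

    def __post_init__(self) -> None:
        if self.fpkm.index.has_duplicates:
            dup = self.fpkm.index[self.fpkm.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup!r}")
        if self.fpkm.columns.has_duplicates:
            dup = self.fpkm.columns[self.fpkm.columns.duplicated()][0]
            raise ValueError(f"duplicate tissue name: {dup!r}")
        values = self.fpkm.to_numpy(dtype=float)
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid FPKM value {self.fpkm.iat[i, j]!r} at gene "
                f"{self.fpkm.index[i]!r}, tissue {self.fpkm.columns[j]!r}"
            )
        if not self.subgenome.index.equals(self.fpkm.index):
            self.subgenome = self.subgenome.reindex(self.fpkm.index, fill_value="unknown")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fpkm.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.fpkm.columns)


@dataclass
class GeneClassification:
    """Per-gene expression status and tissue group."""

    gene_id: str
    status: str
    specific_tissue: str | None = None
    group: str = GROUP_NA
    expression_level: float = math.nan  # log2 FPKM in the expressing tissue(s)
    subgenome: str = "unknown"


def infer_subgenome(gene_id: str, subgenome_rule: dict[str, str] | None) -> str:
    """Assign a subgenome label from a gene-ID prefix map, else 'unknown'."""
    if subgenome_rule:
        for prefix, label in subgenome_rule.items():
            if gene_id.startswith(prefix):
                return label
    return "unknown"


def load_fpkm(path, subgenome_rule: dict[str, str] | None = None) -> ExpressionMatrix:
    """Read a tab-delimited FPKM matrix (header = tissue names, column 1 = gene id).

    Raises ValueError naming the offending row/column on ragged rows,
    duplicate gene IDs, or negative/non-numeric values.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, engine="python")
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValueError(f"duplicate gene ID: {dup!r}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        cell = raw.iat[i, j]
        what = "missing (ragged row?)" if pd.isna(cell) else f"non-numeric {cell!r}"
        raise ValueError(
            f"bad FPKM cell at gene {raw.index[i]!r}, tissue {raw.columns[j]!r}: {what}"
        )
    sub = pd.Series(
        [infer_subgenome(g, subgenome_rule) for g in numeric.index],
        index=numeric.index,
        dtype=object,
    )
    return ExpressionMatrix(fpkm=numeric.astype(float), subgenome=sub)


def log2_levels(m: ExpressionMatrix, pseudocount: float = 0.0) -> pd.DataFrame:
    """log2-transformed FPKM levels.

    pseudocount >= 0. With pseudocount 0, zero FPKM yields NaN (the explicit
    "not expressed" sentinel); the transform is strictly monotone on the
    remaining values.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    values = m.fpkm.to_numpy(dtype=float) + pseudocount
    with np.errstate(divide="ignore"):
        out = np.log2(values)
    out[values == 0] = np.nan
    return pd.DataFrame(out, index=m.fpkm.index, columns=m.fpkm.columns)


def classify_genes(
    m: ExpressionMatrix,
    expressed_threshold: float = DEFAULT_EXPRESSED_THRESHOLD,
    sex_tissues: frozenset[str] | set[str] = DEFAULT_SEX_TISSUES,
) -> list[GeneClassification]:
    """Partition every gene into tissue_specific / common / intermediate.

    Expressed means FPKM >= expressed_threshold. Exactly one expressed tissue
    (and below threshold in all others) -> tissue_specific; expressed in all
    tissues -> common; anything else -> intermediate. Tissue-specific genes
    whose tissue is in sex_tissues are sex_specific, otherwise
    somatic_specific.
    """
    if m.fpkm.empty:
        raise ValueError("empty expression matrix")
    if expressed_threshold <= 0:
        raise ValueError("expressed_threshold must be > 0")
    unknown = set(sex_tissues) - set(m.tissue_ids)
    if unknown:
        raise ValueError(f"unknown sex tissue name(s): {sorted(unknown)}")

    levels = log2_levels(m)
    expressed = m.fpkm.to_numpy(dtype=float) >= expressed_threshold
    n_expressed = expressed.sum(axis=1)
    n_tissues = m.fpkm.shape[1]
    tissues = np.asarray(m.tissue_ids, dtype=object)

    out: list[GeneClassification] = []
    for i, gene in enumerate(m.gene_ids):
        sub = m.subgenome.iloc[i]
        if n_expressed[i] == 1:
            tissue = tissues[expressed[i]][0]
            group = GROUP_SEX if tissue in sex_tissues else GROUP_SOMATIC
            out.append(
                GeneClassification(
                    gene_id=gene,
                    status=STATUS_TISSUE_SPECIFIC,
                    specific_tissue=tissue,
                    group=group,
                    expression_level=float(levels.iat[i, list(tissues).index(tissue)]),
                    subgenome=sub,
                )
            )
        elif n_expressed[i] == n_tissues:
            out.append(
                GeneClassification(
                    gene_id=gene,
                    status=STATUS_COMMON,
                    expression_level=float(np.nanmean(levels.iloc[i].to_numpy())),
                    subgenome=sub,
                )
            )
        else:
            row = levels.iloc[i].to_numpy()
            level = float(np.nanmean(row)) if np.isfinite(row).any() else math.nan
            out.append(
                GeneClassification(
                    gene_id=gene,
                    status=STATUS_INTERMEDIATE,
                    expression_level=level,
                    subgenome=sub,
                )
            )
    return out


def classifications_to_frame(classifications: list[GeneClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in classifications],
            "status": [c.status for c in classifications],
            "specific_tissue": [c.specific_tissue for c in classifications],
            "group": [c.group for c in classifications],
            "expression_level": [c.expression_level for c in classifications],
            "subgenome": [c.subgenome for c in classifications],
        }
    )


def _percent(count: int, total: int) -> float:
    return round(100.0 * count / total, 2)


def summarize(classifications: list[GeneClassification], total_genes: int) -> pd.DataFrame:
    """Count/percentage table by status, group, subgenome and tissue.

    Percentages are 100 * count / total_genes rounded to two decimals.
    Tissue rows (counts of tissue-specific genes per tissue) are sorted
    descending by count. total_genes may exceed the number of classified
    genes (unclassified genes count only in the denominator).
    """
    if total_genes <= 0:
        raise ValueError("total_genes must be positive")
    if total_genes < len(classifications):
        raise ValueError("total_genes is smaller than the number of classified genes")

    df = classifications_to_frame(classifications)
    rows: list[tuple[str, str, int, float]] = []

    for status in (STATUS_TISSUE_SPECIFIC, STATUS_COMMON, STATUS_INTERMEDIATE):
        n = int((df["status"] == status).sum())
        rows.append(("status", status, n, _percent(n, total_genes)))

    for group in (GROUP_SEX, GROUP_SOMATIC):
        n = int((df["group"] == group).sum())
        rows.append(("group", group, n, _percent(n, total_genes)))

    for status in (STATUS_TISSUE_SPECIFIC, STATUS_COMMON):
        for sub in ("A", "B"):
            n = int(((df["status"] == status) & (df["subgenome"] == sub)).sum())
            rows.append((f"status_subgenome", f"{status}:{sub}", n, _percent(n, total_genes)))

    for group in (GROUP_SEX, GROUP_SOMATIC):
        for sub in ("A", "B"):
            n = int(((df["group"] == group) & (df["subgenome"] == sub)).sum())
            rows.append(("group_subgenome", f"{group}:{sub}", n, _percent(n, total_genes)))

    specific = df[df["status"] == STATUS_TISSUE_SPECIFIC]
    tissue_counts = specific["specific_tissue"].value_counts()
    for tissue, n in tissue_counts.items():
        rows.append(("tissue", str(tissue), int(n), _percent(int(n), total_genes)))

    return pd.DataFrame(rows, columns=["section", "category", "count", "percent"])
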