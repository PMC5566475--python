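"""End-to-end orchestration: classify -> duplicates -> align -> Ka/Ks -> Fop -> stats.

Every stage writes its table (TSV) to the output directory so each step is
independently re-runnable; the run ends with a consolidated human-readable
summary. Outputs are pure functions of (inputs, config). Defaults carry the
analysis thresholds: expressed at FPKM >= 1.0; duplicate criteria identity
> 80, coverage > 80, E <= 1e-10; Ks admissibility [0.01, 0.30]; optimal-codon
derivation from the top 5% expressed genes; alpha = 0.05.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from tsevol import codon_align, codon_usage, duplicates, evolution, expression, stats, synthetic

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    fasta: str | None = None
    matrix: str | None = None
    synthetic: synthetic.SyntheticConfig | None = None
    out_dir: str = "tsevol_out"
    subgenome_rule: dict[str, str] = field(
        default_factory=lambda: dict(synthetic.SUBGENOME_PREFIXES)
    )
    expressed_threshold: float = 1.0
    sex_tissues: tuple[str, str] = ("gynoecium", "androecium")
    min_identity: float = 80.0
    min_coverage: float = 80.0
    max_significance: float | None = 1e-10
    ks_low: float = evolution.KS_LOW
    ks_high: float = evolution.KS_HIGH
    top_fraction: float = 0.05
    alpha: float = 0.05
    total_genes: int | None = None  # denominator for percentages; default = matrix size
    seed: int = 0


@dataclass
class PipelineResult:
    classification: pd.DataFrame
    summary: pd.DataFrame
    pairs: pd.DataFrame
    estimates: pd.DataFrame
    usage: pd.DataFrame
    group_means: pd.DataFrame
    comparisons: pd.DataFrame
    out_dir: Path


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and write all tables under config.out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        bundle = synthetic.gen_dataset(config.synthetic)
        synthetic.write_bundle(bundle, out / "synthetic_input")
        matrix = bundle.expression
        cdss = bundle.cdss
    else:
        if not config.matrix or not config.fasta:
            raise RuntimeError("stage 'load' failed: need both --matrix and --fasta (or a synthetic config)")
        matrix = _stage("load_fpkm")(expression.load_fpkm)(config.matrix, config.subgenome_rule)
        cdss = _stage("read_fasta")(duplicates.read_cds_fasta)(config.fasta)

    sex = frozenset(t for t in config.sex_tissues if t in matrix.tissue_ids)
    classifications = _stage("classify")(expression.classify_genes)(
        matrix, config.expressed_threshold, sex
    )
    cls_frame = expression.classifications_to_frame(classifications)
    cls_frame.to_csv(out / "classification.tsv", sep="\t", index=False)

    total = config.total_genes or len(matrix.gene_ids)
    summary = _stage("summarize")(expression.summarize)(classifications, total)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)

    full_length = [c for c in cdss if duplicates.is_full_length(c)]
    logger.info("%d of %d CDSs are full-length", len(full_length), len(cdss))
    hits = _stage("all_vs_all")(duplicates.all_vs_all)(full_length)
    retained = _stage("apply_criteria")(duplicates.apply_criteria)(
        hits, config.min_identity, config.min_coverage, config.max_significance
    )

    cls_lookup = {c.gene_id: c for c in classifications}
    labeled = []
    for pair in retained:
        lp = duplicates.label_pair(pair, cls_lookup)
        if lp is not None:
            labeled.append(lp)
    pairs_frame = pd.DataFrame(
        [
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "identity": p.identity,
                "coverage": p.coverage,
                "significance": p.significance,
                "expression_class": p.expression_class,
                "composition": p.composition,
            }
            for p in labeled
        ]
    )
    pairs_frame.to_csv(out / "pairs.tsv", sep="\t", index=False)

    cds_by_id = {c.gene_id: c for c in cdss}
    est_rows = []
    for p in labeled:
        aln = codon_align.align_pair(cds_by_id[p.gene_a], cds_by_id[p.gene_b])
        e = evolution.estimate(aln)
        keep, reason = evolution.ks_filter(e, config.ks_low, config.ks_high)
        row = vars(e).copy()
        row["retained"] = keep
        if not keep:
            row["status"] = reason
        row["selection_class"] = (
            evolution.classify_selection(e.omega) if not math.isnan(e.omega) else None
        )
        row["expression_class"] = p.expression_class
        row["composition"] = p.composition
        est_rows.append(row)
    estimates = pd.DataFrame(est_rows)
    estimates.to_csv(out / "estimates.tsv", sep="\t", index=False)

    retained_est = (
        estimates[estimates["retained"]] if len(estimates) else estimates
    )
    gm_rows = []
    if len(retained_est):
        gm_rows.append(evolution.group_means(retained_est, by="expression_class"))
        gm_rows.append(
            evolution.group_means(retained_est, by="composition").rename(
                columns={"composition": "expression_class"}
            )
        )
    group_means = (
        pd.concat(gm_rows, ignore_index=True).rename(columns={"expression_class": "group"})
        if gm_rows
        else pd.DataFrame(columns=["group", "mean_ka", "mean_ks", "mean_omega"])
    )
    group_means.to_csv(out / "group_means.tsv", sep="\t", index=False)

    levels = expression.log2_levels(matrix)
    expr_level = {
        c.gene_id: c.expression_level for c in classifications
    }
    genes_with_cds = [c for c in cdss if c.gene_id in expr_level]
    try:
        optimal = codon_usage.derive_optimal_codons(
            genes_with_cds,
            {g: v for g, v in expr_level.items() if not math.isnan(v)},
            config.top_fraction,
        )
    except ValueError:
        optimal = codon_usage.builtin_optimal_codons()
        logger.info("falling back to the built-in optimal-codon table")
    usage = codon_usage.usage_table(cdss, optimal)
    usage.to_csv(out / "codon_usage.tsv", sep="\t", index=False)

    comparisons = _stage("compare_report")(stats.compare_report)(
        cls_frame, usage, estimates, config.alpha
    )
    extra = stats.rate_comparisons(estimates, config.alpha)
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    extra.to_csv(out / "rate_comparisons.tsv", sep="\t", index=False)

    _write_text_summary(out, summary, pairs_frame, estimates, group_means, comparisons, config)
    return PipelineResult(
        classification=cls_frame,
        summary=summary,
        pairs=pairs_frame,
        estimates=estimates,
        usage=usage,
        group_means=group_means,
        comparisons=comparisons,
        out_dir=out,
    )


def _write_text_summary(out, summary, pairs, estimates, group_means, comparisons, config):
    lines = ["# analysis summary", ""]
    lines.append("substitution rates: NG86 pathway counting with Jukes-Cantor correction")
    lines.append(
        f"thresholds: expressed FPKM >= {config.expressed_threshold}; identity > "
        f"{config.min_identity}%, coverage > {config.min_coverage}%, "
        f"E <= {config.max_significance}; Ks in [{config.ks_low}, {config.ks_high}]; "
        f"alpha = {config.alpha}"
    )
    lines.append("")
    lines.append("## gene classification (count, percent of total)")
    for _, r in summary[summary["section"].isin(["status", "group"])].iterrows():
        lines.append(f"  {r['category']}: {r['count']} ({r['percent']:.2f}%)")
    lines.append("")
    n_ret = int(estimates["retained"].sum()) if len(estimates) else 0
    lines.append(f"## duplicate pairs: {len(pairs)} labeled, {n_ret} retained by the Ks filter")
    if n_ret:
        kept = estimates[estimates["retained"]]
        by_sel = kept["selection_class"].value_counts()
        for sel, cnt in by_sel.items():
            lines.append(f"  {sel}: {cnt}")
        lines.append(
            f"  mean Ka = {kept['Ka'].mean():.4f}, mean Ks = {kept['Ks'].mean():.4f}, "
            f"mean omega = {kept['omega'].mean():.4f}"
        )
    lines.append("")
    lines.append("## group means")
    for _, r in group_means.iterrows():
        lines.append(
            f"  {r['group']}: Ka {r['mean_ka']:.4f}, Ks {r['mean_ks']:.4f}, "
            f"omega {r['mean_omega']:.4f}"
        )
    lines.append("")
    lines.append("## comparisons")
    for _, r in comparisons.iterrows():
        star = "*" if r["significant"] else " "
        lines.append(
            f" {star} {r['comparison']}: {r['test']} stat={r['statistic']:.2f} "
            f"p={r['p_value']:.3g} ({r['direction']})"
        )
    (Path(out) / "summary.txt").write_text("\n".join(lines) + "\n")
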