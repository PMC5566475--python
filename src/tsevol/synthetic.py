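"""Synthetic datasets with known ground truth.

Emulates the structure of a 22-tissue allotetraploid FPKM panel and a CDS set
containing duplicate gene pairs:

* expression — log-normal FPKM with planted tissue-specific genes (expressed
  at >= 2x the calling threshold in one tissue, zero elsewhere), common genes
  (expressed everywhere) and intermediate genes; sex-specific genes carry a
  planted upward shift on the log2 scale (gynoecium above androecium);
* sequences — full-length CDSs; duplicate pairs are produced by evolving an
  ancestor down two lineages with a rejection-sampling substitution process
  whose acceptance ratio for nonsynonymous proposals is the planted omega, so
  ground-truth dN/dS is the acceptance ratio by construction; background
  sequences are unrelated random CDSs.

Everything is driven by one numpy Generator seeded from the config, so a
fixed config yields byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from tsevol.duplicates import CodingSequence
from tsevol.evolution import codon_sites
from tsevol.expression import ExpressionMatrix, GROUP_NA, GROUP_SEX, GROUP_SOMATIC
from tsevol.genetic_code import BASES, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, split_codons

#: the 22 tissues / developmental stages of the peanut expression panel
PEANUT_TISSUES: tuple[str, ...] = (
    "gynoecium",
    "androecium",
    "root",
    "nodule",
    "reproductive_shoot",
    "vegetative_shoot",
    "main_stem_leaf",
    "lateral_leaf",
    "seedling_leaf",
    "perianth",
    "stalk",
    "aerial_gynophore",
    "subterranean_gynophore",
    "pattee_1_pod",
    "pattee_3_pod",
    "pattee_5_pericarp",
    "pattee_6_pericarp",
    "pattee_5_seed",
    "pattee_6_seed",
    "pattee_7_seed",
    "pattee_8_seed",
    "pattee_10_seed",
)

SUBGENOME_PREFIXES = {"Aradu": "A", "Araip": "B"}


@dataclass
class SyntheticConfig:
    n_genes: int = 1000
    n_tissues: int = 22
    frac_specific: float = 0.20
    frac_common: float = 0.40
    sex_tissues: tuple[str, str] = ("gynoecium", "androecium")
    # log2-scale expression model
    specific_log2_mu: float = 3.0
    common_log2_mu: float = 5.0
    log2_sigma: float = 1.0
    sex_shift: float = 1.0  # planted sex-specific median shift (log2)
    gynoecium_shift: float = 1.0  # extra shift of gynoecium over androecium
    expressed_threshold: float = 1.0
    # sequence model
    n_duplicate_pairs: int = 50
    n_background: int = 100
    codon_length: int = 300
    target_ks: float = 0.2
    omega: float = 0.5
    frac_sex_sex: float = 0.10
    frac_somatic_sex: float = 0.15
    frac_homogeneous_somatic: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_specific", "frac_common", "frac_sex_sex", "frac_somatic_sex",
                     "frac_homogeneous_somatic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_specific + self.frac_common > 1.0:
            raise ValueError("frac_specific + frac_common must be <= 1")
        if self.frac_sex_sex + self.frac_somatic_sex > 1.0:
            raise ValueError("pair composition fractions exceed 1")

    @property
    def tissues(self) -> tuple[str, ...]:
        if self.n_tissues == len(PEANUT_TISSUES):
            return PEANUT_TISSUES
        if self.n_tissues < len(PEANUT_TISSUES):
            return PEANUT_TISSUES[: self.n_tissues]
        extra = tuple(f"tissue_{i}" for i in range(len(PEANUT_TISSUES), self.n_tissues))
        return PEANUT_TISSUES + extra


@dataclass
class GroundTruth:
    genes: dict[str, dict] = field(default_factory=dict)
    pairs: list[dict] = field(default_factory=list)
    optimal_codons: dict[str, str] | None = None


@dataclass
class Bundle:
    expression: ExpressionMatrix
    cdss: list[CodingSequence]
    truth: GroundTruth
    config: SyntheticConfig


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _gene_id(index: int, subgenome: str) -> str:
    prefix = "Aradu" if subgenome == "A" else "Araip"
    return f"{prefix}.G{index:05d}"


def _expressed_fpkm(rng: np.random.Generator, mu: float, sigma: float, floor: float, size) -> np.ndarray:
    """Log-normal FPKM clipped from below so planted expression never falls
    under the calling threshold margin."""
    return np.maximum(2.0 ** rng.normal(mu, sigma, size=size), floor)


def gen_expression(
    config: SyntheticConfig,
    rng: np.random.Generator | int | None = None,
    specific_tissue_plan: list[str] | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the FPKM matrix and its per-gene ground truth.

    specific_tissue_plan, when given, fixes the expressing tissue of the
    first len(plan) tissue-specific genes (used to place duplicate-pair
    members); remaining specific genes get uniform random tissues.
    """
    rng = _rng(config.seed if rng is None else rng)
    tissues = config.tissues
    n = config.n_genes
    n_spec = int(round(config.frac_specific * n))
    n_common = int(round(config.frac_common * n))
    if n_spec + n_common > n:
        raise ValueError("infeasible fractions: specific + common exceed total genes")
    plan = list(specific_tissue_plan or [])
    if len(plan) > n_spec:
        raise ValueError(
            f"tissue plan ({len(plan)} genes) exceeds planted specific genes ({n_spec})"
        )
    unknown = set(plan) - set(tissues)
    if unknown:
        raise ValueError(f"planned tissues not in panel: {sorted(unknown)}")

    floor = 2.0 * config.expressed_threshold
    sex_set = set(config.sex_tissues)
    n_tissues = len(tissues)
    tissue_index = {t: j for j, t in enumerate(tissues)}

    fpkm = np.zeros((n, n_tissues))
    subgenomes = np.where(rng.random(n) < 0.5, "A", "B")
    gene_ids = [_gene_id(i, subgenomes[i]) for i in range(n)]
    truth = GroundTruth()

    for i in range(n):
        gid = gene_ids[i]
        if i < n_spec:
            if i < len(plan):
                tissue = plan[i]
            else:
                tissue = tissues[rng.integers(n_tissues)]
            mu = config.specific_log2_mu
            if tissue in sex_set:
                mu += config.sex_shift
                if tissue == "gynoecium":
                    mu += config.gynoecium_shift
            fpkm[i, tissue_index[tissue]] = _expressed_fpkm(
                rng, mu, config.log2_sigma, floor, None
            )
            group = GROUP_SEX if tissue in sex_set else GROUP_SOMATIC
            truth.genes[gid] = {
                "status": "tissue_specific",
                "specific_tissue": tissue,
                "group": group,
                "subgenome": subgenomes[i],
            }
        elif i < n_spec + n_common:
            fpkm[i] = _expressed_fpkm(
                rng, config.common_log2_mu, config.log2_sigma, floor, n_tissues
            )
            truth.genes[gid] = {
                "status": "common",
                "specific_tissue": None,
                "group": GROUP_NA,
                "subgenome": subgenomes[i],
            }
        else:
            k = int(rng.integers(2, n_tissues))  # expressed in 2..n_tissues-1 tissues
            cols = rng.choice(n_tissues, size=k, replace=False)
            fpkm[i, cols] = _expressed_fpkm(
                rng, config.specific_log2_mu, config.log2_sigma, floor, k
            )
            truth.genes[gid] = {
                "status": "intermediate",
                "specific_tissue": None,
                "group": GROUP_NA,
                "subgenome": subgenomes[i],
            }

    matrix = ExpressionMatrix(
        fpkm=pd.DataFrame(fpkm, index=gene_ids, columns=list(tissues)),
        subgenome=pd.Series(subgenomes, index=gene_ids, dtype=object),
    )
    return matrix, truth


def gen_cds(length_codons: int, seed, gene_id: str = "synthetic") -> CodingSequence:
    """Random full-length CDS: ATG + uniform sense codons + a uniform stop."""
    if length_codons < 10:
        raise ValueError("length_codons must be >= 10")
    rng = _rng(seed)
    body = rng.choice(len(SENSE_CODONS), size=length_codons - 1)
    stops = sorted(STOP_CODONS)
    stop = stops[rng.integers(len(stops))]
    seq = "ATG" + "".join(SENSE_CODONS[i] for i in body) + stop
    return CodingSequence(gene_id=gene_id, nucleotides=seq)


def _synonymous_sites(cds: CodingSequence) -> float:
    return sum(codon_sites(c)[0] for c in split_codons(cds.nucleotides)[:-1])


def evolve_pair(
    ancestor: CodingSequence,
    target_ks: float,
    omega: float,
    seed,
    ids: tuple[str, str] = ("a", "b"),
    max_proposals: int | None = None,
) -> tuple[CodingSequence, CodingSequence, dict]:
    """Evolve two descendants to a target synonymous divergence at a given omega.

    Single-nucleotide proposals at uniform positions (start and stop codons
    are immutable; proposals creating a stop are rejected). Synonymous
    proposals are accepted with probability 1 and nonsynonymous with
    probability omega; for omega > 1 the roles invert (synonymous accepted
    with probability 1/omega). Proposals continue until the accepted
    synonymous events reach target_ks x (ancestral synonymous sites).
    Returns the descendants and the realized event counts.
    """
    if target_ks < 0 or target_ks > 0.5:
        raise ValueError("target_ks must be in [0, 0.5]")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    rng = _rng(seed)
    codons = split_codons(ancestor.nucleotides)
    if codons[0] != "ATG" or codons[-1] not in STOP_CODONS:
        raise ValueError("ancestor must be a full-length CDS")

    s_sites = _synonymous_sites(ancestor)
    target_events = int(round(target_ks * s_sites))
    lineages = [list(codons), list(codons)]
    realized = {"syn_events": 0, "nonsyn_events": 0, "synonymous_sites": s_sites}

    if target_events == 0:
        a = CodingSequence(ids[0], ancestor.nucleotides)
        b = CodingSequence(ids[1], ancestor.nucleotides)
        return a, b, realized

    p_syn, p_nonsyn = (1.0, omega) if omega <= 1.0 else (1.0 / omega, 1.0)
    budget = max_proposals if max_proposals is not None else 2000 * target_events + 100000
    n_internal = len(codons) - 2  # mutable codons (start and stop excluded)
    if n_internal < 1:
        raise ValueError("ancestor too short to evolve")

    proposals = 0
    while realized["syn_events"] < target_events:
        proposals += 1
        if proposals > budget:
            raise RuntimeError(
                f"target Ks {target_ks} unreachable within {budget} proposals"
            )
        lineage = lineages[rng.integers(2)]
        ci = 1 + int(rng.integers(n_internal))
        pos = int(rng.integers(3))
        codon = lineage[ci]
        base = BASES[rng.integers(4)]
        if base == codon[pos]:
            continue
        mutant = codon[:pos] + base + codon[pos + 1 :]
        if mutant in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[mutant] == CODON_TO_AA[codon]
        accept_p = p_syn if synonymous else p_nonsyn
        if rng.random() >= accept_p:
            continue
        lineage[ci] = mutant
        realized["syn_events" if synonymous else "nonsyn_events"] += 1

    a = CodingSequence(ids[0], "".join(lineages[0]))
    b = CodingSequence(ids[1], "".join(lineages[1]))
    return a, b, realized


def _plan_pair_tissues(config: SyntheticConfig, rng: np.random.Generator) -> list[dict]:
    """Composition and expressing-tissue plan for each duplicate pair."""
    tissues = config.tissues
    sex = list(config.sex_tissues)
    somatic = [t for t in tissues if t not in set(sex)]
    plans = []
    for _ in range(config.n_duplicate_pairs):
        u = rng.random()
        if u < config.frac_sex_sex:
            t_a = sex[rng.integers(len(sex))]
            t_b = sex[rng.integers(len(sex))]
            composition = "sex_sex"
        elif u < config.frac_sex_sex + config.frac_somatic_sex:
            t_a = sex[rng.integers(len(sex))]
            t_b = somatic[rng.integers(len(somatic))]
            composition = "somatic_sex"
        else:
            t_a = somatic[rng.integers(len(somatic))]
            if rng.random() < config.frac_homogeneous_somatic:
                t_b = t_a
            else:
                others = [t for t in somatic if t != t_a]
                t_b = others[rng.integers(len(others))]
            composition = "somatic_somatic"
        plans.append(
            {
                "tissue_a": t_a,
                "tissue_b": t_b,
                "composition": composition,
                "expression_class": "homogeneous" if t_a == t_b else "heterogeneous",
            }
        )
    return plans


def gen_dataset(config: SyntheticConfig, rng: np.random.Generator | int | None = None) -> Bundle:
    """Generate the full bundle: FPKM matrix, CDS set and ground truth.

    The first 2 x n_duplicate_pairs planted tissue-specific genes are the
    duplicate-pair members (their expressing tissues follow the composition
    plan); background CDSs are unrelated random sequences absent from the
    expression matrix.
    """
    rng = _rng(config.seed if rng is None else rng)
    n_spec = int(round(config.frac_specific * config.n_genes))
    if 2 * config.n_duplicate_pairs > n_spec:
        raise ValueError(
            "infeasible config: duplicate-pair members exceed planted specific genes"
        )
    pair_plans = _plan_pair_tissues(config, rng)
    tissue_plan = [t for plan in pair_plans for t in (plan["tissue_a"], plan["tissue_b"])]
    matrix, truth = gen_expression(config, rng, specific_tissue_plan=tissue_plan)

    gene_ids = matrix.gene_ids
    cdss: list[CodingSequence] = []
    for p, plan in enumerate(pair_plans):
        id_a = gene_ids[2 * p]
        id_b = gene_ids[2 * p + 1]
        ancestor = gen_cds(config.codon_length, rng, gene_id=f"anc{p:04d}")
        a, b, realized = evolve_pair(
            ancestor, config.target_ks, config.omega, rng, ids=(id_a, id_b)
        )
        cdss.extend([a, b])
        truth.pairs.append(
            {
                "gene_a": id_a,
                "gene_b": id_b,
                "omega": config.omega,
                "target_ks": config.target_ks,
                **realized,
                "composition": plan["composition"],
                "expression_class": plan["expression_class"],
            }
        )
    for k in range(config.n_background):
        cdss.append(gen_cds(config.codon_length, rng, gene_id=f"BG.G{k:05d}"))
    return Bundle(expression=matrix, cdss=cdss, truth=truth, config=config)


def write_bundle(bundle: Bundle, out_dir) -> dict[str, Path]:
    """Write FASTA + FPKM TSV + ground-truth JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "cds.fasta"
    with fasta.open("w") as fh:
        for cds in bundle.cdss:
            fh.write(f">{cds.gene_id}\n")
            for i in range(0, len(cds.nucleotides), 60):
                fh.write(cds.nucleotides[i : i + 60] + "\n")
    tsv = out / "fpkm.tsv"
    bundle.expression.fpkm.to_csv(tsv, sep="\t", index_label="gene_id", float_format="%.6g")
    truth_path = out / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "genes": bundle.truth.genes,
                "pairs": bundle.truth.pairs,
                "optimal_codons": bundle.truth.optimal_codons,
                "config": asdict(bundle.config),
            },
            indent=1,
        )
    )
    return {"fasta": fasta, "fpkm": tsv, "truth": truth_path}


def gen_biased_cds(
    length_codons: int,
    optimal: dict[str, str],
    bias: float,
    seed,
    gene_id: str = "biased",
) -> CodingSequence:
    """Random CDS whose codon choices favour a planted optimal-codon set.

    Each amino acid is drawn uniformly; its codon is the planted optimal one
    with probability ``bias``, otherwise uniform among the alternatives.
    Used to test optimal-codon derivation against a known ground truth.
    """
    from tsevol.genetic_code import AA_TO_CODONS

    if length_codons < 10:
        raise ValueError("length_codons must be >= 10")
    rng = _rng(seed)
    aas = sorted(AA_TO_CODONS)
    out = ["ATG"]
    for _ in range(length_codons - 2):
        aa = aas[rng.integers(len(aas))]
        codons = AA_TO_CODONS[aa]
        opt = optimal.get(aa)
        if opt is not None and rng.random() < bias:
            out.append(opt)
        else:
            alternatives = [c for c in codons if c != opt] or list(codons)
            out.append(alternatives[rng.integers(len(alternatives))])
    stops = sorted(STOP_CODONS)
    out.append(stops[rng.integers(len(stops))])
    return CodingSequence(gene_id=gene_id, nucleotides="".join(out))
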