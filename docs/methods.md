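# Methods

This document describes the models, parameter choices and design decisions
behind each stage of the pipeline, in enough detail to reimplement it.

## 1. Expression classification (`expression.py`)

**Model.** The input is an FPKM matrix (genes × tissues, 22 tissues by
default) plus a rule mapping gene-identifier prefixes to subgenomes. A gene
is *expressed* in a tissue when FPKM ≥ `expressed_threshold` (default 1.0,
inclusive). Breadth determines status:

- exactly 1 expressed tissue → `tissue_specific`; the group is
  `sex_specific` when that tissue is in the sex-tissue set (default
  {gynoecium, androecium}), else `somatic_specific`;
- expressed in **all** tissues → `common`;
- expressed in 2 … (n−1) tissues → `intermediate`;
- expressed nowhere → `not_expressed`.

The per-gene expression level is log2 of the mean FPKM over expressed
tissues; log2(0) is represented as NaN rather than −∞ (pseudocount 0 by
design: an unexpressed gene has no defined level, and a pseudocount would
silently shift all levels).

**Summary percentages** are `round(100 · count / total, 2)`, where the
denominator defaults to the number of genes in the matrix but can be
overridden (`total_genes`) when the matrix is a subset of the annotated gene
set.

## 2. Duplicate detection (`duplicates.py`)

Full-length CDSs (start codon, terminal stop, length divisible by 3, no
internal stop, unambiguous bases) are compared all-vs-all:

- **Prefilter:** pairs must share at least one 11-mer (exact word), the
  standard seed size for nucleotide search; this prunes the quadratic
  candidate set without affecting any pair that can reach 80% identity at
  the lengths considered.
- **Alignment:** local (Smith–Waterman) with match +1, mismatch −2, gap open
  −5, gap extend −2.
- **Criteria (strict inequalities where stated):** identity > 80% of the
  aligned columns, alignment length > 80% of the *longer* sequence, and
  E ≤ 1e-10. E-values use the Karlin–Altschul formula E = K·m·n·e^(−λS)
  with K = 0.1 and λ solved from 0.25·e^(λ·match) + 0.75·e^(λ·mismatch) = 1
  (the ungapped scale for a uniform base composition); the significance
  filter can be disabled (`max_significance=None`) since ungapped λ is an
  approximation for gapped scores.
- When one gene hits several partners, the best-scoring (then longest)
  alignment per pair is kept. Pairs are labeled only when **both** members
  are tissue-specific: `homogeneous` when they share the specific tissue,
  `heterogeneous` otherwise; composition is `sex_sex`, `somatic_sex` or
  `somatic_somatic` by how many members are sex-specific.

## 3. Codon-aware alignment (`codon_align.py`)

Nucleotide alignments misplace gaps relative to codon boundaries, so Ka/Ks
uses protein-guided alignment: translate both CDSs (stop removed), align the
proteins globally under BLOSUM62 with affine gaps (open −10, extend −1),
then back-translate each aligned residue to its source codon. To make the
result independent of argument order, the pair is aligned in a canonical
(sorted) order and the rows swapped back afterwards. Only columns without
gaps in either row enter the rate estimation.

## 4. Substitution rates (`evolution.py`)

**NG86 site counting.** For each codon, position *i* contributes
(synonymous changes at *i*) / 3 synonymous sites; mutations creating stop
codons count as nonsynonymous. S and N are averaged over the two sequences.

**NG86 difference counting.** For a codon pair differing at *k* positions,
synonymous/nonsynonymous differences are averaged over all *k*! substitution
orders. Pathways passing through a stop codon are excluded; if every pathway
does, all are averaged (the pair is still informative and discarding it
would bias Ka downward).

**Distance.** Jukes–Cantor: d = −(3/4)·ln(1 − (4/3)p). When p ≥ 3/4 the
estimate is *saturated* and the pair's status records which proportion
saturated. ω = Ka/Ks is undefined when Ks = 0.

**Ks admissibility.** Pairs are retained only when 0.01 ≤ Ks ≤ 0.30 (both
bounds inclusive; values outside are excluded, not clamped). The lower bound
removes alleles/assembly artifacts masquerading as duplicates, the upper
bound removes ancient duplicates whose Ka/Ks averages over too much history.
Selection classes: ω < 1 purifying, ω = 1 (tolerance 1e-9) neutral,
ω > 1 positive.

## 5. Codon usage (`codon_usage.py`)

Fop = (codons using a designated optimal codon) / (codons of amino acids
that have a designated optimal codon). Methionine, tryptophan (single-codon)
and stops never count; the start codon counts like any other methionine.
Fop is NaN when the denominator is 0. The optimal set is either

- **derived**: pool codon counts of the top `top_fraction` (default 5%,
  floor, ties broken lexicographically by gene id) most highly expressed
  valid CDSs and take each degenerate amino acid's most frequent codon
  (lexicographic tie-break); requires ≥ 10 valid CDSs and expression values;
- **built-in**: a dicot-typical table used as fallback.

Protein length is (CDS length / 3) − 1 (stop excluded).

## 6. Rank statistics (`stats.py`)

Two-group comparisons use the two-sided Mann–Whitney U (reported statistic
min(U₁, U₂)). When both samples have ≤ 8 observations the p-value is exact:
all C(n+m, n) rank splits are enumerated with mid-ranks for ties, and
p = P(|U − nm/2| ≥ |u_obs − nm/2|). Larger samples use the tie-corrected
normal approximation with continuity correction. k-group comparisons use
tie-corrected Kruskal–Wallis (χ², k−1 df); identical pooled values give
H = 0, p = 1 rather than a 0/0. Significance is judged at α = 0.05 with no
multiplicity adjustment (raw p-values are reported so readers can apply
their own).

`compare_report` produces exactly nine rows: expression
(specific vs common; across tissues; sex vs somatic; gynoecium vs
androecium), Ka (homogeneous vs heterogeneous pairs), Fop (across tissues;
sex vs somatic) and protein length (across tissues; sex vs somatic).
Comparisons whose groups are empty in a given dataset yield an NaN row
(`significant = False`) instead of aborting the run; `rate_comparisons`
supplies the Ks and ω analogues of the Ka contrast.

## 7. Synthetic data generator (`synthetic.py`)

The generator emulates the *statistical structure* of an allotetraploid
expression/CDS dataset, not its biology:

- **Expression.** `frac_specific` (default 0.20) of genes are planted
  tissue-specific and `frac_common` (0.40) common; the rest intermediate.
  Expressed cells draw FPKM = max(2^N(μ, σ), 2·threshold) so planted labels
  sit at least a factor of 2 from the threshold — classification on
  generated data is exact by construction, which is the property the
  recovery tests rely on. Defaults: specific μ = 3, common μ = 5, σ = 1,
  with additive log2 shifts for sex tissues (1.0) and gynoecium (another
  1.0) so the planted contrasts are detectable. Gene ids follow the two
  subgenome prefixes; tissue names are the 22 defaults.
- **Duplicate pairs.** `n_duplicate_pairs` (50) ancestral CDSs of
  `codon_length` codons (300) are evolved into two descendants by rejection
  sampling: random single-base codon changes are accepted with probability
  1 if synonymous and ω if nonsynonymous (inverted for ω > 1); start and
  stop codons are immutable; sampling stops when the synonymous event count
  reaches round(target_ks · S_ancestor). With target_ks = 0.2 and ω = 0.5
  the resulting pairs stay above 80% identity and inside the Ks window, so
  planted pairs are recoverable at the default thresholds; pushing
  `target_ks` or `codon_length` far beyond the defaults can break that
  invariant. Pair members are assigned tissues according to planned
  fractions of sex_sex / somatic_sex pairs and homogeneous somatic pairs.
- **Background.** `n_background` (100) unrelated CDSs not in the expression
  matrix exercise the duplicate filter's specificity.
- **Ground truth** records every gene's planted status/tissue and every
  pair's genes, target Ks/ω, realized event counts and expression class.
  All randomness flows from a single integer seed; identical seeds give
  byte-identical bundles.

## 8. Pipeline (`pipeline.py`)

Stages run in order (load → classify → summarize → all-vs-all → criteria →
label → align → estimate → filter → group means → Fop → report); each writes
its table as TSV so any stage can be inspected or re-run, and a failure
raises `RuntimeError("stage '<name>' failed: …")` naming the stage. Outputs
are pure functions of (inputs, config). Optimal-codon derivation falls back
to the built-in table when the corpus is too small.

## Numerical and design notes

- Codon site/difference counting is memoized (`lru_cache`) over the 61×61
  sense-codon pairs; pathway enumeration is at most 3! = 6 orders.
- p-values are clipped to (0, 1] to avoid log-of-zero downstream.
- Exact-MWU enumeration is capped at n, m ≤ 8 (≤ 12 870 splits).
- The saturation boundary p = 3/4 is tested as ≥ so the JC logarithm never
  receives a non-positive argument.
- Thresholds (FPKM 1.0, identity/coverage 80, E 1e-10, Ks ∈ [0.01, 0.30],
  top 5%, α 0.05) are config fields, not constants baked into the logic.

## Limitations

- NG86 assumes equal base frequencies and no transition/transversion bias;
  Ka/Ks is therefore comparable within this pipeline but not directly with
  maximum-likelihood (e.g. GY94) estimates.
- The Karlin–Altschul λ is the ungapped value; E-values for gapped local
  alignments are approximate (the identity/coverage criteria do the real
  filtering).
- The generator's evolution model is site-independent and time-reversible
  only in aggregate; it targets a synonymous event count, not a realized
  Ks, so estimated Ks scatters around the target.
- Exact MWU enumeration is exponential and intentionally limited to small
  samples; beyond that the asymptotic approximation is used even under
  heavy ties.
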