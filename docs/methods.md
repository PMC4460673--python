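# Methods

This note documents the statistical model behind `methtriage`, the defaults
it ships with, what the synthetic cohort generator does and does not
emulate, and the design choices made where the underlying workflow was
genuinely open.

## Methylation quantification and testing

A CpG's methylation fraction is β = m/(m+u) from strand-collapsed read
counts.  Collapsing sums the forward-strand C and reverse-strand G records
of each CpG dinucleotide onto the forward coordinate before depth
filtering; CpG methylation is strand-symmetric, so this only adds depth.
The minimum per-CpG depth defaults to 10 reads (standard targeted bis-seq
practice; set `min_depth: 1` to disable).

An amplicon's per-sample level is the **unweighted mean** of its covered
CpG fractions (×100).  Read-weighted averaging was rejected because uneven
PCR coverage would otherwise let one deep CpG dominate an amplicon.

Differential methylation is a two-sided paired Student's t per amplicon on
patient-aligned percent values, d = tumor − non-tumor,
t = d̄/(s_d/√n), df = n−1, with sample (n−1) SDs throughout.  Family-wise
correction is Bonferroni over the amplicons tested in the run (not over
genes); significance is adjusted p ≤ 0.05.  Candidate markers additionally
need |d̄| > 20 percentage points.  Zero-variance differences with nonzero
mean report p = 0 with an explicit flag rather than NaN.

Hierarchical clustering of samples over the significant amplicons uses
Euclidean distance and average linkage; rows are sorted lexicographically
by sample id before linkage so equal-distance merges resolve identically
under input permutation, and missing cells are mean-imputed per amplicon.
The dendrogram is exported as newick.

## Expression

qRT-PCR log2 expression is −ΔCt = −(Ct_target − Ct_reference).  No ΔΔCt
calibrator is applied: group fold changes are computed directly from log2
means as +2^Δ (Δ ≥ 0) or −2^(−Δ) (Δ < 0), so |fold| ≥ 1 always and the
sign encodes direction.  Note a reporting subtlety: folds recomputed from
group means that were themselves rounded to 2 decimals can differ from a
fold computed on unrounded means by up to ±0.01 in the last digit; outputs
therefore document printed-input reproduction as exact to ±0.01.

Paired expression contrasts are **one-sided**, with the direction bound to
the gene's methylation call (hypermethylated → test under-expression;
hypomethylated → over-expression).  A gene without a methylation call falls
back to a two-sided test with a warning.

Per-array expression matrices are log2-transformed, median-centered per
array, and scaled to unit sample SD per array (n−1 denominator).  Zeros are
lifted to half the smallest positive value before the log.  Tissue-group
contrasts (tumor vs precursor, tumor vs normal) use one-sided
pooled-variance Student's t; a gene is *consistently* differentially
expressed only when both contrasts are significant at 0.05, *partially*
when exactly one is.

## Integrative screens

**Concordance.**  A pair is hypermethylated iff tumor percent strictly
exceeds the paired non-tumor percent (ties count as not hypermethylated)
and under-expressed iff tumor log2 expression is strictly lower.  The
concordance percentage is under-expressed / hypermethylated pairs, to one
decimal.  Pearson correlation is computed on per-pair differences
(Δmethylation vs Δexpression) by default; `correlation_on: levels` switches
to tumor-tissue levels, since the published operands of this correlation
are ambiguous.

**CNV.**  Tumor methylation (0–1 scale) is compared between CNV-loss and
no-loss tumors with a two-sided pooled-variance t; the effect is recorded
only when loss tumors are significantly *less* methylated.  The CNV ×
expression-direction association is a Pearson chi-square without
continuity correction, with a warning when any expected count is < 5.
Groups with fewer than two tumors skip the comparison with a flag instead
of failing the run.

**miRNA screen.**  miRNAs targeting a gene (the target map is an input;
no target prediction is performed) are tested when detected in ≥ 50% of
paired samples, with a paired t on complete pairs and Bonferroni correction
within the gene.  Direction is assigned from the sign of the log2 fold
change when the adjusted p ≤ 0.05.  The gene-level confounding flag fires
on any `up` miRNA; this is equivalent to a one-sided over-expression gate
at the same α (the one-sided p is half the two-sided p when the effect is
positive), while still letting the report label significantly *down*
miRNAs, which is how such screens are tabulated.

**Chromatin.**  Peak overlap is binary on 0-based half-open intervals (no
signal heights): `active` = DNase hypersensitivity plus at least one of
H3K4me1/H3K4me3/H3K27ac; `repressed` = H3K27me3 without DNase; anything
else `ambiguous`.  A missing track records the mark as unknown and flags
the annotation incomplete rather than guessing.  This discretization is a
deliberate simplification of qualitative genome-browser reading.

## The triage rule

Rules fire in a fixed order, first match wins (the order itself is a design
choice; the workflow it formalises applies these exclusions narratively):

1. methylation not validated (not significant or |Δ| ≤ 20 pp)
2. no expression data in any assay
3. no significant expression difference anywhere
4. expression significant but opposite to the methylation call (detected
   via the complement of the one-sided p: 1 − p ≤ α)
5. a targeting miRNA over-expressed in tumors
6. methylation lower in CNV-loss tumors
7. otherwise `methylation_regulated` if paired concordance is consistent
   (≥ 50% of hypermethylated pairs under-expressed **and** negative
   correlation).

Rule 7's edge cases are resolved as follows: weak concordance (below the
threshold, or a non-negative correlation) yields `inconsistent_expression`;
absent concordance data (e.g. no qPCR assay for the gene) keeps
`methylation_regulated` on tissue-level evidence alone, with a reason
noting the limitation.  This makes the decision function total over every
combination of present/missing evidence.  The ≥ 50% concordance threshold
is a parameter; observed values for genuinely methylation-regulated genes
run 67–78%.

Gene-level methylation evidence is the amplicon with the largest
|difference| among the gene's amplicons; no cross-amplicon pooling is
attempted.

## Synthetic cohort generator

The generator's defaults are the reference study's conditions: 24
tumor/non-tumor pairs, 29 amplicons whose non-tumor baselines and tumor
shifts (12–43 percentage points; 24 hyper, 5 hypo) are the published
amplicon summaries, mean read depth 100, plus two Chr6q amplicons carrying
a planted copy-number-loss methylation drop.

Read counts are **beta-binomial**: each (sample, amplicon) draws a latent
methylation level from a Beta with mean μ and dispersion ρ (default 0.05;
ρ = 0 collapses to pure binomial, and with ρ > 0 the latent spread makes
counts overdispersed).  Amplicons of the same gene share one latent uniform
per sample mapped through their Beta quantiles, i.e. a sample's amplicons
are comonotone — an exchangeable "sample epigenetic state" that keeps the
gene-level expression link coherent whichever amplicon downstream analysis
selects.  Depth is Poisson floored at 1; reads are split across strands so
the reader's collapsing is exercised.  The true per-CpG correlation
structure within amplicons is unknown, so a single exchangeable ρ is used.

Expression: Ct_target = Ct_reference − (α + β·β_meth + shift·[tumor] + ε),
so −ΔCt is linear in the methylation fraction; with β = −3.4 log2 per
fraction the qPCR genes reproduce ~2-fold repression and the ≈ −0.4 to
−0.5 methylation–expression correlation regime.  The three-group array
matrix adds per-gene tumor/precursor shifts in SD units on top of 40
unshifted filler genes that anchor the per-array median.  miRNA values are
normal around per-group means with configured tumor shifts; CNV states are
multinomial per gene and tumor; chromatin tracks are constructed
deterministically to realise each planted state over every amplicon of the
gene.

One root seed drives five named `SeedSequence` child streams (cnv, bisseq,
expression, tissue, mirna, in that order), so identical (config, seed)
yields byte-identical outputs.

**Planted labels.**  The reference-like preset engineers one or more genes
per triage label and records them in `expected_labels`.  Genes whose
published effect sizes sit essentially *on* a decision boundary — DUOX1
(shift at the 20-point gate, simulated with inflated dispersion ρ = 0.30
so it fails Bonferroni), FAM66B (−19.3), PROKR2 (−18.5), SERHL's best
amplicon margin, PTPRN2 (−21.1, within 0.4 SE of the gate) — are planted
as published but carry no expected label, because their classification
legitimately flips between adjacent labels under resampling.  Conversely a
few planted parameters are chosen with explicit power margins so the
recovery checks measure the pipeline rather than coin flips: the
discordant gene's expression link (β = +3.0 with a −1.9 group shift), the
CNV-loss drop (0.20 at loss probability 0.5), tissue shifts of ±1.2 SD,
and a tightened ρ for the one below-threshold amplicon kept as the
not-validated representative.  The "no expression difference" class is
planted with a +0.25 SD non-repressive drift so the one-sided screen
reports it negative robustly.

**What passing tests do and do not show.**  The generator reproduces the
study's *statistical* structure — paired design, effect sizes, dispersion,
the methylation→expression link — not real data's CpG-level spatial
correlation, bisulfite conversion failure, mapping artefacts, batch
effects, or cell-type heterogeneity.  Recovery results certify the
pipeline's arithmetic and calibration under its assumed model; they do not
certify robustness to violations of that model.

## Problem sizes in routine checks

The default test run uses 24-pair cohorts at depth 100 (one pipeline run
per seed, ~0.8 s), 100 seeds for label recovery, 200 replicates of a
three-amplicon cohort for shift-recovery bias, 10,000 simulated amplicons
for the type-I error check, and exact 2^n sign-flip enumeration (n ≤ 10)
as the permutation oracle for the paired t.  These sizes give Monte-Carlo
standard errors comfortably below the asserted tolerances (e.g. ±0.2 pp
on bias, ±0.2% on the type-I rate).

## Known limitations

- No DMR discovery outside predefined amplicons, and no beta-binomial
  *regression* for differential testing; the paired t on amplicon means is
  the reference workflow's test and loses power when CpGs within an
  amplicon disagree.
- The chromatin annotation ignores peak heights and distances; an amplicon
  just outside a promoter peak is called ambiguous.
- Bonferroni is intentionally conservative; no FDR alternative is wired in.
- The miRNA screen tests marginal expression only — no target-site
  context, no expression-weighted interaction model.
- Triage rule order is fixed; a gene with both a CNV-loss effect and
  discordant expression is labelled by the earlier rule
  (`inconsistent_expression`), which is one of several defensible
  orderings.
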