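# Methods

This note documents the statistical procedures, the default parameter
choices and what the synthetic-data tests do and do not establish.

## Variant triage

Without matched-normal sequencing, somatic status is approximated by a
population-frequency filter: any call observed at > 0.1% in a population
exome database is removed as putative germline. Calls with *no* frequency
annotation are retained — the rule excludes only observed high-frequency
variants, since absence of annotation is not evidence of germline origin.
The threshold is a parameter (`af_threshold`, default 0.001, exclusive
bounds (0, 1)).

Deleteriousness: all loss-of-function consequences (nonsense, frameshift
indel, splice site) are deleterious; missense calls are deleterious when
SIFT says "damaging" **and/or** PolyPhen-2 says "probably damaging"
(implemented as inclusive or). The SNV count is the number of exonic
non-synonymous variants — missense, nonsense, frameshift and in-frame
indels, splice site — after germline filtering; synonymous and other
classes are excluded. The splice-site consequence is taken at face value
from the input annotation; no positional check against consensus
nucleotides is attempted.

DDR alterations come in two flavours applied per gene-pathway table:
*inclusive* (any deleterious variant in a DDR gene) and *restrictive*
(loss-of-function, or missense recurrent ≥ 5 times in COSMIC, reported in
OncoKB or in a hotspot catalog; for ERCC2, missense within the conserved
helicase domains also qualifies, supplied either as a precomputed input
flag or via a configurable interval list). The two criteria are not
nested: a catalog-recurrent missense with benign predictions is
restrictive-only, a predicted-damaging missense without catalog support is
inclusive-only. The 30-gene DDR list with pathway assignments and the
tumour-suppressor/oncogene role table are **not** part of the published
text; the packaged `gene_annotations.tsv` is a documented default drawn
from the general DDR/cancer-gene literature and is meant to be replaced by
the user's own panel table (the feature-table manifest records which table
was used).

## Mutation spectra and signature refitting

Substitutions are folded onto the pyrimidine strand and indexed as
`16·block + 4·rank(5′ base) + rank(3′ base)` over the six blocks C>A, C>G,
C>T, T>A, T>C, T>G with flanking bases ordered A, C, G, T. A variant's
trinucleotide context may be supplied in reference orientation or as its
reverse complement; both map to the same channel. Indels and context-less
SNVs are excluded from the spectrum and tallied separately.

Refitting solves `min_{w≥0} ‖c − Pᵀw‖₂` by non-negative least squares on
**raw counts** (not frequencies), then rescales `w` to sum to the spectrum
total, so the output is an estimated count of mutations generated by each
process (rescaling is skipped when all loadings are zero). Rank-deficient
catalogs are flagged with a warning — the optimum is then non-unique and
one optimum is returned. Refitting against a fixed catalog is the entire
scope; de novo signature discovery is not.

The packaged catalog is **synthetic**: four constructed 96-channel
profiles emulating the processes dominant in bladder cancer — APOBEC
C>T at TpCpW, APOBEC C>G at TpCpW (fused to one APOBEC label in reports),
a broad flat profile standing in for the ERCC2/NER-deficiency process, and
C>T at CpG. The true published reference profiles are not reproduced in
the source text, so signature outputs are validated at the property level
(mixture recovery, scale equivariance, attribution bounds), not against
cohort figures. Any catalog with the same TSV schema (96 canonical channel
rows × one column per signature) can be substituted.

## Copy-number features

Only gene-level homozygous deletions and >6-copy amplifications are
considered. The CNV count pairs event type with gene role: deletions count
in tumour-suppressors, amplifications in oncogenes, genes annotated "both"
count through either, and genes of unknown role never count (a warning
lists skipped events). Repeated segments collapse to one (gene, event)
count. Purity is *not* adjusted for — the detection confound (low-purity
tumours yield fewer detectable CNV calls) is instead reproduced in the
simulator so its consequences can be studied.

## Dichotomization and subgroups

All "≥ cut" comparisons are inclusive: NLR ≥ 5, SNV ≥ 10, ECOG ≥ 1; CNV
"high" is strictly > 0. The median SNV split recomputes the cohort median
(lower median for even cohorts) unless pinned in the rule set (the study
cohort's median was 8). Missing covariates leave the corresponding
indicator missing, and exclusion is listwise **per analysis** — a patient
missing NLR is excluded from score-based classification but not from
analyses that do not use NLR.

## Inference conventions

- Fisher exact: two-sided by the point-probability method (sum of all
  margin-preserving tables no more probable than the observed one), the
  convention that matches the published p-values. Note one published value
  (0.029 for the NER table) is a double-rounding of the exact 0.02846;
  comparisons are made at the published display precision.
- Chi-square: Pearson, no continuity correction.
- Rank tests: mid-ranks; exact enumeration when both groups have ≤ 8
  untied observations, tie-corrected normal approximation otherwise
  (no continuity correction, so symmetric configurations give p = 1).
- Logistic/Cox: Wald intervals and p-values; Cox uses Efron tie handling
  (the original analysis's convention is unstated; Efron is the less
  biased default). Complete separation in logistic fits is detected
  (non-convergence or |β| > 30 on standardized data) and either flagged
  (univariable) or replaced by a Jeffreys-prior Firth-type penalized fit
  (multivariable), always flagged in the result.
- No multiple-testing correction by default — the source analysis reports
  unadjusted gene-level p-values and notes they do not survive correction;
  the `associations` CLI offers optional Bonferroni / Benjamini–Hochberg
  columns.

## Model building

ALASSO: initial estimator is a ridge fit (logistic: L2 at C = 10 on
standardized covariates; Cox: L2 penalizer 0.1), chosen for stability
under collinearity; adaptive weights `1/|β̂_j|^γ` with γ = 1; the weighted
L1 problem is reduced to a plain LASSO by column rescaling; λ is chosen by
BIC over a log-spaced grid (default 10⁻⁵…1, 31 points), with seeded
cross-validation as an alternative. BIC uses the unpenalized refit on each
support (logistic: `−2ℓ + k·log n`; Cox: `−2ℓ_partial + k·log(events)`).
Constant covariates are dropped with a warning; an empty selection is a
legal outcome, not an error. The published analysis's exact tuning is in
unavailable supplementary material, so all three choices (initializer, γ,
tuning rule) are exposed in `ModelBuildConfig`.

Multivariable fits prune by backward elimination: drop the variable with
the largest Wald p while it exceeds the stay criterion (default 0.10),
refit, stop when all survive or one remains.

The c-statistic is the ROC area for binary benefit (ties count ½, computed
from mid-ranks) and Harrell's concordance over usable pairs for survival;
intervals are percentile bootstrap (2000 seeded resamples of the scored
subjects; resamples with a single outcome class are discarded).

Point scores round each logistic coefficient and the intercept to the
nearest half point (ties away from zero). This reproduces three of the
four published points but maps −2.93 to −3.0 where the publication prints
−2.5; since the publication's rounding rule is unstated, an *explicit*
mode pins a user-supplied mapping, and the published mapping
{+1, −2.5, −2, +3} with threshold −1 ships as `PAPER_POINTS`. For newly
derived scores the classification threshold is chosen by maximizing
Youden's J over achievable score values; the published −1 is pinned in the
reproduction path (its original selection criterion is unstated).
Survival stratification uses the published prognostic-index cutoffs
(−0.29, 1.54; intervals closed on the left) and the overall-survival point
system (visceral 2, NLR ≥ 5 1, ECOG ≥ 1 1; groups 0–2 / 3 / 4). The
coefficients behind the progression-free-survival index are not published;
only its cutoffs are reproducible, so `PrognosticIndex` takes coefficients
as input.

## Synthetic cohorts

The simulator generates, per patient: clinical covariates matched to the
study's printed marginals (age ≈ 65.6 ± 9 truncated to 41–84, 73% male,
73% visceral metastasis, ECOG 44/42/14%, lognormal NLR with mean ≈ 5 and
11% missingness, Hb ≈ 12 g/dl, platelets ≈ 240); an SNV count
`1 + NegBin(mean 8.7, dispersion 2.5)` targeting the printed mean 9.7 and
1–32 range; substitution channels drawn multinomially from a per-patient
Dirichlet mixture of the catalog signatures with contexts realized
per channel on a random strand (no reference genome needed); consequence
classes and SIFT/PolyPhen/COSMIC/hotspot annotations drawn so configured
fractions pass the triage rules; Poisson putative-germline contaminants at
2–5% population frequency (removed by the filter); CNV events (9p21
deletion probability 0.40 with 85% CDKN2A/CDKN2B concordance, plus
Poisson tumour-suppressor deletions and oncogene amplifications) thinned
by purity-dependent detection `P(detect) = logistic(−1.6 + 4·purity)`,
purity ~ Beta(5, 3) — which reproduces the positive purity–CNV-count
correlation with no purity–SNV correlation; clinical benefit from a
logistic model on the realized indicator features, defaulting to the
published coefficients (1.15, −2.93, −2.11, 3.21) in the ICI arm and to
an intercept-only null in the taxane arm (every feature coefficient zero,
so no predictor carries information there — the comparator-arm
construction); and exponential proportional-hazards progression and death
times with independent censoring, progression-free time defined as
min(progression, death) so PFS ≤ OS holds by construction.

All randomness flows from one seed through per-patient spawned substreams
keyed by patient index, so outputs are bit-reproducible and patient k is
unchanged when the cohort grows.

What the simulator does **not** emulate: realistic genomic positions or
linkage, panel read-level noise, germline subtraction error, correlated
clinical covariates (each marginal is drawn independently), non-
exponential hazards, and informative censoring. Passing tests therefore
demonstrate correctness of the pipeline's arithmetic and the stated
statistical properties under the generating model — not clinical validity
on real cohorts, for which the published model itself awaits external
validation.

## Problem sizes and numerics

Test and acceptance runs use: 500 random tables (N ≤ 60) for the Fisher
enumeration oracle; exhaustive pair counting at n ≤ 12 for the AUC oracle;
100 replicates at n = 2000 for coefficient recovery; 50 replicates at
n = 1000 for ALASSO selection; 200 multinomial spectra of 500 mutations
for mixture recovery; simulated cohorts of 200 (truth recovery) and 5000
(null-arm discrimination, marginal checks). NNLS tolerances are scipy
defaults; mixture-recovery assertions use mean absolute error < 0.05;
ridge/LASSO numerical zeros are |β| < 10⁻¹⁰ (logistic path) and < 10⁻⁵
(Cox path, whose L1 implementation is a smooth approximation).

## Known limitations

- The default gene table, helicase-domain handling and signature catalog
  are documented stand-ins; analyses of real panels must supply the
  panel's own tables.
- Published cohort-level effect sizes (multivariable ORs/HRs, the 0.90
  c-statistic) require the undeposited patient-level data and are
  reproduced only in distribution via simulation, never asserted as
  numbers.
- The Cox ALASSO path uses a smooth L1 approximation (thresholded), so
  selection near the boundary can differ from an exact coordinate-descent
  solver by one weak variable.
- Firth fallback reports Wald intervals from the penalized information
  matrix; profile-likelihood intervals would be preferable at extreme
  separation but are out of scope.
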