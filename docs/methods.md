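# Methods

## Model and estimation

The core model is y = Xb + Qq + Zu* + e with u* ~ N(0, K_w σ_g²) and
e ~ N(0, I σ_e²).  X always contains an intercept (plus user
covariates), Q holds the dosages of the selected pseudo-QTNs, and K_w is
the (possibly SNP-weighted) genomic relationship matrix built on the
full panel — reference and candidates together — so that
reference-to-candidate covariances are available at prediction time.

Variance components are estimated by REML, profiled to a one-dimensional
search over h² = σ_g²/(σ_g²+σ_e²): a single eigendecomposition of the
phenotyped block of K diagonalises V for every h², so each likelihood
evaluation is O(np).  A 64-point grid brackets the optimum and bounded
Brent refinement finishes it; the result is deterministic.  h² is
constrained to [1e-5, 1−1e-5]; a phenotype numerically inside the
fixed-effect column space returns zero variances with a warning.  The
same eigendecomposition serves REML, the BLUP solve and the whitening of
the mixed-model association scan, which keeps fitting and prediction
numerically consistent.

Genetic values are the conditional mean u* = Qq + σ_g² K_w Z' V⁻¹
(y − Xb − Qq); the σ_g² factor is required for equivalence with
Henderson's mixed-model equations, which the test suite checks to 1e-8.
Binary 0/1 traits are fitted as continuous responses and the predictions
read as case probabilities; accuracy switches automatically to the
rank-based AUROC (midranks for ties, so it coincides exactly with
Mann-Whitney U / (N_case · N_control)).  Categorical traits coded on
more than two levels are treated as continuous.

Association scans: the GLM scan is per-marker OLS with a two-sided
t-test, vectorised through the Frisch–Waugh projection; the MLM scan
estimates variance components once on the null model (P3D) and tests
each marker by a Wald chi-square after whitening.  GLM is the default
(it is far cheaper and ranks markers nearly identically in unstructured
panels); MLM is recommended for family-structured or inbred panels.

## The tuning loop

All tuning happens inside one s-repeats × v-folds partition of the
phenotyped individuals (defaults s = 1, v = 5; binary traits are
stratified by class).  Each fold gets one association scan on its
training individuals only; the left-out group's phenotypes never enter
any quantity computed for that fold, and an explicit leak test in the
suite garbles the left-out phenotypes and asserts the fold scan is
bit-identical.

Pseudo-QTN candidates: per fold, rank markers by ascending p, prune
greedily at r² > 0.3 (computed on the fold's training dosages), keep the
top 15.  Markers recurring in strictly more than 90% of the s·v fold
lists become candidates, ordered by mean ascending-p rank.  The stepwise
audition adds candidates one at a time under the families "pQ+K" and
"pQ"; acceptance requires strict improvement of the family's running
accuracy and strict superiority over the plain-LMM baseline Ā₀.  Family
choice is the accuracy argmax over {K, pQ+K, pQ}; exact ties prefer
fewer covariates, then the kinship-only family.

Kinship weighting: ξ_k = 1 + log_α(P_c) − log_α(P_k) for the top
c = round(mβ) markers (round half-up; c = 0 means unweighted; zero
p-values are clamped two decades below the smallest positive one; ties
in p broken by marker order).  The weighted matrix is built
incrementally as K plus the extra contribution of the top-c markers
only, mathematically identical to weighting the full panel (checked to
1e-10).  The (α, β) objective is the CV accuracy using each fold's own
scan p-values; evaluations are memoised on (α, weighted count).

Grid and refinement: the default grids α ∈ (1.01, 1.11, e, 10) and
β ∈ (1e-4, 1e-3, 1e-2, 1e-1) are searched exhaustively; refinement then
runs on transformed axes t_α = log10(ln α), t_β = log10(β), because the
grids span orders of magnitude and raw-scale midpoints would collapse
the search into the top decade.  Each iteration draws one uniform level
on each flank of the current best level (inside the midpoint bounds of
the current bracket), scores the four cross combinations, moves the best
point, and contracts the bracket to 2/2.5 of its width re-centred on the
best point; drawing on both flanks guarantees the bracket straddles the
optimum, and the contraction guarantees termination.  Stopping: 10
iterations or accuracy improvement < 1e-5.  On a smooth unimodal stub
surface the refinement reaches the dense-grid maximum to 1e-3 from every
tested seed.  The tuned weighting is kept only if it *strictly* beats
both the plain-LMM baseline and the selected family's unweighted
accuracy; ties fall back to the standard kinship (parsimony — a β that
rounds to c = 0 must not relabel the model as weighted).

Application stage: a `pQ` model predicts by plain least squares on the
selected marker dosages; all other families run one fresh association
scan of the current reference (or accept externally merged per-fold
p-values), rebuild the weighted kinship with the stored (α, β), and
solve the mixed model once.  A stored model therefore transfers to new
data at roughly GBLUP cost — the pre-trained ("half") workflow.

## Single-step extension

A is computed by the exact tabular method (inbreeding included).  G of
the genotyped subset — weighted, when the model carries (α, β) — is
first moment-matched to A22 (solve G* = a + bG so diagonal and
off-diagonal means equal those of A22), then blended with weight 0.05 of
A22 for invertibility, the prevailing convention.  H is assembled
directly via the joint-normal block formula, and H⁻¹ = A⁻¹ +
[0; G_adj⁻¹ − A22⁻¹] is verified against it to 1e-8 in the suite.
Pseudo-QTN covariates are never fitted in single-step mode: their
dosages do not exist for non-genotyped individuals.  Markers that are
monomorphic within the genotyped subset are dropped before building G.
The τ/ω scaling parameters of some single-step variants are fixed at 1.

## Synthetic data

Genotypes: marker frequencies uniform on the MAF range, two haplotypes
per individual drawn by thresholding a latent AR(1) Gaussian track at
the per-marker frequency quantile.  Marginal frequencies are exact;
adjacent-marker LD decays geometrically with the `ld_decay` lag-one
correlation.  This emulates local LD but not long-range structure,
population stratification, or realistic allele-frequency spectra —
passing tests demonstrate correctness of the machinery on this
idealised structure, not performance on any real cohort.

Traits: causal markers are drawn without replacement; per-block effects
are N(0, v) with v = 0.005 (polygenic), 0.01 (moderate) or 0.1 (major),
or gamma(shape 0.42, scale 5.4) with random signs for the workshop-style
50-QTL trait.  In the "polygenic + major" architecture the two blocks
are rescaled post hoc to equal realized variance shares, since the
nominal per-SNP variances alone do not guarantee equality.  The residual
variance is computed from the *realized* var(g) so each dataset hits its
nominal h² exactly on average (h² = 1 means phenotype ≡ genetic value).
True breeding values and causal indices are returned for scoring.

Pedigrees: non-overlapping generations, random disjoint pairing, and
Mendelian gamete sampling with per-interval recombination (default
0.01); founder genotypes can be supplied and are phased at random.

## Problem sizes used in the acceptance experiments

The directional experiments run at n = 500 individuals, m = 5000
markers, `ld_decay` 0.9 and a 4×5 cross-validation, with 20% of
individuals masked as validation and accuracy measured against true
breeding values.  These sizes were chosen so the plain-GBLUP baseline
accuracy on the polygenic architecture (~0.4) matches the regime of the
dense human panels the benchmark scenarios emulate — with too few
markers or no LD, the >90% recurrence rule loses its stringency (a
top-15 list from 5000 markers is a far weaker filter than one from
450k), and spuriously recurrent markers contaminate the audition.  The
polygenic block is half the panel.  Single-step experiments use 800
founders, one offspring generation (offspring generation unphenotyped,
20% of it ungenotyped), m = 3000.  At these sizes one directional
experiment of 20 replicates takes a few minutes on one CPU.

Known scale effect: on the pure major-gene architecture the selected
family is a pseudo-QTN family in every replicate, but the *plain* pQ
linear model is modal only in a minority of runs; with ~400 training
individuals some causal loci sit at the stepwise acceptance boundary or
are captured by an LD proxy, leaving residual genetic signal that the
kinship-weight search legitimately detects, so `pQ+Kw` often wins the
family argmax instead.  This gap closes as n grows toward the original
cohort sizes.

## Known limitations

Exact per-marker REML is not implemented (P3D only); kinships are dense
(no LOCO, no sparse storage); the simulator's LD is first-order only;
pedigree mode supports neither metafounders nor genotype imputation for
non-genotyped individuals; and the QC Hardy-Weinberg test is the 1-df
chi-square, not the exact test.
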