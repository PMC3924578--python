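# Methods

This note records the statistical models, the choices made where the design
was genuinely open, and what the synthetic cohort does and does not emulate.

## Cohort model

A cohort of children with sickle cell disease and healthy sibling controls.
Samples carry: Hb genotype (HbSS; optionally HbSC patients; HbAS/HbAA
controls, 3:1), clinical status (E = sampled at entry in steady state,
FU = under follow-up care, Ctl = sibling control; an acute group A is
supported in the data model but not generated by default, matching the
steady-state analysis slice), sex, white and red blood cell counts, family
id, and sampling phase. The default generated cohort is n = 173 (79 E, 41
FU, 53 Ctls) — the genotyped steady-state HbSS slice of the full design —
with half of the samples in full-sib pairs (sibling controls are paired
with patients first).

Blood counts are log-normal: WBC median 15×10⁹/L in patients vs 7.5 in
controls (σ_log = 0.30, leukocytosis), RBC median 2.8×10¹²/L vs 4.4
(σ_log = 0.15, anemia). No distributional values were available for these;
the medians are typical pediatric SCD clinical chemistry, chosen once.

## Genotype generator

Per SNP, a MAF is drawn uniformly from `maf_range` (default 0.05–0.5) and
positions are uniform over `n_chromosomes` (default 22) autosomes. Founders
are binomial(2, MAF) draws, so Hardy–Weinberg equilibrium holds among
founders by construction. Each sib pair is gene-dropped from two simulated
parents (one transmitted allele per parent per SNP), giving expected
π̂ = 0.5 per pair. Missing calls are masked independently at `missing_rate`.

Linkage disequilibrium is off by default (`ld_rho = 0`): the default keeps
null calibrations clean. With `ld_rho > 0`, haplotypes come from an AR(1)
Gaussian copula along each chromosome, and gene-dropping transmits whole
chromosomes without recombination (preserving LD at the cost of a higher
variance of realized sib sharing — acceptable for exercising the pruner).

## Expression generator

Per probe: intercept 8.0 (log2 scale) + per-level Hb offsets (SD
`hb_effect_sd`, all probes) + per-level clinical-status offsets (SD
`clinstatus_effect_sd`) on a random `de_fraction` of probes (the ground-truth
DE set; a fraction is needed so FDR behavior is testable on a null/non-null
mixture) + a sex offset + WBC and RBC slopes on centered counts + Gaussian
noise (`noise_sd`, default 0.5 log2 units).

Planted eSNPs add β·(dosage − mean) with β = √(r²/(1−r²))·σ_noise/σ_dosage,
so the expected partial R² of the SNP given the covariates equals `esnp_r2`
(default 0.33 — a third of transcript variance). Local eSNPs move the probe
onto the SNP's chromosome (within ±500 kb); distal eSNPs move it off.
Planted interactions add a per-group allelic slope — `interaction_delta`
(default 0.5 log2/allele) in the FU group only, mirroring follow-up-driven
regulatory effects — and are placed on status-affected probes so a DE screen
retains them.

What the generator does **not** emulate: bead-level microarray noise, batch
or chip layout artifacts, β-globin-locus haplotype structure, population
stratification, realistic LD block structure, or correlated expression
networks. Passing tests therefore demonstrate the estimators' correctness
and calibration under the assumed sampling model, not robustness to
real-data artifacts.

## QC

* **MAF / call rate / exact HWE** thresholds: ≥ 5%, ≥ 99%, p ≥ 0.001. The
  HWE test is the standard exact formulation: the conditional distribution
  of heterozygote counts given allele counts, summing probabilities ≤ the
  observed outcome's (not mid-p); monomorphic → p = 1. Computed against an
  exact rational enumeration oracle to ≤ 1e-12 for all tables with n ≤ 50.
  In sibship data HWE should be computed in founders/controls only
  (relatedness distorts it); the filter accepts a sample mask for this.
* **Interaction-stage filter**: every criterion applied within every
  clinical group separately, with per-group missingness ≤ 1% (call rate
  ≥ 99%). The stage's published description inverts its comparison
  directions; the conventional exclusions are implemented and this is
  flagged to users here.
* **Quantile normalization**: after log2, every sample's sorted vector is
  set to the cross-sample mean of order statistics; ties receive the mean
  of the quantile values their ranks span (the dominant convention). The
  operation is idempotent.
* **Background filter**: probes whose mean normalized intensity falls below
  the knee of the rank-ordered intensity curve are dropped. The knee is the
  rank minimizing the discrete second difference of the moving-average
  smoothed curve (window max(5, n/50)); a curve with no knee (|d²| below
  1e-8 of the dynamic range) requires an explicit cutoff. On a bimodal
  low/high mixture the cutoff lands between the modes.
* **Outlier handling** before normalization: per-probe winsorization at 4
  SD. The original pipeline's outlier procedure is unspecified; this is a
  documented stand-in.

## Structure analysis

Expression PCA is SVD on centered data with a deterministic sign convention
(largest-|loading| positive). Genotype PCA uses the Eigenstrat
normalization — center by 2p̂, scale by √(p̂(1−p̂)), missing dosages
mean-imputed for the PCA only.

Variance components of the leading ePCs: each factor (Hb genotype, clinical
status, sex, optionally pairwise combinations as crossed labels) enters as
a random effect in a REML variance-components model (statsmodels MixedLM;
the Powell optimizer, which is markedly more reliable than gradient methods
on these small crossed designs). Proportions are component/total, with
non-negativity guaranteed by the parameterization; the "pooled" summary is
the variance-explained-weighted mean of per-PC proportions — a stated
convention, since no pooling rule is standard. Single-level (aliased)
factors are reported as non-identifiable (NaN).

Hierarchical clustering: average linkage on 1 − correlation. Exact ties
break toward lower original indices (an index-ordered jitter ~1e-10 of the
dynamic range, far below any meaningful correlation difference), and leaf
traversal puts the child containing the smallest original index first, so
an identity correlation matrix preserves input order.

Fst: the Weir–Cockerham (1984) a/b/c components per SNP; a set-level value
is the ratio of sums Σa/Σ(a+b+c) over SNPs with defined components
(monomorphic SNPs excluded). Raw θ is retained; a [0,1]-clipped column is
provided for reporting.

## Differential expression

One design matrix per cohort (samples with any missing covariate dropped
globally, keeping df identical across probes), solved as multi-response
least squares. Marginal tests are drop-term F tests — for this
main-effects-only model they coincide with classical Type III tests and are
coding-invariant; sequential Type I tests are available. In the HbSS-only
cohort the HbSS dummy equals the patient (E+FU) indicator: the design
builder sweeps linearly dependent columns in entry order (Hb before
ClinStatus, as the model is written), so the ClinStatus test retains the
estimable within-patient df and the swept columns are reported. FDR is
Benjamini–Hochberg per term at q = 0.01. Pairwise status contrasts are
t tests of level-difference contrasts with per-contrast FDR; a contrast
touching an aliased level is skipped with a warning. A constant response
takes the F = 0, p = 1 convention.

## eSNP mapping

The scan residualizes expression and dosage on the covariates once per
missingness pattern (Frisch–Waugh–Lovell) and reduces the probe × SNP grid
to matrix products; results are exact OLS (verified to 1e-8 against
per-pair normal-equations fits). Missing dosages drop samples pairwise,
with df adjusted; SNPs monomorphic among usable samples are skipped and
counted.

Local = same chromosome, exactly as defined (no distance window for
classification; the generator places local eSNPs within ±500 kb anyway).
The 200-SNPs-per-probe constant of the local threshold is a configuration
input, not recomputed from the data, because the published scheme fixes it.
"Peak" = per probe per class, the minimum-p record; ties break toward
larger |β|, then lexicographically smallest SNP id. The per-class argmin
reading is an interpretation consistent with local + distal peak counts
adding to the reported total.

**Two-tier calibration.** Each tier (local, distal) is a Bonferroni family
controlled at α = 0.05; the union of the two tiers is therefore controlled
at 2α, not α. Null-cohort tests assert the per-tier guarantee (zero hits
per tier in ≥ 95% of seeds) and the acceptance script reports both per-tier
zero-hit fractions.

**Conditioning.** Per probe with a peak eSNP, the ClinStatus omnibus F
p-value is extracted from the covariate model with and without the SNP
term; the table carries both NLPs, a sign-consistency flag of the status
coefficients between models, the Spearman rank correlation of the NLPs, and
counts significant at the 0.05/n_probes Bonferroni level in either model.

## Interaction mapping and the Q-K mixed model

The screen tests Model 2 against Model 1 by partial F (RSS bookkeeping
verified against explicit refits). Pairs where any status group is
monomorphic for the SNP are skipped as non-estimable. Per-group slopes
(slope_E = β_SNP; slope_FU = β_SNP + β_SNP×FU; …) are reported for
plotting. Thresholds reuse the two-tier scheme with the interaction-stage
probe/SNP counts. At the default planted effect of 0.5 log2/allele and
n = 173 the interaction F sits near the genome-wide boundary (p ~ 1e-5 to
1e-9 against thresholds ~4e-6), so the screen recovers a fraction of
planted effects — slope estimates, by contrast, are essentially unbiased.

Kinship: method-of-moments IBD — per pair, observed IBS-state counts are
combined with their allele-frequency expectations to solve for P(IBD=0/1/2);
π̂ = P(IBD=1)/2 + P(IBD=2), truncated to [0,1] only at the end (clipping
components individually biases null relatedness upward). Pairs with < 50
comparable SNPs get π̂ = NaN. The estimator uses sample allele frequencies
without finite-sample corrections; on 2,000 pruned SNPs the null bias is
below 0.01 and the sib mean is 0.5 within 0.01. LD pruning is greedy and
windowed (50 SNPs, step 5, r² < 0.3, MAF ≥ 0.10, zero missingness),
keeping the earlier-position SNP of an offending pair; distant within-
chromosome pairs are not rechecked, as in standard windowed pruners.

The mixed refit fits y = Xβ + u + ε with cov(u) = σ²g·G, G = 2K (π̂
approximates twice the kinship coefficient, so 2K is the numerator
relationship matrix). Non-PSD G gets minimal eigenvalue bending. The single
variance ratio δ = σ²g/σ²e is profiled by REML on the spectral
decomposition of G (bounded scalar search on log δ ∈ [−12, 12]); the
interaction coefficients get a Wald F with residual df — an approximation
(the reference implementation's df method is unstated); with G ∝ I the GLS
fit and test reduce exactly to OLS, which the tests assert to 1e-6.
Refits apply only to screen-significant pairs (the screen is cheap, the
refit is not), so the final set is a subset of the screen by construction.
Ancestry PCs (Q) may enter the refit as fixed covariates; whether the
published analysis included them is ambiguous, so both modes are supported.

Under a polygenic sibship null (h² = 0.5), the naive OLS interaction test
is anticonservative when sib pairs are concordant for clinical status (the
interaction predictor is then correlated within families — the adversarial
configuration used in the acceptance test, observed type-I ≈ 0.07 at
nominal 0.05), while the mixed test stays within Monte-Carlo error of
nominal. With status-discordant pairs (patients paired with their sibling
controls) the OLS miscalibration largely vanishes.

## Problem sizes used in tests

Unit tests run on cohorts of 100–200 samples with 10–5,000 SNPs and 5–500
probes. The calibration acceptance test runs twenty 500-probe × 5,000-SNP
null scans at n = 173; recovery tests plant 30 local eSNPs per cohort over
six seeds; the mixed-model calibration uses 2,000 refits. The whole suite
completes in about a minute on one CPU, the acceptance script in about half
a minute.

## Known limitations

* Allele labels are opaque (array convention); strandedness is ignored.
* The probe-annotation pipeline (genome alignment, RefSeq filtering, probes
  overlaying SNPs) is not reproducible without array manifests; probe
  annotations are inputs, and a helper removes a user-supplied list of
  SNP-overlapping probes.
* The Wald-F df in the mixed model and the pooled VCA summary are stated
  conventions, not derived quantities.
* Cohort-specific published counts (numbers of significant probes, eSNPs,
  interactions) depend on the original data and are mirrored here only as
  parameter-recovery properties on synthetic cohorts.
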