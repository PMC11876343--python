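# Methods

This note documents the models behind each `pgslink` stage, the synthetic
data-generating process, the parameter defaults and why they were chosen,
numerical conventions, and known limitations.

## The synthetic study

The generator (`pgslink.simulate`) emulates the statistical structure that
every downstream stage assumes, at a scale a single CPU handles in seconds.

**Genome.** Each protein gets one cis region of
`n_variants_per_cis_region` (default 20) variants around its transcription
start site; the disease PGS consists of `pgs_n_variants` (default 200)
mutually independent loci placed far from every cis region. Haplotypes
within a region follow a first-order binary Markov chain whose transition
probabilities are derived from the bivariate Bernoulli covariance
ρ·√(p₁q₁p₂q₂), so the realized correlation between *adjacent dosages*
targets `ld_rho` (default 0.6) directly; the chain is clipped to
feasibility when adjacent minor-allele frequencies differ. Variants within
a region share a jittered regional base frequency (drawn uniformly from
`maf_range`, default (0.05, 0.5), ± 0.02), both because variants in an LD
block have similar frequencies in real panels and because widely different
marginals make high dosage correlations infeasible for binary variables.
Regions are mutually independent — the minimal LD model under which
clumping and colocalization are non-trivial.

**Phenotype chain.** With PGS standardized,

- BMI = γ·PGS + ε, γ = `gamma_bmi` (default 0.3, a realistic share of
  variance for an adiposity score);
- protein_p = δ_p·PGS + b_p·BMI + Σ cis effects + Σ trans effects + ε_p,
  with b_p = f·τ/γ and δ_p = (1−f)·τ so the total PGS→protein effect is
  exactly τ (`pgs_total_effect`, default 0.15 per SD) with mediated
  fraction f (`mediated_fraction`, default 0.3) — the closed-form
  product-of-coefficients identity f = γ·b/(γ·b+δ);
- cis architecture: `n_causal_cis` (default 4) causal variants per region,
  spread so their pairwise LD (ρ^gap) is weak, each with
  β = √(h²_cis/k) on the standardized dosage (`protein_h2_cis` default
  0.2); residual variance completes each protein to unit variance and a
  budget exceeding 1 raises a configuration error;
- one *trans hub* variant affects `n_trans_hit` (default 6) proteins,
  deliberately crossing the ≥ 5-protein pleiotropy filter so instrument QC
  is exercised end to end;
- incident disease is a logistic liability in the causal proteins
  (`disease_log_odds`, default 0.5 per SD, for the first `n_true_targets`
  proteins, which are both the PGS targets and the disease-causal set —
  completing the PGS → protein → disease chain), BMI, and mild age/sex
  terms, with the intercept calibrated by root-finding to
  `disease_prevalence` (default 0.1). Prevalent disease is assigned
  independently at half that rate and excludes incident status. Disease is
  binary in the biobank arm because the mediation design treats incident
  status as an indicator; time-to-event structure lives in the trial arm.

BMI affects only the target proteins (via f) and the liability. Giving
non-target proteins adiposity paths would create additional true
PGS→protein effects through BMI and blur the planted 10-of-50 truth that
the recovery tests count against.

**Colocalization scenarios.** Causal-protein cis regions share their
causal variants with the disease through the protein (scenario `shared`);
`n_distinct_regions` (default 5) non-causal regions receive a *direct*
disease effect on a cis variant that is not a pQTL (`distinct`); all other
regions are `null` on the disease side. The scenario label per region is
recorded in the truth ledger.

**GWAS samples.** The two-sample MR currency is produced by drawing
disjoint sample sets over the same variant map: the proteomics cohort
(4000 discovery + 2000 replication — a 2:1 split; the real design's ratio
is exposed as config, not fixed), a pQTL exposure sample
(`n_gwas_exposure`, default 4000) and a disease outcome GWAS sample
(`n_gwas_outcome`, default 20 000 — a binary trait at 10% prevalence needs
roughly this many samples for cis instruments of a 0.5-per-SD causal
protein to be detectable, which is exactly the regime the real studies
operate in). Quantitative GWAS use covariate-residualized per-variant
least squares (exact single-predictor OLS after projecting the covariates
out of phenotype and dosages); binary GWAS use a per-variant Newton
logistic fit warm-started from the covariate-only model. Reported p-values
use the normal approximation to z = β/se, keeping the stated
p-vs-z consistency invariant exact. Effect-allele frequency equals column
mean dosage / 2 exactly.

**Trial.** Event times are exponential with
log-hazard = Σ loghr_p·protein_p + 0.02·(age−57) + 0.2·prior-HF over the
endpoint's causal set (`trial_log_hr` default 0.4 per SD,
`n_trial_causal` = 5 per endpoint with overlapping sets for MACE/HHF/renal),
independent exponential dropout censoring at `censor_rate` (default
0.05/year) plus administrative end at 5 years, a random treatment-arm
flag, and two protein timepoints at test–retest correlation
`test_retest_rho` (default 0.7, typical for plasma proteins). One designated
protein's hazard flows entirely through NT-proBNP (its clinical-tier
covariate), so tiered adjustment has something to find. A
`reverse_causation` switch adds a fixed boost to the *repeat* measurement
of causal proteins in subjects with early events.

## Analysis stages

**Scoring.** score_i = Σ w_j·d_ij with the dosage complemented (2−d) when
the weight's effect allele matches the panel's other allele; variants
missing from the panel are dropped by default (mean-imputation contributes
only a constant and is therefore a no-op for association testing);
irreconcilable allele pairs are dropped with a warning count. Strand
ambiguity is not resolved at scoring time — weights are assumed
pre-harmonized; palindrome handling lives in MR harmonization where the
two-sample design requires it.

**Clumping.** Greedy: smallest-p variant passing the threshold becomes an
index; unclaimed variants within ±window (inclusive, same chromosome)
with dosage r² above the threshold are claimed; ties on p are broken by
lexicographically smaller variant id, making output independent of row
order. Zero-variance variants are treated as duplicates (r² = 1).

**Two-stage scan.** Proteins and scores are standardized within stratum so
betas are per-SD and cross-score comparisons are scale-free. Partial R²
for the variance-explained labelling is t²/(t²+df) of the PGS term, not
model R². Replication q-values are computed within score, never pooled.
Pairs significant only *after* covariate adjustment are flagged
`gained_after_adjustment` and excluded from headline counts (adjusting for
a collider can manufacture association). Missing protein values are
complete-case per protein.

**Mediation.** Continuous: mediator ~ exposure + C and
outcome ~ exposure + mediator + C; NIE = a·b, NDE = c′, TE = c′ + a·b
(additivity holds to numerical tolerance by construction); inference by
percentile bootstrap over rows (default 1000 replicates; fewer than 100 is
refused), p-values by two-sided bootstrap inversion. Binary: the
imputation-based natural-effects estimator — fit the observed-data
logistic model, duplicate each row with a counterfactual direct-path
exposure drawn by permuting the observed exposures, impute the expected
outcome, and fit the natural-effects logistic model to the expanded data;
effects are log-odds, proportion mediated = NIE/(NDE+NIE), and the whole
procedure is bootstrapped. Effects at numerical zero (relative magnitude
below 1e−10) count as concordant when deciding whether a
direct/indirect sign conflict suppresses the proportion mediated.
Exposure–mediator confounding is assumed absent (the genetic exposure is
fixed at conception); the sensitivity analysis
nie(ρ) = a·(b − ρ·σ_y·resid/σ_m·resid) covers mediator–outcome confounding
only, with ρ* the grid root of the indirect effect.

**MR.** Fixed-effect IVW is the base estimator (Cochran's Q reported for
heterogeneity transparency); the median estimators use the interpolated
cumulative-weight rule with parametric-bootstrap SEs (1000 draws,
seedable); MR-Egger orients all exposure betas non-negative and fits WLS
with intercept, the intercept t-test (df J−2) with residual-dispersion
scaling being the directional-pleiotropy gate — exactly calibrated under
the parametric null. Harmonization flips swapped alleles, aligns
unambiguous palindromes by frequency and drops ambiguous ones
(minor-frequency > 0.42 on either side, the common practice threshold).
The consensus is the median of the four estimator p-values (mean of the
2nd and 3rd order statistics), FDR across proteins, Bonferroni over
proteins × 4 methods, with Egger-intercept-flagged proteins excluded from
the significant set. MVMR fits WLS of outcome betas on both exposures'
betas without intercept; Q uses df J−2; the conditional F for exposure k
is the weighted residual sum of squares after regressing its betas on the
other exposure's (weights 1/se²_xk), divided by J−1 — published df
conventions differ, so this statistic is validated by calibration tests
rather than package equality. Retention requires both conditional F > 10
and Q p > 0.05.

**Colocalization.** Wakefield log-ABF per variant with effect prior
sd = 0.15·sdY for quantitative traits (sdY = 1 for standardized proteins,
assumed and logged) and 0.20 for case-control log-odds. Hypothesis sums
are kept in log space; H3 uses logdiff(L1+L2, L12) with a −∞ guard when
the difference underflows. The decision rule treats PP.H4/PP.H3 as +∞
when PP.H3 = 0. Trans-region colocalization reuses the same machinery —
no special-case code. Region pairs are seeded by variants below p < 10⁻⁶
in both GWAS, ±250 kb, 1-based inclusive, with overlapping seeds merged.

**Trial survival.** Cox fits go through lifelines (Efron ties, Newton
precision 10⁻⁹); the proportional-hazards diagnostic regresses scaled
Schoenfeld residuals on Kaplan–Meier-transformed times (identity and rank
transforms available) with the global statistic the chi-square sum over
terms; flagged models are reported, not dropped. Tiers nest:
base (age, sex, age×sex, PCs 1–10) ⊂ clinical (+ prior HF, CAD, AF, eGFR,
UACR) ⊂ clinical+NT-proBNP. Discovery applies Bonferroni over proteins ×
endpoints; replication BH-FDR restricted to discovery hits. Competing
risks are handled by censoring. On the repeat-measurement contrast: a
repeat-timepoint hazard ratio exceeding the baseline one is the
signature of reverse causation. Adjusting the repeat fit for baseline does
**not** attenuate that inflation — a boost caused by the event itself is
not blocked by conditioning on the earlier measurement, and empirically
the adjusted coefficient grows — so the diagnostic implemented here is the
complementary contrast: under pure forward causation the repeat
measurement carries no information beyond baseline and its
baseline-adjusted coefficient collapses, while under reverse causation it
persists.

**Enrichment.** Upper-tail hypergeometric P[X ≥ k] with the population
restricted to the assayed background, BH across tested pathways
(a standard, testable substitute for proprietary multiple-testing
corrections in web tools); enrichment-only, one-sided.

## Covariates

Synthetic cohorts carry {age, sex, age×sex, PCs 1–10}; cohort-specific
batch/centre/array covariates have no portable definition and exist only
as optional generator columns. GWAS adjust for age, sex and PCs.

## Numerical conventions

- All randomness flows from `numpy.random.SeedSequence([seed, stage_tag,
  subseed])`; identical config ⇒ bit-identical outputs, including every
  TSV (fixed `%.10g` float formatting). The pipeline manifest records
  SHA-256 digests and reruns reproduce them byte for byte.
- Normal-approximation p-values in GWAS tables; t-tail p-values in the
  per-pair association scan (checked against the t distribution at 1e−10).
- Bonferroni thresholds are α/(family size) with the families named in
  config, never hard-coded counts; the mediation significance family is
  configurable because printed family sizes for that design are not
  reconstructable from first principles.
- Degenerate inputs raise typed errors (`ConfigError`, `NoOverlapError`,
  `CollinearityError` naming the offending columns, `NoEventsError`,
  `InsufficientInstrumentsError`, …); skips in batch analyses are recorded
  with reasons rather than raised.

## What the tests do and do not show

The generator draws unrelated individuals, independent LD blocks with a
single Markov-chain decay, Gaussian protein noise, and exponential event
times. Passing recovery tests therefore demonstrates the estimators are
correct under their stated assumptions and the pipeline is wired
correctly — not robustness to realistic human LD, relatedness, ancestry
admixture, assay batch structure, non-collapsibility subtleties of
log-odds mediation at high prevalence, or model misspecification in the
trial arm. Problem sizes in the shipped benchmark runs (e.g. 10 000-sample
mediation grids, 20 000-sample outcome GWAS, 500–1000 null replicates per
calibration) were chosen as the smallest at which the Monte-Carlo error of
each check is comfortably inside its assertion band.

## Known limitations

- Single-causal-variant colocalization only; no LD-aware Bayes factors or
  credible sets.
- No Steiger filtering or winner's-curse correction in MR; the reverse-MR
  design carries the directionality burden.
- Binary-outcome mediation reports log-odds natural effects; proportion
  mediated on that scale is not collapsible across covariate sets.
- The cross-ancestry beta comparison is unweighted Pearson correlation;
  precision weighting is not implemented.
- The trial simulator models one generic renal endpoint; real trials
  define renal composites differently, and endpoint labels are metadata.
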