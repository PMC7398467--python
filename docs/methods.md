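# Methods

## Scope and data model

The unit of evidence is one study's case/control genotype counts for one
variant: triples (wt/wt, wt/var, var/var) for each arm.  All pooling is
of crude (unadjusted) odds ratios; covariate-adjusted estimates, allele
counts without genotypes, and overlapping samples across publications are
out of scope — `study_id` uniqueness per variant is the caller's
responsibility and duplicated rows are rejected at parse time.

Eligibility filtering drops variants whose stated control minor-allele
frequency is below `min_maf` (default 0.01).  A missing MAF never
excludes a variant: many older candidate-gene sources lack it, and
absence of an annotation is not evidence of rarity.  It only disables the
MAF-based power variant (below).

## Genetic contrasts and per-study effects

Three contrasts collapse the genotype triple into a 2×2 table: allelic
(per-allele, 2N chromosomes), dominant (carrier), recessive (homozygote).
The allelic model treats the two chromosomes of one person as independent
observations; this ignores within-person correlation and is a documented
limitation (it is exact under Hardy-Weinberg equilibrium and standard
practice in this literature).

Per-study effects are Woolf estimates.  Continuity correction is
table-wise: 0.5 is added to all four cells of any table containing a
zero, and only to such tables.  The `corrected` flag records this.  A
contrast whose exposed column is zero in both arms is still usable after
correction (its estimate is 1 with a wide variance); only a table with an
empty case or control margin is an error.

## Pooling and method selection

Fixed-effect pooling is Mantel-Haenszel evaluated on the *raw* tables —
MH tolerates zero cells natively, so corrected cells would only bias it —
with the Robins-Breslow-Greenland variance for the log pooled OR, which
stays consistent under both sparse-strata and large-strata asymptotics.
Random-effects pooling is DerSimonian-Laird inverse-variance on the
(corrected) per-study estimates.  MH is defined on tables and DL on
estimates, which is why the two entry points take different inputs.

Per variant and per model: fewer than `min_studies` (default 3)
independent studies → not meta-analysed; otherwise Cochran's Q against
the fixed inverse-variance mean decides the method at p < 0.05
(random effects under substantial heterogeneity, fixed effects
otherwise).  The choice is made independently for each genetic model of
the same variant.  A recessive contrast with no variant homozygote in any
study of the variant is reported as unavailable rather than pooled from
pure correction artifacts.

p-values are two-sided normal on the pooled log OR.  No multiple-testing
correction is applied anywhere: classification operates at the nominal
0.05 level by design, and the credibility machinery (BFDP, power, I²) is
the guard against false positives.

## Heterogeneity

I² = max(0, (Q−df)/Q)·100.  Its 95% CI uses the Higgins-Thompson
test-based standard error of ln H, H = √(Q/df):
se(ln H) = ½·(ln Q − ln df)/(√(2Q) − √(2k−3)) when Q > k, and the
moment-based formula √(1/(2(k−2))·(1 − 1/(3(k−2)²))) when Q ≤ k with
k > 2.  For k = 2 with small Q neither form is defined and the interval
is reported as the full (0, 100) range — visible in published synopsis
tables as "0 (0 to 100)" for two-study rows.  Interval ends are truncated
to [0, 100] and by construction bracket the point estimate.

## Small-study effects

The Egger test regresses the standardized effect yᵢ/sᵢ on precision
1/sᵢ (ordinary least squares); the intercept's two-sided t-test with
k−2 df flags asymmetry.  The flag threshold defaults to p < 0.10 — the
conventional level for this low-powered test — and is configuration, not
fact.  The test needs k ≥ 3 and non-constant precisions; it runs on the
allelic-model effects only, and its result is reported as an annotation
(together with the four fixed qualitative protection-from-bias
considerations: phenotype definition, genotyping error, cross-study
replication, population stratification), never as a classification
input.

## Power

Power of the two-sided α-level Wald test at a true log OR θ:
Φ(|θ|/se − z₁₋α∕₂) + Φ(−|θ|/se − z₁₋α∕₂); at θ = 0 this recovers α
exactly.  Two bases for the standard error are exposed:

* `pooled_se` (default): the pooled meta-analytic se with θ set to the
  pooled log OR — the power of the meta-analysis to detect its own
  observed effect;
* `maf_expected`: the Woolf se of the null design table expected under
  HWE at the control MAF in both arms (allelic uses 2N chromosomes) —
  monotone decreasing in MAF and scaling as 1/√N.  Available only when
  the variant's MAF is stated.

## BFDP

Wakefield's approximate Bayes factor for the null against a N(0, W)
alternative on the log OR scale:
ABF = √((V+W)/V)·exp(−θ̂²W/(2V(V+W))), and
BFDP = ABF·PO/(ABF·PO+1) with prior odds of the null PO = (1−π)/π.
Defaults: W = (ln 1.5/1.96)², i.e. a 95% prior interval of (2/3, 1.5)
for the OR under the alternative (Wakefield's worked convention), and the
prior grid π ∈ {0.05, 10⁻³, 10⁻⁴, 10⁻⁶} spanning the candidate-gene to
random-SNP range.  The noteworthiness threshold 0.2 is the optimal
decision boundary when a false discovery costs four times a false
non-discovery: declare noteworthy iff BFDP·C_FD < (1−BFDP)·C_FND, i.e.
BFDP < 1/(1+4).

BFDP is monotone: strictly decreasing in |θ̂| and non-increasing in π;
as W → 0⁺ the alternative collapses onto the null, ABF → 1 and
BFDP → 1−π.

## Venice grades and classification

Amount of evidence: A/B/C at power > 0.80 / [0.50, 0.80] / < 0.50.
Replication consistency: A/B/C at I² < 25 / [25, 50) / ≥ 50 (the
boundary I² = 50 is graded C, consistent with the "I² below 50"
requirement of the positive class).

Four-tier label per variant:

* **positive** — p < α in at least two *available* models, BFDP < 0.2 at
  the π = 0.05 prior, power > 0.80, I² < 50;
* **less-credible positive** — significant in ≥1 model, failing any
  positive criterion;
* **null** — no significant model and more than 5000 accrued cases;
* **negative** — no significant model and ≤5000 cases (too little
  evidence to call the association null).

Design choices made where the published rules are ambiguous:

* The BFDP criterion is evaluated at prior π = 0.05, the top of the
  medium/low (candidate-gene) grid.
* The power and I² feeding classification come from the *headline*
  model — the available model with the smallest p-value.  A worst-case-I²
  rule is available (`i2_rule: worst`) but would contradict published
  synopsis labels in which a positive variant's non-headline model shows
  I² > 50.
* "Significant in ≥2 models" counts only available models, so a variant
  whose recessive contrast is structurally missing (rare homozygotes)
  can still be positive via the allelic and dominant models.

External validation: the smallest available consortium p-value sets the
status — genome-wide at p ≤ 5×10⁻⁸, nominal at p < 0.05, failed
otherwise; a missing record or poor imputation quality leaves the variant
untested.  Only a positive label with failed status is downgraded (to
less-credible positive); other labels never change, so the only possible
difference between the labels before and after validation is that single
downgrade.

## Synthetic catalogs

The generator emulates the statistical structure the pipeline assumes.
Controls are multinomial draws from HWE genotype frequencies at the
control MAF.  Study i's true log OR is
θᵢ = ln(OR) + N(0, τ²) + b·seᵢ, where seᵢ is the study's expected
allelic Woolf se under the null design, so the bias coefficient b
inflates imprecise studies more — the signature of small-study /
publication bias.  Case genotype frequencies follow the multiplicative
per-allele odds model: HWE weights times exp(θᵢ)^g (g = variant-allele
copies), renormalised; under this model the allelic case/control odds
ratio equals exp(θᵢ) exactly.  One global seed drives the catalog;
per-study streams derive from (seed, study_index), so fixed seeds give
bit-identical output.

Default scenario: MAF 0.3, OR 1.3, τ = 0, 12 studies of 2000 cases and
2000 controls — a well-powered, moderately sized synopsis entry typical
of the confirmed low-penetrance loci this pipeline is built to grade.

What the generator does *not* emulate: linkage disequilibrium between
variants, covariates and confounding, population stratification,
genotyping error, selective publication of whole studies (bias enters
only through the per-study effect shift), or cohort/GWAS design
differences (all records are case-control draws).  Passing calibration
therefore shows the pipeline is correct under its own assumptions, not
that real catalogs satisfy them.

## Calibration suites and problem sizes

The acceptance checks run the full pipeline on simulated catalogs at
these sizes, chosen to balance Monte-Carlo error against runtime:

* type-I error: 1000 null catalogs (OR = 1), 10 studies of 1000/1000;
  the pooled allelic p < 0.05 rate must lie in [0.035, 0.065] — the band
  is around, not exactly at, 0.05 because the Q-gated switch to random
  effects perturbs the test slightly;
* fixed-effect CI coverage: 500 homogeneous catalogs (OR = 1.3, τ = 0),
  8 studies of 1000/1000; coverage in [0.93, 0.97];
* classification recovery: 400 catalogs at OR = 1.3 (12 × 2000/2000)
  must classify positive ≥90% of the time; 2000 null catalogs with
  24 000 accrued cases must classify null ≥90% with ≤2% positives.
  The null rate sits near 90–91% because three correlated model tests at
  nominal 0.05 produce a family-wise significance rate just under 10% —
  the classifier sends those to less-credible positive by design;
* Egger calibration: 500 catalogs of 10 studies with sizes geometrically
  spaced from 200 to 5000; the unbiased flag rate at threshold 0.10 must
  lie in [0.05, 0.15] and the rate under injected bias (b = 1) must
  exceed it.

## Numerical conventions

z₀.₉₇₅ is fixed at 1.959964 throughout (including the prior-variance
default), matching the printing conventions of published synopsis
tables.  Wald p-values underflow to exactly 0.0 beyond |z| ≈ 39 in
double precision.  Ties in headline-model selection follow the fixed
model order allelic, recessive, dominant.  All output files are
deterministic functions of inputs and configuration; logs contain no
timestamps so reruns are byte-identical.
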