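"""Evidence appraisal: power, BFDP, Venice grading and classification.

This module turns a variant's three pooled model results into a
credibility verdict:

* statistical power of the meta-analysis to detect its own pooled effect
  at alpha = 0.05 (or, alternatively, the power implied by the design —
  allele frequency and sample sizes — under Hardy-Weinberg equilibrium);
* the Bayesian False-Discovery Probability (BFDP) over a grid of prior
  probabilities of association, using Wakefield's approximate Bayes
  factor; an association is "noteworthy" when BFDP < 0.2, the threshold
  implied by a false discovery costing four times a false non-discovery;
* Venice grades for amount of evidence (power) and replication
  consistency (I^2), with protection-from-bias reported as an annotation;
* a four-tier label (positive / less-credible positive / null / negative)
  and, when external GWAS-consortium summary results are supplied, a
  validation status with the positive→less-credible downgrade on failure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats

from .catalog_io import ExternalValidationRecord, VariantKey
from .meta_analysis import MetaResult, Z_95
from .small_study_bias import EggerResult

# classification labels
POSITIVE = "positive"
LESS_CREDIBLE = "less_credible_positive"
NULL = "null"
NEGATIVE = "negative"
NOT_META_ANALYSED = "not_meta_analysed"

# validation statuses
GENOME_WIDE = "genome_wide"
NOMINAL = "nominal"
FAILED = "failed"
UNTESTED = "untested"

DEFAULT_PRIOR_GRID = (0.05, 1e-3, 1e-4, 1e-6)

#: Fixed qualitative protection-from-bias considerations reported alongside
#: the Egger flag: phenotype definition, genotyping error, cross-study
#: replication, population stratification.
BIAS_PROTECTION_NOTES = (
    "phenotype definition addressed by inclusion criteria",
    "genotyping error rates generally low",
    "replication across studies addresses genotyping-quality variation",
    "population stratification effects generally small",
)


@dataclass(frozen=True)
class CredibilityConfig:
    """Thresholds and choices for the appraisal stage."""

    alpha: float = 0.05
    bfdp_threshold: float = 0.2
    prior_grid: tuple[float, ...] = DEFAULT_PRIOR_GRID
    prior_or_bound: float = 1.5   # 97.5% prior quantile of the OR under H1
    power_basis: str = "pooled_se"  # or "maf_expected"
    i2_rule: str = "headline"     # or "worst"
    egger_threshold: float = 0.10
    min_studies: int = 3
    null_case_threshold: int = 5000
    gw_threshold: float = 5e-8

    @property
    def prior_w(self) -> float:
        """Prior variance W of the log OR under the alternative."""
        return (math.log(self.prior_or_bound) / Z_95) ** 2


@dataclass(frozen=True)
class BfdpResult:
    prior_pi: float
    W: float
    abf: float
    bfdp: float
    noteworthy: bool


@dataclass(frozen=True)
class PowerSpec:
    alpha: float
    basis: str
    power: float


@dataclass(frozen=True)
class VeniceGrades:
    amount: str       # A/B/C by power
    replication: str  # A/B/C by I^2
    bias_note: str


@dataclass
class CredibilityResult:
    variant: Optional[VariantKey]
    p_values: dict[str, float]
    power: Optional[PowerSpec]
    bfdp_grid: list[BfdpResult]
    venice: Optional[VeniceGrades]
    egger: Optional[EggerResult]
    label: str
    label_after_validation: str
    validation_status: str
    headline_model: Optional[str] = None
    i2_used: float = float("nan")


def noteworthiness_threshold(cost_ratio: float = 4.0) -> float:
    """BFDP decision threshold implied by the cost of a false discovery
    being ``cost_ratio`` times the cost of a false non-discovery.

    Declaring noteworthy is optimal when bfdp * cost_fd <
    (1 - bfdp) * cost_fnd, i.e. bfdp < 1/(1 + cost_ratio).
    """
    if cost_ratio <= 0:
        raise ValueError("cost_ratio must be positive")
    return 1.0 / (1.0 + cost_ratio)


def statistical_power(theta: float, se: float, alpha: float = 0.05) -> float:
    """Power of the two-sided alpha-level Wald test at true log OR ``theta``.

    power = Phi(|theta|/se - z_{1-a/2}) + Phi(-|theta|/se - z_{1-a/2});
    at theta = 0 this recovers alpha exactly.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    z_crit = stats.norm.isf(alpha / 2)
    u = abs(theta) / se
    return float(stats.norm.cdf(u - z_crit) + stats.norm.cdf(-u - z_crit))


def expected_se(maf: float, n_cases: int, n_controls: int,
                model: str) -> float:
    """Design-based Woolf se of the null contrast table expected under HWE.

    Both groups are given the control genotype distribution at ``maf``;
    the allelic model counts 2N chromosomes.  Monotone decreasing in maf
    on (0, 0.5] and scaling as 1/sqrt(N).
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample sizes must be positive")
    if model == "allelic":
        exposed = maf
        n_case_units, n_ctrl_units = 2 * n_cases, 2 * n_controls
    elif model == "dominant":
        exposed = 1 - (1 - maf) ** 2
        n_case_units, n_ctrl_units = n_cases, n_controls
    elif model == "recessive":
        exposed = maf ** 2
        n_case_units, n_ctrl_units = n_cases, n_controls
    else:
        raise ValueError(f"unknown model: {model}")
    a = n_case_units * exposed
    b = n_case_units * (1 - exposed)
    c = n_ctrl_units * exposed
    d = n_ctrl_units * (1 - exposed)
    return math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)


def bfdp(theta_hat: float, V: float, prior_pi: float, W: float) -> BfdpResult:
    """Wakefield's Bayesian False-Discovery Probability.

    ABF = sqrt((V+W)/V) * exp(-theta_hat^2 W / (2 V (V+W))) is the
    approximate Bayes factor for the null against a N(0, W) alternative;
    with prior odds of the null PO = (1 - pi)/pi,
    BFDP = ABF*PO / (ABF*PO + 1).
    """
    if V <= 0 or W <= 0:
        raise ValueError("V and W must be positive")
    if not (0 < prior_pi <= 1):
        raise ValueError("prior_pi must lie in (0, 1]")
    log_abf = 0.5 * math.log((V + W) / V) - theta_hat**2 * W / (2 * V * (V + W))
    abf = math.exp(log_abf)
    po = (1 - prior_pi) / prior_pi
    val = abf * po / (abf * po + 1.0)
    return BfdpResult(prior_pi=prior_pi, W=W, abf=abf, bfdp=val,
                      noteworthy=val < 0.2)


def bfdp_grid(theta_hat: float, V: float,
              priors: Sequence[float] = DEFAULT_PRIOR_GRID,
              W: Optional[float] = None) -> list[BfdpResult]:
    """BFDP at each prior probability of association in ``priors``."""
    if len(priors) == 0:
        raise ValueError("prior grid must be non-empty")
    if W is None:
        W = CredibilityConfig().prior_w
    return [bfdp(theta_hat, V, pi, W) for pi in priors]


def venice_grades(power: float, i2: float,
                  egger: Optional[EggerResult] = None) -> VeniceGrades:
    """Venice A/B/C grades for amount of evidence and replication.

    Amount: A when power > 0.80, B when 0.50 <= power <= 0.80, C below.
    Replication: A when I^2 < 25, B when 25 <= I^2 < 50, C when I^2 >= 50.
    Protection from bias is an annotation, never a classification input.
    """
    if not (0 <= power <= 1):
        raise ValueError("power must lie in [0, 1]")
    if not (0 <= i2 <= 100):
        raise ValueError("i2 must lie in [0, 100]")
    amount = "A" if power > 0.80 else ("B" if power >= 0.50 else "C")
    replication = "A" if i2 < 25 else ("B" if i2 < 50 else "C")
    notes = list(BIAS_PROTECTION_NOTES)
    if egger is not None:
        notes.insert(0, "Egger small-study test "
                     + ("FLAGGED" if egger.flagged else "not flagged")
                     + f" (p={egger.p_value:.3g})")
    return VeniceGrades(amount=amount, replication=replication,
                        bias_note="; ".join(notes))


def classify(p_values: dict[str, float], bfdp_at_pi005: float, power: float,
             i2: float, n_cases: int,
             config: CredibilityConfig = CredibilityConfig()) -> str:
    """Four-tier classification of one variant's pooled evidence.

    positive: significant (p < alpha) in >= 2 of the available models AND
    BFDP < 0.20 AND power > 0.80 AND I^2 < 50.  less-credible positive:
    significant in >= 1 model but failing any positive criterion.  With no
    significant model the variant is null when more than
    ``null_case_threshold`` cases were accrued, otherwise negative (too
    little evidence to call it null).
    """
    ps = [p for p in p_values.values() if p is not None and not math.isnan(p)]
    if not ps:
        raise ValueError("need at least one available model result")
    n_sig = sum(p < config.alpha for p in ps)
    if (n_sig >= 2 and bfdp_at_pi005 < config.bfdp_threshold
            and power > 0.80 and i2 < 50):
        return POSITIVE
    if n_sig >= 1:
        return LESS_CREDIBLE
    if n_cases > config.null_case_threshold:
        return NULL
    return NEGATIVE


def apply_validation(
    label: str, external: Optional[ExternalValidationRecord],
    config: CredibilityConfig = CredibilityConfig(),
) -> tuple[str, str]:
    """Attach the external-GWAS validation verdict to a label.

    Status is genome_wide / nominal / failed by the smallest available
    external p-value, or untested when no usable record exists.  Only a
    ``positive`` label with status ``failed`` is downgraded (to
    less-credible positive); every other label passes through unchanged.
    """
    if external is None or not external.imputation_ok or not external.p_values:
        return label, UNTESTED
    p_min = min(external.p_values)
    if p_min <= config.gw_threshold:
        status = GENOME_WIDE
    elif p_min < config.alpha:
        status = NOMINAL
    else:
        status = FAILED
    if label == POSITIVE and status == FAILED:
        return LESS_CREDIBLE, status
    return label, status


def assess_variant(
    model_results: dict[str, MetaResult],
    egger: Optional[EggerResult] = None,
    external: Optional[ExternalValidationRecord] = None,
    config: CredibilityConfig = CredibilityConfig(),
) -> CredibilityResult:
    """Full appraisal of one variant from its per-model pooled results.

    The headline model is the available model with the smallest p-value;
    its power and (under the default ``headline`` rule) its I^2 feed the
    classification.  Appraisal is only performed for variants significant
    in at least one model; others go straight to null/negative.
    """
    available = {m: r for m, r in model_results.items() if r.status == "ok"}
    variant = next(iter(model_results.values())).variant if model_results else None
    if not available:
        return CredibilityResult(
            variant=variant, p_values={}, power=None, bfdp_grid=[],
            venice=None, egger=egger, label=NOT_META_ANALYSED,
            label_after_validation=NOT_META_ANALYSED,
            validation_status=UNTESTED)

    p_values = {m: r.p_value for m, r in available.items()}
    headline = min(available, key=lambda m: available[m].p_value)
    head = available[headline]

    if config.power_basis == "maf_expected" and variant is not None \
            and variant.maf is not None:
        se_for_power = expected_se(variant.maf, head.n_cases,
                                   head.n_controls, headline)
        basis = "maf_expected"
    else:
        se_for_power = head.se_log
        basis = "pooled_se"
    power = statistical_power(head.log_or, se_for_power, config.alpha)
    power_spec = PowerSpec(alpha=config.alpha, basis=basis, power=power)

    if config.i2_rule == "worst":
        i2_used = max(r.i2 for r in available.values())
    else:
        i2_used = head.i2

    grid = bfdp_grid(head.log_or, head.se_log**2, config.prior_grid,
                     config.prior_w)
    bfdp_top = grid[0].bfdp  # prior 0.05, top of the medium/low grid
    venice = venice_grades(power, min(i2_used, 100.0), egger)
    label = classify(p_values, bfdp_top, power, i2_used, head.n_cases, config)
    label_after, status = apply_validation(label, external, config)
    return CredibilityResult(
        variant=variant, p_values=p_values, power=power_spec,
        bfdp_grid=grid, venice=venice, egger=egger, label=label,
        label_after_validation=label_after, validation_status=status,
        headline_model=headline, i2_used=i2_used)
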