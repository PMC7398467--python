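"""Per-variant pooling of study effects under each genetic model.

Fixed-effect pooling uses the Mantel-Haenszel odds ratio computed directly
on the raw 2x2 tables with the Robins-Breslow-Greenland variance for its
log; random-effects pooling uses DerSimonian-Laird inverse-variance
weighting of the per-study (continuity-corrected) Woolf estimates with the
moment estimator of the between-study variance tau^2.

The method is chosen per variant and per model by Cochran's Q: when the
heterogeneity p-value falls below 0.05 the random-effects model is used,
otherwise the fixed-effect model.  Variants with fewer than three
independent studies are not pooled at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .catalog_io import StudyGenotypeRecord, VariantKey
from .genetic_models import ContrastTable, EffectEstimate, contrast_table, effect_estimate

Z_95 = 1.959964  # two-sided 95% normal quantile

FIXED_MH = "fixed_MH"
RANDOM_DL = "random_DL"


class MetaAnalysisError(ValueError):
    pass


@dataclass
class MetaResult:
    """Pooled result for one variant under one genetic model."""

    variant: Optional[VariantKey]
    model: str
    status: str = "ok"  # ok | not_meta_analysed | model_unavailable
    n_studies: int = 0
    n_cases: int = 0
    n_controls: int = 0
    pooled_or: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    se_log: float = float("nan")
    p_value: float = float("nan")
    q: float = float("nan")
    q_p: float = float("nan")
    i2: float = float("nan")
    i2_low: float = float("nan")
    i2_high: float = float("nan")
    tau2: float = 0.0
    method: str = FIXED_MH

    @property
    def log_or(self) -> float:
        return math.log(self.pooled_or)


def cochran_q(effects: Sequence[EffectEstimate]) -> tuple[float, int, float]:
    """Cochran's Q against the fixed inverse-variance pooled mean.

    Returns ``(q, df, q_p)`` with the p-value from the chi-square(df)
    upper tail.
    """
    if len(effects) < 2:
        raise MetaAnalysisError("insufficient_studies")
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    y_fixed = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - y_fixed) ** 2))
    df = len(effects) - 1
    q_p = float(stats.chi2.sf(q, df))
    return q, df, q_p


def i_squared(q: float, df: int) -> tuple[float, float, float]:
    """Higgins-Thompson I^2 with its test-based 95% confidence interval.

    I^2 = max(0, (Q - df)/Q) * 100.  The CI is built on ln H where
    H = sqrt(Q/df), using the test-based standard error of ln H and
    truncating to [0, 100].
    """
    if df < 1:
        raise MetaAnalysisError("df must be >= 1")
    i2 = max(0.0, (q - df) / q) * 100.0 if q > 0 else 0.0
    k = df + 1
    ln_h = 0.5 * math.log(max(q / df, 1.0))
    if q > k:
        se_ln_h = 0.5 * (math.log(q) - math.log(df)) / (
            math.sqrt(2 * q) - math.sqrt(2 * k - 3))
    elif k > 2:
        se_ln_h = math.sqrt(1.0 / (2 * (k - 2)) * (1 - 1.0 / (3 * (k - 2) ** 2)))
    else:
        # k = 2 with Q <= k: no usable test-based se; report the full range.
        return i2, 0.0, 100.0
    lo, hi = ln_h - Z_95 * se_ln_h, ln_h + Z_95 * se_ln_h

    def h_to_i2(ln_h_val: float) -> float:
        h2 = math.exp(2 * ln_h_val)
        return max(0.0, min(100.0, (h2 - 1) / h2 * 100.0))

    return i2, h_to_i2(lo), h_to_i2(hi)


def pool_fixed_mh(tables: Sequence[ContrastTable]) -> MetaResult:
    """Mantel-Haenszel fixed-effect pooled OR over raw 2x2 tables.

    OR_MH = sum(a_i d_i / N_i) / sum(b_i c_i / N_i); the variance of
    ln OR_MH is the Robins-Breslow-Greenland estimator, which remains
    consistent under both sparse-data and large-strata asymptotics.
    """
    if len(tables) < 1:
        raise MetaAnalysisError("insufficient_studies")
    model = tables[0].model
    R = S = 0.0
    sum_PR = sum_PSQR = sum_QS = 0.0
    for t in tables:
        n = t.n
        p_i = (t.a + t.d) / n
        q_i = (t.b + t.c) / n
        r_i = t.a * t.d / n
        s_i = t.b * t.c / n
        R += r_i
        S += s_i
        sum_PR += p_i * r_i
        sum_PSQR += p_i * s_i + q_i * r_i
        sum_QS += q_i * s_i
    if S <= 0 or R <= 0:
        raise MetaAnalysisError("degenerate_mh")
    or_mh = R / S
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    se = math.sqrt(var)
    log_or = math.log(or_mh)
    z = log_or / se
    return MetaResult(
        variant=None, model=model, n_studies=len(tables),
        pooled_or=or_mh, se_log=se,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        p_value=float(2 * stats.norm.sf(abs(z))),
        tau2=0.0, method=FIXED_MH,
    )


def pool_random_dl(effects: Sequence[EffectEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooling of per-study estimates.

    tau^2 = max(0, (Q - df)/C) with C = sum(w) - sum(w^2)/sum(w); the
    pooled mean reweights by w*_i = 1/(s_i^2 + tau^2).
    """
    if len(effects) < 2:
        raise MetaAnalysisError("insufficient_studies")
    q, df, _ = cochran_q(effects)
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    c = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (q - df) / c) if c > 0 else 0.0
    w_star = 1.0 / (np.array([e.se**2 for e in effects]) + tau2)
    log_or = float(np.sum(w_star * y) / np.sum(w_star))
    se = float(1.0 / math.sqrt(np.sum(w_star)))
    z = log_or / se
    return MetaResult(
        variant=None, model=effects[0].model, n_studies=len(effects),
        pooled_or=math.exp(log_or), se_log=se,
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        p_value=float(2 * stats.norm.sf(abs(z))),
        tau2=tau2, method=RANDOM_DL,
    )


def meta_analyse(
    records: Sequence[StudyGenotypeRecord],
    model: str,
    min_studies: int = 3,
    het_p_threshold: float = 0.05,
) -> MetaResult:
    """Full pooling pipeline for one variant under one genetic model.

    Fewer than ``min_studies`` independent studies → status
    ``not_meta_analysed``.  A model carrying no information at all (e.g.
    the recessive contrast of a variant with no homozygotes anywhere) →
    status ``model_unavailable``.  Otherwise Cochran's Q decides between
    Mantel-Haenszel fixed-effect (q_p >= threshold) and DerSimonian-Laird
    random-effects pooling.
    """
    variant = records[0].variant if records else None
    if len(records) < min_studies:
        return MetaResult(variant=variant, model=model,
                          status="not_meta_analysed", n_studies=len(records))
    tables, effects = [], []
    for r in records:
        t = contrast_table(r, model)
        tables.append(t)
        effects.append(effect_estimate(t, study_id=r.study_id))
    if model == "recessive" and all(
            r.case_counts[2] == 0 and r.control_counts[2] == 0 for r in records):
        return MetaResult(variant=variant, model=model,
                          status="model_unavailable", n_studies=len(records))

    q, df, q_p = cochran_q(effects)
    i2, i2_lo, i2_hi = i_squared(q, df)
    if q_p < het_p_threshold:
        result = pool_random_dl(effects)
    else:
        result = pool_fixed_mh(tables)
    result.variant = variant
    result.q, result.q_p = q, q_p
    result.i2, result.i2_low, result.i2_high = i2, i2_lo, i2_hi
    result.n_cases = sum(r.n_cases for r in records)
    result.n_controls = sum(r.n_controls for r in records)
    return result


def wald_p_from_ci(or_hat: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal p-value reconstructed from an OR and its 95% CI.

    Useful for re-deriving p-values from published tables that print only
    the point estimate and interval.
    """
    if ci_low <= 0:
        raise ValueError("ci_low must be positive")
    if ci_high < ci_low:
        raise ValueError("ci_high must be >= ci_low")
    se = (math.log(ci_high) - math.log(ci_low)) / (2 * Z_95)
    if se == 0:
        return 1.0 if or_hat == 1.0 else 0.0
    z = math.log(or_hat) / se
    return float(2 * stats.norm.sf(abs(z)))
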