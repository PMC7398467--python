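"""Egger regression test for small-study effects and funnel-plot export.

The Egger test regresses the standardized effect z_i = y_i / s_i on the
precision 1/s_i by ordinary least squares; under no small-study bias the
intercept is zero, and a two-sided t-test on the intercept (k - 2 df)
flags funnel-plot asymmetry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genetic_models import EffectEstimate


class EggerError(ValueError):
    pass


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    t_stat: float
    p_value: float
    df: int
    flagged: bool


def egger_test(effects: Sequence[EffectEstimate],
               threshold: float = 0.10) -> EggerResult:
    """Run the Egger intercept test; flag if the intercept p < threshold."""
    k = len(effects)
    if k < 3:
        raise EggerError("insufficient_studies")
    z = np.array([e.log_or / e.se for e in effects])
    x = np.array([1.0 / e.se for e in effects])
    if np.allclose(x, x[0]):
        raise EggerError("degenerate_regression")
    fit = sm.OLS(z, sm.add_constant(x)).fit()
    resid_var = fit.ssr / (k - 2)
    if resid_var <= 0 or not np.isfinite(fit.bse[0]):
        raise EggerError("degenerate_regression")
    intercept = float(fit.params[0])
    se = float(fit.bse[0])
    t = intercept / se
    p = float(2 * stats.t.sf(abs(t), k - 2))
    return EggerResult(intercept=intercept, intercept_se=se, t_stat=t,
                       p_value=p, df=k - 2, flagged=p < threshold)


def funnel_data(effects: Sequence[EffectEstimate]) -> pd.DataFrame:
    """One row per study: log_or, se, precision and standardized effect."""
    return pd.DataFrame(
        [{"log_or": e.log_or, "se": e.se, "precision": 1.0 / e.se,
          "standardized_effect": e.log_or / e.se} for e in effects],
        columns=["log_or", "se", "precision", "standardized_effect"],
    )
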