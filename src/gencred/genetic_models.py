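"""Collapse genotype counts into 2x2 contrast tables and per-study effects.

Three genetic contrasts are supported:

* ``allelic``   — variant allele vs wild-type allele (2N chromosomes);
* ``dominant``  — carriers (wt/var + var/var) vs non-carriers;
* ``recessive`` — variant homozygotes vs everyone else.

Each table yields a Woolf log odds ratio with its large-sample standard
error; tables containing a zero cell receive the standard 0.5 continuity
correction on all four cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .catalog_io import StudyGenotypeRecord

MODELS = ("allelic", "recessive", "dominant")


@dataclass(frozen=True)
class ContrastTable:
    """A 2x2 case-control table under one genetic model.

    a = exposed cases, b = unexposed cases, c = exposed controls,
    d = unexposed controls.  ``corrected`` records whether the 0.5
    continuity correction was applied (iff any raw cell was zero).
    """

    model: str
    a: float
    b: float
    c: float
    d: float
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model: {self.model}")
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValueError("empty_table")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio y_i and standard error s_i."""

    log_or: float
    se: float
    study_id: str = ""
    model: str = "allelic"

    def __post_init__(self) -> None:
        if not math.isfinite(self.log_or):
            raise ValueError("log_or must be finite")
        if not (self.se > 0):
            raise ValueError("se must be positive")


def contrast_table(record: StudyGenotypeRecord, model: str) -> ContrastTable:
    """Build the 2x2 table for ``record`` under ``model``.

    Allelic counts treat the 2N chromosomes as independent observations.
    If any of the four cells is zero, 0.5 is added to all four and
    ``corrected`` is set.
    """
    cw, ch, cv = record.case_counts
    kw, kh, kv = record.control_counts
    if model == "allelic":
        a, b = 2 * cv + ch, 2 * cw + ch
        c, d = 2 * kv + kh, 2 * kw + kh
    elif model == "dominant":
        a, b = ch + cv, cw
        c, d = kh + kv, kw
    elif model == "recessive":
        a, b = cv, cw + ch
        c, d = kv, kw + kh
    else:
        raise ValueError(f"unknown model: {model}")
    a, b, c, d = float(a), float(b), float(c), float(d)
    if a + b == 0 or c + d == 0:
        raise ValueError("empty_table")
    if min(a, b, c, d) == 0:
        return ContrastTable(model, a + 0.5, b + 0.5, c + 0.5, d + 0.5,
                             corrected=True)
    return ContrastTable(model, a, b, c, d, corrected=False)


def effect_estimate(table: ContrastTable, study_id: str = "") -> EffectEstimate:
    """Woolf estimate: log OR = ln(ad/bc), se = sqrt(1/a+1/b+1/c+1/d)."""
    if min(table.a, table.b, table.c, table.d) <= 0:
        raise ValueError("all cells must be positive (apply correction first)")
    log_or = math.log(table.a * table.d / (table.b * table.c))
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    return EffectEstimate(log_or=log_or, se=se, study_id=study_id,
                          model=table.model)
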