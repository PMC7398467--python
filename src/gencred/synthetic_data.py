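"""Synthetic study catalogs with known ground truth.

Controls are drawn multinomially from Hardy-Weinberg genotype frequencies
at the control minor-allele frequency.  Each study i receives a true
log odds ratio

    theta_i = ln(OR) + Normal(0, tau^2) + bias_coeff * se_i,

where se_i is the study's expected allelic Woolf standard error under the
null design — so a positive ``bias_coeff`` inflates small (imprecise)
studies more, emulating small-study/publication bias.  Case genotype
frequencies follow the multiplicative per-allele odds model: HWE weights
multiplied by exp(theta_i)^g (g = copies of the variant allele) and
renormalised.

One global seed controls the whole catalog; each study's RNG stream is
derived deterministically from (seed, study_index), so a fixed seed yields
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog_io import StudyGenotypeRecord, VariantKey
from .credibility import expected_se


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth parameters for one simulated variant catalog."""

    maf: float = 0.3
    or_allelic: float = 1.3
    tau: float = 0.0
    n_studies: int = 12
    case_sizes: tuple[int, ...] = ()
    control_sizes: tuple[int, ...] = ()
    bias_coeff: float = 0.0
    seed: int = 0
    gene: str = "SIM"
    variant_id: str = "rs0"

    def __post_init__(self) -> None:
        if not (0 < self.maf <= 0.5):
            raise ValueError("maf must lie in (0, 0.5]")
        if self.or_allelic <= 0:
            raise ValueError("or_allelic must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.case_sizes and len(self.case_sizes) != self.n_studies:
            raise ValueError("case_sizes length must equal n_studies")
        if self.control_sizes and len(self.control_sizes) != self.n_studies:
            raise ValueError("control_sizes length must equal n_studies")
        if any(s <= 0 for s in (*self.case_sizes, *self.control_sizes)):
            raise ValueError("study sizes must be positive")

    def case_size(self, i: int) -> int:
        return self.case_sizes[i] if self.case_sizes else 2000

    def control_size(self, i: int) -> int:
        return self.control_sizes[i] if self.control_sizes else 2000


def hwe_frequencies(maf: float) -> np.ndarray:
    """HWE genotype frequencies (wt/wt, wt/var, var/var) at allele freq maf."""
    q = 1.0 - maf
    return np.array([q * q, 2 * q * maf, maf * maf])


def case_genotype_frequencies(maf: float, theta: float) -> np.ndarray:
    """Case genotype frequencies under the multiplicative per-allele model.

    HWE weights times exp(theta)^g, renormalised; g is the number of
    variant alleles carried.
    """
    odds = math.exp(theta)
    w = hwe_frequencies(maf) * np.array([1.0, odds, odds * odds])
    total = w.sum()
    if not (total > 0 and np.isfinite(total)):
        raise RuntimeError("case genotype probabilities failed to normalize")
    return w / total


def _study_theta(scenario: SimScenario, i: int,
                 rng: np.random.Generator) -> float:
    theta = math.log(scenario.or_allelic)
    if scenario.tau > 0:
        theta += rng.normal(0.0, scenario.tau)
    if scenario.bias_coeff != 0.0:
        se_i = expected_se(scenario.maf, scenario.case_size(i),
                           scenario.control_size(i), "allelic")
        theta += scenario.bias_coeff * se_i
    return theta


def _study_rng(scenario: SimScenario, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([scenario.seed, i]))


def simulate_study(scenario: SimScenario, study_index: int,
                   ) -> tuple[StudyGenotypeRecord, float]:
    """Draw one study's genotype counts; returns the record and theta_i."""
    rng = _study_rng(scenario, study_index)
    theta = _study_theta(scenario, study_index, rng)
    variant = VariantKey(gene=scenario.gene, variant_id=scenario.variant_id,
                         effect_allele="var", maf=scenario.maf)
    controls = rng.multinomial(scenario.control_size(study_index),
                               hwe_frequencies(scenario.maf))
    cases = rng.multinomial(scenario.case_size(study_index),
                            case_genotype_frequencies(scenario.maf, theta))
    record = StudyGenotypeRecord(
        study_id=f"study_{study_index:03d}",
        variant=variant,
        case_counts=tuple(int(x) for x in cases),
        control_counts=tuple(int(x) for x in controls),
        design_tag="case-control",
    )
    return record, theta


def simulate_catalog(
    scenario: SimScenario,
) -> tuple[list[StudyGenotypeRecord], pd.DataFrame]:
    """Simulate all studies of a scenario plus the truth sidecar.

    The sidecar has one row per study: study_id, theta_i, true_or, tau.
    """
    records, thetas = [], []
    for i in range(scenario.n_studies):
        rec, theta = simulate_study(scenario, i)
        records.append(rec)
        thetas.append(theta)
    truth = pd.DataFrame({
        "study_id": [r.study_id for r in records],
        "theta_i": thetas,
        "true_or": scenario.or_allelic,
        "tau": scenario.tau,
    })
    return records, truth


def read_scenario(path) -> SimScenario:
    """Load a scenario from a flat key: value YAML file."""
    import yaml
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("case_sizes", "control_sizes"):
        if key in raw and raw[key] is not None:
            raw[key] = tuple(int(x) for x in raw[key])
    return SimScenario(**raw)
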