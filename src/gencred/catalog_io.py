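"""Read, validate and write variant-study catalogs and validation summaries.

The catalog is a TSV with one row per (study, variant) holding case and
control genotype counts, mirroring the standardised extraction tables of a
field synopsis.  The external-validation file carries per-variant p-values
from an independent GWAS consortium meta-analysis under the additive,
dominant and recessive models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

CATALOG_COLUMNS = [
    "study_id", "gene", "variant_id", "effect_allele", "maf",
    "case_wtwt", "case_wtvar", "case_varvar",
    "ctrl_wtwt", "ctrl_wtvar", "ctrl_varvar", "design",
]

EXTERNAL_COLUMNS = [
    "gene", "variant_id", "p_additive", "p_dominant", "p_recessive",
    "imputation_ok", "n_cases", "n_controls",
]


class CatalogError(ValueError):
    """Hard error for a malformed catalog (e.g. missing mandatory column)."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of one polymorphism: gene label, variant label, effect allele.

    ``maf`` is the minor-allele frequency in controls, used only for
    eligibility filtering and the design-based power variant; it may be
    missing (None).
    """

    gene: str
    variant_id: str
    effect_allele: str = ""
    maf: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf must lie in [0, 1], got {self.maf}")

    @property
    def label(self) -> tuple[str, str]:
        """Grouping key: (gene, variant_id)."""
        return (self.gene, self.variant_id)


@dataclass(frozen=True)
class StudyGenotypeRecord:
    """One study's genotype counts for one variant.

    Counts are (wt/wt, wt/var, var/var) triples for cases and controls.
    """

    study_id: str
    variant: VariantKey
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]
    design_tag: str = "case-control"

    def __post_init__(self) -> None:
        for c in (*self.case_counts, *self.control_counts):
            if c < 0:
                raise ValueError("genotype counts must be non-negative")
        if sum(self.case_counts) == 0 or sum(self.control_counts) == 0:
            raise ValueError("need at least one case and one control")

    @property
    def n_cases(self) -> int:
        return sum(self.case_counts)

    @property
    def n_controls(self) -> int:
        return sum(self.control_counts)


@dataclass(frozen=True)
class ExternalValidationRecord:
    """Per-variant validation p-values from an external GWAS consortium."""

    variant: VariantKey
    p_additive: Optional[float] = None
    p_dominant: Optional[float] = None
    p_recessive: Optional[float] = None
    imputation_ok: bool = True
    n_cases: int = 0
    n_controls: int = 0

    @property
    def p_values(self) -> list[float]:
        """The available (non-missing) p-values, any model."""
        return [p for p in (self.p_additive, self.p_dominant, self.p_recessive)
                if p is not None]


@dataclass
class ParseReport:
    """Accounting of one file read: kept records and per-row reject reasons."""

    n_rows: int
    records: list
    rejects: list[tuple[int, str]]  # (0-based data row index, reason)

    def __post_init__(self) -> None:
        assert len(self.records) + len(self.rejects) == self.n_rows


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"true", "1", "yes", "t"}
    return bool(value)


def read_catalog(path) -> ParseReport:
    """Parse a catalog TSV into validated :class:`StudyGenotypeRecord`s.

    Rows failing validation are rejected individually with a reason
    (``negative_count``, ``duplicate_study``, ``empty_counts``,
    ``bad_maf``); a missing mandatory column raises :class:`CatalogError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in CATALOG_COLUMNS:
        if col not in df.columns:
            raise CatalogError(f"missing mandatory column: {col}")

    records: list[StudyGenotypeRecord] = []
    rejects: list[tuple[int, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for idx, row in df.iterrows():
        try:
            counts = [int(row[c]) for c in CATALOG_COLUMNS[5:11]]
        except ValueError:
            rejects.append((idx, "bad_count"))
            continue
        if any(c < 0 for c in counts):
            rejects.append((idx, "negative_count"))
            continue
        if sum(counts[:3]) == 0 or sum(counts[3:]) == 0:
            rejects.append((idx, "empty_counts"))
            continue
        key = (row["study_id"], row["gene"], row["variant_id"])
        if key in seen:
            rejects.append((idx, "duplicate_study"))
            continue
        try:
            variant = VariantKey(
                gene=row["gene"],
                variant_id=row["variant_id"],
                effect_allele=row["effect_allele"],
                maf=_opt_float(row["maf"]),
            )
        except ValueError:
            rejects.append((idx, "bad_maf"))
            continue
        seen.add(key)
        records.append(StudyGenotypeRecord(
            study_id=row["study_id"],
            variant=variant,
            case_counts=tuple(counts[:3]),
            control_counts=tuple(counts[3:]),
            design_tag=row["design"],
        ))
    return ParseReport(n_rows=len(df), records=records, rejects=rejects)


def write_catalog(records: Iterable[StudyGenotypeRecord], path) -> None:
    """Write records back to the catalog TSV schema (round-trip safe)."""
    rows = []
    for r in records:
        v = r.variant
        rows.append({
            "study_id": r.study_id, "gene": v.gene, "variant_id": v.variant_id,
            "effect_allele": v.effect_allele,
            "maf": "" if v.maf is None else repr(v.maf),
            "case_wtwt": r.case_counts[0], "case_wtvar": r.case_counts[1],
            "case_varvar": r.case_counts[2],
            "ctrl_wtwt": r.control_counts[0], "ctrl_wtvar": r.control_counts[1],
            "ctrl_varvar": r.control_counts[2], "design": r.design_tag,
        })
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_external_validation(path) -> ParseReport:
    """Parse the external-validation TSV; one record per variant.

    Missing p-values stay missing (None).  A p-value outside (0, 1] rejects
    the row with reason ``bad_pvalue``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "variant_id"):
        if col not in df.columns:
            raise CatalogError(f"missing mandatory column: {col}")

    records: list[ExternalValidationRecord] = []
    rejects: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        ps = {}
        bad = False
        for name in ("p_additive", "p_dominant", "p_recessive"):
            p = _opt_float(row.get(name))
            if p is not None and not (0.0 < p <= 1.0):
                bad = True
                break
            ps[name] = p
        if bad:
            rejects.append((idx, "bad_pvalue"))
            continue
        records.append(ExternalValidationRecord(
            variant=VariantKey(gene=row["gene"], variant_id=row["variant_id"]),
            imputation_ok=_as_bool(row.get("imputation_ok", True)),
            n_cases=int(row.get("n_cases") or 0),
            n_controls=int(row.get("n_controls") or 0),
            **ps,
        ))
    return ParseReport(n_rows=len(df), records=records, rejects=rejects)


def group_by_variant(
    records: Iterable[StudyGenotypeRecord],
) -> dict[tuple[str, str], list[StudyGenotypeRecord]]:
    """Group study records by (gene, variant_id), preserving input order."""
    groups: dict[tuple[str, str], list[StudyGenotypeRecord]] = {}
    for r in records:
        groups.setdefault(r.variant.label, []).append(r)
    return groups


@dataclass
class EligibilityResult:
    kept: list
    excluded: list[tuple[StudyGenotypeRecord, str]]
    flags: dict[tuple[str, str], str]


def apply_eligibility(
    records: Sequence[StudyGenotypeRecord], min_maf: float = 0.01,
) -> EligibilityResult:
    """Drop variants whose stated control MAF falls below ``min_maf``.

    A variant with no stated MAF is kept but flagged ``maf_missing`` —
    absence of an allele-frequency annotation (common for older candidate
    gene sources) is not evidence of rarity.
    """
    if not (0.0 <= min_maf <= 0.5):
        raise ValueError("min_maf must lie in [0, 0.5]")
    kept, excluded = [], []
    flags: dict[tuple[str, str], str] = {}
    for r in records:
        maf = r.variant.maf
        if maf is None:
            flags[r.variant.label] = "maf_missing"
            kept.append(r)
        elif maf < min_maf:
            excluded.append((r, "maf_below_threshold"))
        else:
            kept.append(r)
    return EligibilityResult(kept=kept, excluded=excluded, flags=flags)
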