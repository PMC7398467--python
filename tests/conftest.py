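import pandas as pd
import pytest

from gencred import StudyGenotypeRecord, VariantKey


@pytest.fixture
def variant():
    return VariantKey(gene="GENE1", variant_id="rs111", effect_allele="A",
                      maf=0.3)


@pytest.fixture
def record(variant):
    return StudyGenotypeRecord(
        study_id="s1", variant=variant,
        case_counts=(10, 20, 5), control_counts=(20, 15, 5))


def make_record(study_id, cases, controls, gene="GENE1", variant_id="rs111",
                maf=0.3):
    return StudyGenotypeRecord(
        study_id=study_id,
        variant=VariantKey(gene=gene, variant_id=variant_id,
                           effect_allele="A", maf=maf),
        case_counts=tuple(cases), control_counts=tuple(controls))


def write_catalog_tsv(path, rows):
    """Write raw rows (dicts) to a catalog-format TSV without validation."""
    cols = ["study_id", "gene", "variant_id", "effect_allele", "maf",
            "case_wtwt", "case_wtvar", "case_varvar",
            "ctrl_wtwt", "ctrl_wtvar", "ctrl_varvar", "design"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = ""
    df[cols].to_csv(path, sep="\t", index=False)
    return path


def catalog_row(study_id="s1", gene="GENE1", variant_id="rs111",
                effect_allele="A", maf=0.3, cases=(10, 20, 5),
                controls=(20, 15, 5), design="case-control"):
    return {
        "study_id": study_id, "gene": gene, "variant_id": variant_id,
        "effect_allele": effect_allele, "maf": maf,
        "case_wtwt": cases[0], "case_wtvar": cases[1], "case_varvar": cases[2],
        "ctrl_wtwt": controls[0], "ctrl_wtvar": controls[1],
        "ctrl_varvar": controls[2], "design": design,
    }
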