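import io

import numpy as np
import pandas as pd
import pytest

from riskoverlap import (Cohort, RateTable, default_config, generate_cohort,
                         load_rate_table)


@pytest.fixture(scope="session")
def white_rates() -> RateTable:
    return load_rate_table("White")


@pytest.fixture(scope="session")
def chinese_rates() -> RateTable:
    return load_rate_table("Chinese")


@pytest.fixture(scope="session")
def rates_by_population(white_rates, chinese_rates):
    return {"White": white_rates, "Chinese": chinese_rates}


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Synthetic cohort at 2% of the emulated study's size (~3600 subjects)."""
    return generate_cohort(default_config(seed=11).scaled(0.02))


def flat_rate_table(h1=0.01, h2=0.0, one_minus_ar=1.0, lo=20, hi=90):
    """Single-band table for closed-form checks."""
    return RateTable(population="flat", age_start=np.array([lo]),
                     age_end=np.array([hi]), h1=np.array([h1]),
                     h2=np.array([h2]), one_minus_ar=np.array([one_minus_ar]))


def phenotype_frame(rows):
    """Build a minimal phenotype DataFrame from per-subject dicts."""
    defaults = dict(study_id="ST1", ancestry="European", age=45.0,
                    status="control", control_source="population",
                    age_menarche="ge14", age_first_birth="lt20",
                    n_relatives="0", n_biopsies="0",
                    atypical_hyperplasia="no", prs_raw=np.nan)
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults, subject_id=f"X{i:04d}")
        rec.update(row)
        records.append(rec)
    return pd.DataFrame(records)


def phenotype_cohort(rows) -> Cohort:
    from riskoverlap.cohort import LEVELS

    df = phenotype_frame(rows)
    for col, levels in LEVELS.items():
        if col in df.columns:
            df[col] = pd.Categorical(df[col].astype(str), categories=levels)
    return Cohort(df)


def phenotype_tsv(rows) -> io.StringIO:
    buf = io.StringIO()
    phenotype_frame(rows).to_csv(buf, sep="\t", index=False)
    buf.seek(0)
    return buf
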