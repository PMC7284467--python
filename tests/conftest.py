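import numpy as np
import pandas as pd
import pytest

from dietomics import synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-participant cohort with a few planted effects, shared read-only."""
    spec = sc.CohortSpec(n_participants=400, seed=11, n_proteins=8,
                         n_metabolites=12)
    plan = sc.EffectPlan(
        entries=(("DASH", "M0001", 0.5), ("AHEI", "P0001", 0.5)),
        noise_sd=1.0,
    )
    return sc.generate_cohort(spec, plan)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def intake_table(rng):
    """A plain intake table with distinct values for rank scoring."""
    n = 120
    ids = pd.Index([f"S{i:04d}" for i in range(n)], name="participant_id")
    fields = ["vegetables", "fruits", "fruit_juice", "nuts", "legumes",
              "whole_grains", "low_fat_dairy", "red_processed_meat", "fish",
              "ssb", "ssb_fruit_juice", "mufa_sfa_ratio", "pufa_pct",
              "trans_pct", "omega3_mg", "sodium_mg", "alcohol_g_day"]
    df = pd.DataFrame({f: rng.random(n) * 5 for f in fields}, index=ids)
    df["energy_kcal"] = rng.normal(1900, 400, n).clip(700)
    df["n_blank_items"] = 0
    return df


@pytest.fixture
def sex_series(intake_table, rng):
    vals = np.where(rng.random(len(intake_table)) < 0.5, "female", "male")
    return pd.Series(vals, index=intake_table.index, name="sex")
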