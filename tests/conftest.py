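import numpy as np
import pandas as pd
import pytest

import mrisubtype as ms


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-subject simulated trial cohort shared by read-only tests."""
    return ms.generate_cohort(ms.SimulationConfig(n_subjects=60, seed=42), validate=True)


@pytest.fixture(scope="session")
def small_derived(small_cohort):
    return ms.derive_measures(small_cohort)


@pytest.fixture(scope="session")
def analysis_table(small_cohort, small_derived):
    profiles, _ = ms.build_subtype_profiles(small_cohort, small_derived)
    return ms.build_analysis_table(small_cohort, small_derived, profiles)


def make_regression_frame(n=200, seed=0, beta=None, sigma=1.0):
    """Synthetic model-input frame with known coefficients.

    ``beta`` maps design columns (const, treatment, severity, typicality,
    age, severity_x_treatment, typicality_x_treatment) to true values;
    unmentioned terms are zero.
    """
    rng = np.random.default_rng(seed)
    beta = beta or {}
    df = pd.DataFrame({
        "treatment": rng.permutation(np.arange(n) % 2).astype(float),
        "severity": rng.normal(29.0, 12.0, n),
        "typicality": rng.normal(0.2, 0.03, n),
        "age": rng.normal(73.0, 6.0, n),
        "field_strength_3t": (rng.random(n) < 0.26).astype(float),
    })
    y = np.full(n, float(beta.get("const", 0.0)))
    for term in ("treatment", "severity", "typicality", "age", "field_strength_3t"):
        y = y + beta.get(term, 0.0) * df[term].to_numpy()
    y = y + beta.get("severity_x_treatment", 0.0) * (df["severity"] * df["treatment"]).to_numpy()
    y = y + beta.get("typicality_x_treatment", 0.0) * (df["typicality"] * df["treatment"]).to_numpy()
    df["y"] = y + sigma * rng.standard_normal(n)
    return df
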