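import numpy as np
import pytest

import afscreen as a
from afscreen import cohort_io


@pytest.fixture(scope="session")
def models():
    return a.load_model_definitions()


@pytest.fixture(scope="session")
def small_cohort():
    """Analysis-ready synthetic cohort (~7.5k rows), no missingness."""
    spec = a.SyntheticSpec(n=10_000, seed=11, missingness_rates={})
    raw = cohort_io.compute_bmi(a.generate_cohort(spec))
    cohort, _ = cohort_io.apply_exclusions(raw)
    return cohort


@pytest.fixture(scope="session")
def masked_cohort():
    """Same construction with MCAR missingness injected."""
    spec = a.SyntheticSpec(n=10_000, seed=11)
    raw = a.generate_cohort(spec)
    raw = a.inject_missingness(raw, spec.missingness_rates, seed=12)
    cohort, _ = cohort_io.apply_exclusions(cohort_io.compute_bmi(raw))
    return cohort


@pytest.fixture(scope="session")
def small_stack(masked_cohort):
    cfg = a.ImputationConfig(m=3, iterations=4, seed=21)
    return a.impute_chained(masked_cohort, cfg)
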