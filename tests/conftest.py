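import numpy as np
import pandas as pd
import pytest

import le8surv as L


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across tests (fixed seed)."""
    spec = L.CohortSpec(n_participants=4000, seed=11)
    cohort, diagnoses = L.generate_cohort(spec)
    return spec, cohort, diagnoses


@pytest.fixture(scope="session")
def scored(small_cohort):
    _, cohort, _ = small_cohort
    return L.score_cohort(cohort)


@pytest.fixture(scope="session")
def mortality_data(small_cohort, scored):
    _, cohort, diagnoses = small_cohort
    surv = L.derive_survival(cohort, diagnoses, L.ALL_CAUSE_MORTALITY)
    return surv.merge(scored[["id", "composite", "quartile"]], on="id").merge(
        cohort, on="id"
    )


@pytest.fixture(scope="session")
def mace_data(small_cohort, scored):
    _, cohort, diagnoses = small_cohort
    surv = L.derive_survival(cohort, diagnoses, L.MACE)
    return surv.merge(scored[["id", "composite", "quartile"]], on="id").merge(
        cohort, on="id"
    )
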