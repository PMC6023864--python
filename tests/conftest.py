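import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import paleoniche as pn

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_stack() -> pn.ClimateStack:
    """A 40x40 five-variable synthetic scenario with mild autocorrelation."""
    cfg = pn.ScenarioConfig(grid_rows=40, grid_cols=40, autocorr_length=3.0, seed=11)
    return pn.generate_climate_stack(cfg)


@pytest.fixture(scope="session")
def niche() -> pn.NicheTruth:
    return pn.NicheTruth(np.zeros(5), np.full(5, 0.5), max_prevalence=0.9)


@pytest.fixture(scope="session")
def presence_table(small_stack, niche) -> pn.TrainingTable:
    suit = pn.true_suitability(small_stack, niche)
    occ = pn.sample_occurrences(suit, 150, seed=21)
    pa = pn.sample_pseudoabsences(small_stack, occ, seed=22)
    return pn.build_training_table(small_stack, occ, pa)


def make_occurrences(x, y, role="presence", period="current") -> pn.OccurrenceSet:
    return pn.OccurrenceSet(pd.DataFrame({
        "x": np.asarray(x, float), "y": np.asarray(y, float),
        "role": role, "period": period}))
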