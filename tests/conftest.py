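"""Shared fixtures: the default synthetic cohort and derived objects.

Session scope keeps the expensive generators to one run; everything is
seeded, so every test sees identical data.
"""

import numpy as np
import pandas as pd
import pytest

from oritrace import (PipelineConfig, SimParams, call_oriprint, classify_cohort,
                      differential_expression, simulate_expression,
                      simulate_methylation)


@pytest.fixture(scope="session")
def default_params() -> SimParams:
    return SimParams()


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def default_cohort(default_params):
    """(MethylCohort, GroundTruth) under the default study conditions."""
    return simulate_methylation(default_params)


@pytest.fixture(scope="session")
def default_signature(default_cohort):
    cohort, _ = default_cohort
    return call_oriprint(cohort)


@pytest.fixture(scope="session")
def default_consensus(default_cohort, default_signature, default_config):
    """Three-method consensus classification of the default cohort."""
    cohort, _ = default_cohort
    return classify_cohort(cohort, default_signature, default_config)


@pytest.fixture(scope="session")
def retrospective(default_params):
    """A 150-patient retrospective expression cohort with known origins.

    Returns (origins, ExprCohort, GroundTruth, DE table, model logCPM
    restricted to the significant genes) — the inputs of the
    transcriptomic-translation stage.
    """
    rng = np.random.default_rng(2024)
    origins = pd.Series(
        rng.permutation(np.array(["FI"] * 75 + ["OSE"] * 75, dtype=object)),
        index=[f"P{i:03d}" for i in range(150)])
    expr, truth = simulate_expression(origins, default_params, preparation="FFPE")
    de = differential_expression(expr.logcpm, origins)
    model = expr.logcpm.loc[de.index[de["significant"]]]
    return origins, expr, truth, de, model
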