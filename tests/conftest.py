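"""Shared fixtures.

The session-scoped default experiment runs the full masking loop once
(20 families, ~2000 dense variants, ~200 scaffold variants, 20 masked
individuals) and is shared by every test that needs pipeline-scale
results.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from pedimpute.core import GenotypeMatrix, Variant
from pedimpute.pipeline import Experiment, ExperimentConfig


def make_matrix(calls, positions=None, ids=None) -> GenotypeMatrix:
    """Small GenotypeMatrix from a nested list; -1 is missing."""
    calls = np.asarray(calls, dtype=np.int8)
    n, v = calls.shape
    positions = positions or [100 * (j + 1) for j in range(v)]
    ids = ids or [f"I{i + 1}" for i in range(n)]
    variants = [Variant(f"v{j + 1}", positions[j]) for j in range(v)]
    return GenotypeMatrix(ids, variants, calls)


@pytest.fixture(scope="session")
def default_experiment() -> Experiment:
    cfg = ExperimentConfig(include_oracle=True)
    return Experiment(cfg)


@pytest.fixture(scope="session")
def default_result(default_experiment):
    return default_experiment.run()
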