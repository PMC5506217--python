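"""Shared fixtures.

The session-scoped ``recovery`` fixture runs the scaled-down
format-comparison study (100 replicates, 11 levels x 40 trials x 2 orders,
error-free regime) for the four scenarios that several tests interrogate;
running it once keeps the suite within a sane wall-clock budget.
"""

from dataclasses import replace

import numpy as np
import pytest

from indecision.simulate import SCENARIOS, recovery_study

RECOVERY_SEED = 0
RECOVERY_REPLICATES = 100
RECOVERY_SCENARIOS = (
    "ternary-detection",
    "ternary-discrimination-same",
    "2AFC-discrimination-same",
    "equality-discrimination-same",
)


@pytest.fixture(scope="session")
def recovery():
    """{scenario-name: (replicate table, summary indexed by parameter)}."""
    out = {}
    for name in RECOVERY_SCENARIOS:
        spec = replace(
            SCENARIOS[name], n_replicates=RECOVERY_REPLICATES, seed=RECOVERY_SEED
        )
        table, summary = recovery_study(spec)
        out[name] = (table, summary.set_index("parameter"))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250925)
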