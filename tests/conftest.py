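import numpy as np
import pytest

from tsameta import (EffectEstimate, SimulationSpec, effect_estimates,
                     generate_meta_dataset)

FIXTURE_SEED = 20260930  # canonical seed for frozen-oracle fixtures


def make_effects(y, v):
    """EffectEstimates from parallel arrays of log ORs and variances."""
    return [
        EffectEstimate(y=float(yi), v=float(vi), corrected=False,
                       included=True, study_id=f"E{i}")
        for i, (yi, vi) in enumerate(zip(y, v))
    ]


@pytest.fixture
def two_effects():
    """y = (0, 2), v = (1, 1): the hand-derivable heterogeneity example."""
    return make_effects([0.0, 2.0], [1.0, 1.0])


@pytest.fixture(scope="session")
def seeded_records():
    """Seeded 12-study heterogeneous dataset behind the frozen oracles."""
    spec = SimulationSpec(k=12, theta=-0.5, tau2=0.12, p_control=(0.1, 0.3),
                          n_min=40, n_max=300, seed=FIXTURE_SEED)
    return generate_meta_dataset(spec)


@pytest.fixture(scope="session")
def seeded_effects(seeded_records):
    return [e for e in effect_estimates(seeded_records) if e.included]


@pytest.fixture(scope="session")
def seeded_effects_k20():
    """Seeded k=20 heterogeneous effects for the likelihood grid oracle."""
    spec = SimulationSpec(k=20, theta=-0.3, tau2=0.08, p_control=(0.1, 0.3),
                          n_min=40, n_max=300, seed=FIXTURE_SEED + 1)
    return [e for e in effect_estimates(generate_meta_dataset(spec))
            if e.included]
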