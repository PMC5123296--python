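import numpy as np
import pandas as pd
import pytest

import varipart as vp


@pytest.fixture
def hand_meta():
    """Hand-written 8-sample table: 2 fixed (age, sex) + 2 random
    (individual, batch) candidates."""
    return pd.DataFrame(
        {
            "individual": ["i1", "i1", "i2", "i2", "i3", "i3", "i4", "i4"],
            "batch": ["b1", "b2", "b1", "b2", "b1", "b2", "b1", "b2"],
            "sex": ["F", "F", "M", "M", "F", "F", "M", "M"],
            "age": [30.0, 30.0, 45.0, 45.0, 52.0, 52.0, 38.0, 38.0],
        },
        index=pd.Index([f"s{i}" for i in range(1, 9)], name="sample_id"),
    )


@pytest.fixture
def oneway_design():
    """Factory: balanced one-way random design with g groups, m replicates."""

    def make(g, m):
        codes = np.repeat(np.arange(g), m)
        meta = pd.DataFrame(
            {"grp": [f"g{c:03d}" for c in codes]},
            index=pd.Index([f"s{i}" for i in range(g * m)], name="sample_id"),
        )
        designs = vp.build_design(meta, vp.parse_formula("(1|grp)"))
        return meta, designs, codes

    return make


@pytest.fixture
def study_scenario():
    """Small multi-factor study: replicated individuals with invariant sex
    and ancestry plus a crossed lab factor."""
    return vp.SimScenario(
        n_samples=120,
        factors=(
            vp.FactorSpec("individual", 60),
            vp.FactorSpec("sex", 2, "invariant-of:individual"),
            vp.FactorSpec("ancestry", 5, "invariant-of:individual"),
            vp.FactorSpec("lab", 7, "random"),
        ),
        fractions={"individual": 0.55, "lab": 0.07, "ancestry": 0.05, "sex": 0.0},
        n_genes=12,
        seed=3,
    )


@pytest.fixture
def study_data(study_scenario):
    return vp.simulate_dataset(study_scenario)
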