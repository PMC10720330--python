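import numpy as np
import pytest

from ffaudit import (
    ConfigurationSet,
    ErrorModelSpec,
    FixtureSpec,
    PredictionRecord,
    generate_predictions,
    generate_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_ds(rng) -> ConfigurationSet:
    """3-frame, 4-atom water-ish set with energies and forces."""
    return ConfigurationSet(
        atomic_numbers=np.array([8, 1, 1, 6]),
        positions=rng.normal(size=(3, 4, 3)),
        energies=rng.normal(size=3),
        forces=rng.normal(size=(3, 4, 3)),
        name="tiny",
    )


@pytest.fixture
def identity_pred(tiny_ds) -> PredictionRecord:
    return PredictionRecord(
        source_id="identity",
        energies=tiny_ds.energies.copy(),
        forces=tiny_ds.forces.copy(),
    )


@pytest.fixture(scope="session")
def basin_ds() -> ConfigurationSet:
    """Three well-separated structural basins, 90 frames, CH4 composition."""
    spec = FixtureSpec(
        formula="CH4", n_frames=90, n_basins=3,
        basin_scale=2.0, thermal_scale=0.05, seed=7,
    )
    return generate_trajectory(spec)


@pytest.fixture(scope="session")
def planted_pair():
    """A 500-frame two-element trajectory with planted H:C error scales 0.1:0.4."""
    spec = FixtureSpec(formula="C6H6", n_frames=500, n_basins=1, seed=11)
    ds = generate_trajectory(spec)
    em = ErrorModelSpec(element_scale={"H": 0.1, "C": 0.4}, seed=12)
    return ds, generate_predictions(ds, em), em
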