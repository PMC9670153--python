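import numpy as np
import pytest

from aufaces.au import AUVector
from aufaces.faces import FaceIdentity, render_face


@pytest.fixture(scope="session")
def average_face():
    return FaceIdentity.average()


@pytest.fixture(scope="session")
def neutral_render(average_face):
    return render_face(average_face, AUVector.zeros(), 64)


@pytest.fixture(scope="session")
def mini_report():
    """One fitted desk-scale twin-culture experiment, shared across tests."""
    from aufaces.experiment import TwinCultureExperiment

    return TwinCultureExperiment.from_fixture("default-twin", scale="mini", master_seed=1).fit()


def micro_config(master_seed: int = 0, fixture: str = "default-twin"):
    """A very small experiment configuration for fast structural tests."""
    import dataclasses

    from aufaces.experiment import fixture_suite
    from aufaces.training import TrainConfig

    cfg = fixture_suite(fixture, scale="mini", master_seed=master_seed)
    return dataclasses.replace(
        cfg,
        database_a=dataclasses.replace(cfg.database_a, n_identities=12),
        database_b=dataclasses.replace(cfg.database_b, n_identities=12),
        train=TrainConfig(total_iterations=150,
                          lr_schedule=((0, 1e-2), (50, 1e-3), (100, 1e-4)),
                          runs=2, split_proportions=(8, 2, 2)),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
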