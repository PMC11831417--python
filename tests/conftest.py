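import warnings

import numpy as np
import pytest

import perfusim as pf


def pytest_configure(config):
    # sklearn's MLP emits convergence warnings at small epoch budgets used
    # in quick tests; they are not failures
    warnings.filterwarnings(
        "ignore", category=UserWarning, module="sklearn"
    )


@pytest.fixture(scope="session")
def ref_params():
    return pf.REFERENCE_KINETICS


@pytest.fixture(scope="session")
def clean_noise():
    return pf.NoiseModel(
        vcd_rel=0.0, viability_abs=0.0, bleed_rel=0.0, titer_rel=0.0,
        diameter_rel=0.0,
    )


@pytest.fixture(scope="session")
def clean_training_records(clean_noise):
    """Noise-free records of the 3-batch training design."""
    from dataclasses import replace

    records, trajs = [], []
    for i, (truth, recipe) in enumerate(pf.make_design("training_3batch")):
        rec, traj = pf.generate_record(
            truth, recipe, noise=replace(clean_noise, seed=i),
            batch_id=f"clean_{i}",
        )
        records.append(rec)
        trajs.append(traj)
    return records, trajs


@pytest.fixture(scope="session")
def noisy_training_records():
    """3-batch training design at the default measurement-noise levels."""
    return pf.generate_design_records("training_3batch", seed=1)


@pytest.fixture(scope="session")
def tiny_pso():
    return pf.PsoConfig(n_particles=8, n_iter=(6, 4), seed=0)
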