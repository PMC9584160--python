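"""Shared fixtures: seeded phantoms and reference libraries.

Phantoms are generated once per session; tests must not mutate them.
Spatial sizes are kept small (32-48 px) so the full suite runs quickly; the
generator's spectral and statistical settings are the package defaults.
"""

import numpy as np
import pytest

from specstack import synthetic_data as syn


@pytest.fixture(scope="session")
def model_phantom():
    """Standard 4-phase aggregate phantom with Poisson noise (seed 0)."""
    spec = syn.model_phantom_spec(seed=0, spatial_shape=(48, 48))
    stack, truth = syn.simulate_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def library11(model_phantom):
    """11-standard library whose first 4 entries generate the model phantom."""
    spec, _, _ = model_phantom
    return syn.phantom_library(spec, 11)


@pytest.fixture(scope="session")
def tiles_phantom():
    """Noiseless 4-quadrant phantom: exactly rank 4, every pixel pure."""
    spec = syn.PhantomSpec(
        seed=0, spatial_shape=(32, 32), geometry="tiles",
        target_fractions=None, poisson=False,
    )
    stack, truth = syn.simulate_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def two_phase_phantom():
    """Noiseless 2-phase half/half phantom for analytic averaging checks."""
    spec = syn.PhantomSpec(
        seed=1, spatial_shape=(24, 24), n_phases=2, geometry="tiles",
        target_fractions=None, poisson=False,
    )
    stack, truth = syn.simulate_stack(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
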