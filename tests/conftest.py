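import numpy as np
import pytest

import sdmkit as sk


@pytest.fixture(scope="session")
def harmonic_model():
    """The default harmonic toy complex: u(d) = -60 + 2 d^2, 6 A site."""
    return sk.harmonic_well(-60.0, 2.0)


@pytest.fixture(scope="session")
def small_grid():
    """A short single-temperature coupling ladder."""
    return sk.StateGrid([0.0, 0.1, 0.25, 0.45, 0.7, 1.0], [300.0])


@pytest.fixture(scope="session")
def harmonic_run(harmonic_model, small_grid):
    """A modest replica-exchange run on the harmonic toy (shared, read-only)."""
    return sk.run_hrem(
        harmonic_model,
        small_grid,
        n_sweeps=6000,
        swap_period=2,
        sample_period=10,
        seed=42,
        step_size=1.2,
    )


@pytest.fixture(scope="session")
def harmonic_oracle(harmonic_model):
    """Quadrature standard-state binding free energy at 300 K."""
    v = harmonic_model.site.volume
    return sk.analytic_binding_free_energy(
        harmonic_model, 300.0
    ) + sk.standard_state_correction(v, 300.0)


@pytest.fixture()
def rng():
    return np.random.Generator(np.random.Philox(np.random.SeedSequence(1234)))
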