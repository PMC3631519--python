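"""Shared simulated fixtures.

Session-scoped: the larger reference panels are expensive enough that every
test module reuses the same simulated universe.  All seeds fixed.
"""

from __future__ import annotations

import numpy as np
import pytest

from forensnp import sim


@pytest.fixture(scope="session")
def ref3_small() -> sim.SimulatedReference:
    """Three moderately drifted populations, desk-scale marker counts."""
    config = sim.SimConfig(
        n_populations=3,
        n_autosomal=2_000,
        n_x=1_000,
        drift=(0.1, 0.1, 0.1),
        seed=11,
    )
    return sim.simulate_reference_panel(config, n_per_pop=30)


@pytest.fixture(scope="session")
def ref2_20k() -> sim.SimulatedReference:
    """Two populations at 20k autosomal markers (kinship-grade)."""
    config = sim.SimConfig(
        n_populations=2,
        n_autosomal=20_000,
        n_x=50,
        drift=(0.05, 0.05),
        seed=5,
    )
    return sim.simulate_reference_panel(config, n_per_pop=25)


@pytest.fixture(scope="session")
def ref5_20k() -> sim.SimulatedReference:
    """Five continental-style populations at 20k autosomal markers."""
    config = sim.SimConfig(
        n_populations=5,
        n_autosomal=20_000,
        n_x=200,
        drift=tuple(np.linspace(0.05, 0.15, 5)),
        seed=7,
    )
    return sim.simulate_reference_panel(config, n_per_pop=30)
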