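"""Shared fixtures: geometry, material cards and converged spine states.

Expensive equilibrium solves are session-scoped and shared across test
modules so the suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from lumbokin.geometry import build_default_spine
from lumbokin.materials import elastic_comparison_card, load_card
from lumbokin.solver import LoadCase, solve_equilibrium


@pytest.fixture(scope="session")
def geometry():
    return build_default_spine()


@pytest.fixture(scope="session")
def healthy_card():
    return load_card("healthy")


@pytest.fixture(scope="session")
def degenerated_card():
    return load_card("degenerated")


@pytest.fixture(scope="session")
def comparison_card():
    return elastic_comparison_card()


@pytest.fixture(scope="session")
def healthy_cards(geometry, healthy_card):
    return {level: healthy_card for level in geometry.joints}


@pytest.fixture(scope="session")
def preload_state(geometry, healthy_card):
    return solve_equilibrium(LoadCase(preload=400.0), geometry, healthy_card)


@pytest.fixture(scope="session")
def moment_states(geometry, healthy_card):
    """Converged pure-moment states (with preload) for all four movements."""
    return {
        movement: solve_equilibrium(LoadCase(movement=movement), geometry, healthy_card)
        for movement in ("FLX", "EXT", "LB", "AR")
    }


@pytest.fixture(scope="session")
def toy_geometry():
    """Single-segment column (L5 over the sacrum) for optimization oracles."""
    return build_default_spine({"levels": ["L5"]})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
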