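"""Shared fixtures: tiny deterministic worlds built in memory."""

import numpy as np
import pytest

from marrowsim.grid import CellKind, GridSpec, WorldState, init_world


@pytest.fixture
def small_spec() -> GridSpec:
    return GridSpec(nx=30, ny=30)


@pytest.fixture
def small_world(small_spec) -> WorldState:
    """30x30 world with procedurally generated trabecular bone."""
    return init_world(small_spec, target_bone_fraction=0.129, seed=7)


@pytest.fixture
def block_world() -> WorldState:
    """20x20 world with a hand-placed 5x5 solid bone block (25/400 = 6.25%),
    built from a mask so geometry is exact."""
    spec = GridSpec(nx=20, ny=20)
    mask = np.zeros(spec.shape)
    mask[8:13, 8:13] = 1.0
    return init_world(spec, target_bone_fraction=25 / 400, seed=0, mask=mask)


@pytest.fixture
def empty_world() -> WorldState:
    """Marrow-only world (one distant bone site to satisfy init), cleared of
    lining agents -- a clean canvas for agent-level tests."""
    spec = GridSpec(nx=24, ny=24)
    mask = np.zeros(spec.shape)
    mask[0:2, 0:2] = 1.0
    w = init_world(spec, target_bone_fraction=4 / 576, seed=0, mask=mask)
    for s in map(tuple, np.argwhere(w.kind != CellKind.EMPTY)):
        w.remove_agent(s)
    return w
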