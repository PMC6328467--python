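"""Shared fixtures: small synthetic systems generated at test time."""

import numpy as np
import pytest

from gsecdyn import SyntheticSpec, build_bundle, generate
from gsecdyn.synthetic_data import TransitionSpec


@pytest.fixture(scope="session")
def bundle():
    """A protein-only bundle (system + reference coordinates)."""
    spec = SyntheticSpec(solvent=None, lipids=None)
    system, ref = build_bundle(spec)
    return system, ref


@pytest.fixture(scope="session")
def small_study():
    """A short full run (protein + solvent + lipids) with a mid-point
    transition: 400 frames keep every per-state statistic estimable."""
    spec = SyntheticSpec(n_frames=400, transition=TransitionSpec(frame=200))
    system, traj, truth = generate(spec, seed=11)
    return spec, system, traj, truth


@pytest.fixture(scope="session")
def protein_run():
    """Protein-only trajectory without transition/tilt: pure jitter."""
    spec = SyntheticSpec(n_frames=300, transition=None, tilt_wobble=None,
                         solvent=None, lipids=None)
    system, traj, truth = generate(spec, seed=12)
    return spec, system, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
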