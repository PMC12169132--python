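import copy

import numpy as np
import pytest

from hemodyn.synthetic import (ContactSpec, GateSpec, LoopSpec, RotationSpec,
                               SyntheticSpec, build_toy_topology)


@pytest.fixture(scope="session")
def default_spec():
    """Small-but-complete two-state spec for fast structural tests."""
    return SyntheticSpec(n_frames=40, n_replicates=2, seed=11)


@pytest.fixture(scope="session")
def toy(default_spec):
    return build_toy_topology(default_spec)


@pytest.fixture(scope="session")
def mini_spec():
    """Tiny chain (60 residues) for statistics-heavy generator tests."""
    return SyntheticSpec(
        n_residues=60, domain_split=40, tail_start=61,
        loop_ranges=[LoopSpec(10, 15, {"oxy": 0.2, "deoxy": 0.9})],
        baseline_amplitude=0.3,
        gate=GateSpec(residue=30, open_prob={"oxy": 0.1, "deoxy": 0.9}),
        planted_contacts=[ContactSpec(5, 50, "VDW", {"oxy": 0.7, "deoxy": 0.7})],
        rotation=RotationSpec(mean_deg={"oxy": 0.0, "deoxy": 0.0}, jitter_deg=0.0),
        n_frames=40, n_replicates=2, seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def clone_spec(spec, **overrides):
    """Deep-copied spec with field overrides (fixtures stay pristine)."""
    out = copy.deepcopy(spec)
    for key, value in overrides.items():
        setattr(out, key, value)
    return out

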