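"""Shared fixtures: small synthetic systems built in memory."""

import numpy as np
import pytest

from gpianchor.system import Frame, Topology, Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def tiny_gpi_topology():
    """A minimal glycolipid-like topology: one atom per name/residue."""
    records = [
        ("C1", "PGL", 1), ("P", "PGL", 1),
        ("C6", "Ino", 2), ("O6", "Ino", 2),
        ("C1", "GlcN", 3),
        ("C4", "Man3", 6),
        ("OW", "SOL", 7), ("HW1", "SOL", 7),
        ("P", "DMPC", 8), ("C1", "DMPC", 8),
    ]
    return Topology.from_records(records)


@pytest.fixture
def box():
    return np.array([5.0, 5.0, 5.0])


def make_trajectory(coords_per_frame, box, records):
    top = Topology.from_records(records)
    frames = [Frame(np.asarray(c, dtype=float), box, time=float(t))
              for t, c in enumerate(coords_per_frame)]
    return Trajectory(top, frames)


@pytest.fixture
def make_traj():
    return make_trajectory
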