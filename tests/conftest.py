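"""Shared fixtures: all inputs are generated programmatically."""

import numpy as np
import pytest

import porekinetics as pk
from porekinetics.model import AtomRecord, MolecularModel


@pytest.fixture
def axis_frame():
    """Pore frame aligned with the lab z axis, origin at 0."""
    return pk.PoreFrame(origin=np.zeros(3), axis=np.array([0.0, 0.0, 1.0]))


@pytest.fixture
def cone_pore():
    """Ten-ring conical pore with its analytic radius profile."""
    z = np.arange(0.0, 20.0, 2.0)
    radii = np.linspace(6.0, 2.5, len(z))
    spec = pk.RingPoreSpec(z_planes=z, ring_radius_at_z=radii,
                           atoms_per_ring=24, atom_radius=1.5)
    return pk.generate_ring_pore(spec)


@pytest.fixture
def straight_helix():
    return pk.generate_kinked_helix(30)


@pytest.fixture
def five_atom_model():
    """Minimal hand-built model with distinctive author resids."""
    atoms = [
        AtomRecord(1, "N", "N", "GLY", 394, "A", np.array([0.0, 0.0, 0.0])),
        AtomRecord(2, "CA", "C", "GLY", 394, "A", np.array([1.4, 0.2, 0.1])),
        AtomRecord(3, "C", "C", "GLY", 394, "A", np.array([2.1, 1.1, -0.2])),
        AtomRecord(4, "O", "O", "GLY", 394, "A", np.array([2.0, 2.3, -0.1])),
        AtomRecord(5, "CA", "C", "ALA", 398, "B", np.array([5.0, 4.0, 3.0])),
    ]
    return MolecularModel(atoms, title="five-atom fixture")


def make_trace(z, t=None, r=None, ion_id="ion1"):
    z = np.asarray(z, dtype=float)
    if t is None:
        t = np.arange(len(z), dtype=float)
    if r is None:
        r = np.zeros_like(z)
    return pk.IonTrace(ion_id=ion_id, t=np.asarray(t, float), z=z,
                       r_offset=np.asarray(r, float))
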