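"""Shared fixtures: tiny hand-built trajectories with known geometry."""

import numpy as np
import pytest

from cglipidsite.core import ParticleTopology, Role, Trajectory


def make_topology(n_protein, n_ligands, prot_resids=None, head_name="AM1"):
    """n_protein protein beads (one residue each) + n_ligands single-bead ligands."""
    if prot_resids is None:
        prot_resids = list(range(1, n_protein + 1))
    names = np.array(["BB"] * n_protein + [head_name] * n_ligands)
    resids = np.array(list(prot_resids) + [200 + i for i in range(n_ligands)])
    resnames = np.array(["ALA"] * n_protein + ["CER"] * n_ligands)
    mols = np.array([0] * n_protein + [1 + i for i in range(n_ligands)])
    roles = np.array(
        [Role.PROTEIN] * n_protein + [Role.LIGAND] * n_ligands, dtype=object
    )
    return ParticleTopology(
        particle_names=names,
        residue_ids=resids,
        residue_names=resnames,
        molecule_ids=mols,
        roles=roles,
    )


def make_trajectory(coords, box=(100.0, 100.0, 100.0), frame_interval=600.0, topology=None):
    coords = np.asarray(coords, dtype=float)
    n_frames = coords.shape[0]
    return Trajectory(
        coordinates=coords,
        box=np.tile(np.asarray(box, dtype=float), (n_frames, 1)),
        frame_interval=frame_interval,
        topology=topology,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def topo_builder():
    return make_topology


@pytest.fixture
def traj_builder():
    return make_trajectory


def random_small_trajectory(rng, max_particles=20, max_frames=50, box=30.0):
    """Random fixture for oracle-equivalence tests: half protein, half ligand."""
    n_prot = int(rng.integers(2, max_particles // 2 + 1))
    n_lig = int(rng.integers(1, max_particles // 2 + 1))
    n_frames = int(rng.integers(1, max_frames + 1))
    topo = make_topology(n_prot, n_lig)
    coords = rng.uniform(0.0, box, size=(n_frames, n_prot + n_lig, 3))
    return make_trajectory(coords, box=(box, box, box), topology=topo)
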