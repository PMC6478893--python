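"""In-plane alignment, occupancy gridding and OpenDX export."""

import numpy as np
import pytest

from cglipidsite.core import AnalysisConfig
from cglipidsite.volume import (
    OccupancyGrid,
    align_protein_xy,
    export_grid,
    iso_threshold,
    occupancy_volume,
    read_grid,
)

from conftest import make_topology, make_trajectory


def brute_force_grid_total(traj, spacing, head_names=("AM1",)):
    """Time-average distinct-occupied-cell count by per-frame enumeration."""
    heads = np.where(traj.topology.head_mask(head_names))[0]
    total = 0
    for f in range(traj.n_frames):
        cells = set()
        for j in heads:
            pos = traj.coordinates[f, j] % traj.box[f]
            cells.add(tuple(int(x // spacing) for x in pos))
        total += len(cells)
    return total / traj.n_frames


def spinning_trajectory(rng, n_frames=12, degrees_per_frame=30.0):
    """Protein rotated about z (plus lipids) by a known angle per frame."""
    topo = make_topology(6, 2)
    base = rng.uniform(30, 70, size=(8, 3))
    frames = []
    for f in range(n_frames):
        th = np.deg2rad(degrees_per_frame * f)
        c, s = np.cos(th), np.sin(th)
        rot = np.array([[c, -s], [s, c]])
        fr = base.copy()
        fr[:, :2] = (base[:, :2] - 50.0) @ rot.T + 50.0
        frames.append(fr)
    return make_trajectory(frames, topology=topo)


class TestAlignProteinXY:
    def test_inverts_known_rotation(self, rng):
        traj = spinning_trajectory(rng)
        aligned = align_protein_xy(traj, ref_frame=0)
        prot = traj.topology.protein_mask()
        for f in range(traj.n_frames):
            assert np.allclose(
                aligned.coordinates[f][prot], traj.coordinates[0][prot], atol=1e-6
            )

    def test_idempotent(self, rng):
        traj = spinning_trajectory(rng)
        once = align_protein_xy(traj)
        twice = align_protein_xy(once)
        assert np.abs(once.coordinates - twice.coordinates).max() < 1e-6

    def test_z_drift_left_untouched(self, rng):
        topo = make_topology(4, 1)
        base = rng.uniform(20, 40, size=(5, 3))
        frames = [base + np.array([0.0, 0.0, 2.0 * f]) for f in range(5)]
        traj = make_trajectory(frames, topology=topo)
        aligned = align_protein_xy(traj)
        for f in range(5):
            # z coordinates unchanged (drift retained), xy unchanged
            assert np.allclose(aligned.coordinates[f], traj.coordinates[f], atol=1e-9)

    def test_too_few_protein_particles(self, rng):
        topo = make_topology(2, 1)
        traj = make_trajectory(rng.uniform(0, 50, (3, 3, 3)), topology=topo)
        with pytest.raises(ValueError, match="at least 3"):
            align_protein_xy(traj)


class TestOccupancyVolume:
    def test_stationary_particle_single_cell(self):
        topo = make_topology(2, 1)
        frame = np.array([[1.0, 1, 1], [2.0, 1, 1], [12.5, 22.5, 32.5]])
        traj = make_trajectory([frame] * 20, box=(50, 50, 50), topology=topo)
        grid = occupancy_volume(traj, "ceramide", AnalysisConfig(), head_names=("AM1",))
        assert grid.occupancy[2, 4, 6] == 1.0
        assert grid.total == pytest.approx(1.0)

    def test_split_between_two_cells(self):
        topo = make_topology(2, 1)
        frames = []
        for f in range(100):
            x = 2.0 if f < 50 else 12.0
            frames.append([[1.0, 1, 1], [2.0, 1, 1], [x, 2.0, 2.0]])
        traj = make_trajectory(frames, box=(50, 50, 50), topology=topo)
        grid = occupancy_volume(traj, "ceramide", AnalysisConfig(), head_names=("AM1",))
        assert grid.occupancy[0, 0, 0] == pytest.approx(0.5)
        assert grid.occupancy[2, 0, 0] == pytest.approx(0.5)

    def test_total_equals_brute_force(self, rng):
        topo = make_topology(3, 3)
        coords = rng.uniform(0, 50, size=(30, 6, 3))
        traj = make_trajectory(coords, box=(50, 50, 50), topology=topo)
        grid = occupancy_volume(traj, "ceramide", AnalysisConfig(), head_names=("AM1",))
        assert grid.total == pytest.approx(
            brute_force_grid_total(traj, 5.0), abs=1e-12
        )
        assert np.all(grid.occupancy >= 0) and np.all(grid.occupancy <= 1)

    def test_three_stationary_heads_sum_three(self):
        topo = make_topology(2, 3)
        frame = np.array(
            [[1.0, 1, 1], [2.0, 1, 1], [2.5, 2.5, 2.5], [22.5, 2.5, 2.5], [42.5, 2.5, 2.5]]
        )
        traj = make_trajectory([frame] * 10, box=(50, 50, 50), topology=topo)
        grid = occupancy_volume(traj, "ceramide", AnalysisConfig(), head_names=("AM1",))
        assert grid.total == pytest.approx(3.0)


class TestIsoThreshold:
    def test_published_defaults(self):
        cfg = AnalysisConfig()
        assert iso_threshold("ceramide", cfg) == pytest.approx(0.10)
        assert iso_threshold("cholesterol", cfg) == pytest.approx(0.20)

    def test_compensation_ratio_one_is_identity(self):
        cfg = AnalysisConfig()
        assert iso_threshold(
            "ceramide", cfg, n_species_molecules=16, n_reference_molecules=16,
            compensate=True,
        ) == pytest.approx(0.10)

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            iso_threshold("ceramide", AnalysisConfig(), 0, 16, compensate=True)


class TestGridExport:
    def test_round_trip(self, tmp_path, rng):
        occ = rng.random((4, 3, 5))
        grid = OccupancyGrid(
            origin=np.array([0.0, 0.0, 0.0]),
            spacing=5.0,
            shape=(4, 3, 5),
            occupancy=occ,
            species="ceramide",
            n_frames=10,
        )
        path = tmp_path / "g.dx"
        export_grid(grid, path)
        back = read_grid(path)
        assert back.shape == grid.shape
        assert back.spacing == pytest.approx(5.0)
        assert np.abs(back.occupancy - occ).max() < 1e-6

    def test_readable_by_griddata(self, tmp_path, rng):
        # independent reader: the gridData package used by VMD-adjacent tools
        gridData = pytest.importorskip("gridData")
        occ = rng.random((2, 2, 2))
        grid = OccupancyGrid(
            origin=np.array([1.0, 2.0, 3.0]),
            spacing=5.0,
            shape=(2, 2, 2),
            occupancy=occ,
            species="ceramide",
            n_frames=4,
        )
        path = tmp_path / "g.dx"
        export_grid(grid, path)
        g = gridData.Grid(str(path))
        assert np.abs(g.grid - occ).max() < 1e-6
        assert np.allclose(g.origin, [1.0, 2.0, 3.0])

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            OccupancyGrid(
                origin=np.zeros(3),
                spacing=5.0,
                shape=(0, 0, 0),
                occupancy=np.zeros((0, 0, 0)),
                species="x",
                n_frames=1,
            )
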