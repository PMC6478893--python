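"""Space-occupation analysis: in-plane alignment, occupancy gridding, export.

The simulation box is gridded at 5 Å spacing; a cell's occupancy is the
fraction of frames in which at least one head-group bead of the species
lies inside it (multiple beads in one cell count once, keeping values in
[0, 1]).  Because the membrane normal must be preserved, the protein is
aligned beforehand by a z-axis rotation plus xy-translation only — never a
full 3-D superposition.  Grids are exported as OpenDX scalar fields
loadable by VMD or ChimeraX.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnalysisConfig, Trajectory

__all__ = [
    "OccupancyGrid",
    "align_protein_xy",
    "occupancy_volume",
    "iso_threshold",
    "export_grid",
    "read_grid",
]


@dataclass
class OccupancyGrid:
    """Regular 3-D lattice of per-cell occupancy fractions."""

    origin: np.ndarray  # (3,) Å
    spacing: float  # Å
    shape: tuple[int, int, int]
    occupancy: np.ndarray  # shape, float in [0, 1]
    species: str
    n_frames: int

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.occupancy.shape != tuple(self.shape):
            raise ValueError("occupancy array does not match declared shape")
        if self.occupancy.size == 0:
            raise ValueError("grid must contain at least one cell")
        if np.any(self.occupancy < 0) or np.any(self.occupancy > 1):
            raise ValueError("cell occupancies must lie in [0, 1]")

    @property
    def total(self) -> float:
        """Σ over cells — the time-average number of occupied cells per frame."""
        return float(self.occupancy.sum())


def _in_plane_rotation(mobile_xy: np.ndarray, ref_xy: np.ndarray) -> tuple[float, np.ndarray]:
    """Optimal z-rotation angle and xy-translation mapping mobile onto ref.

    Closed-form 2-D Kabsch: with centred coordinates, the optimal angle is
    atan2(Σ(x·y' − y·x'), Σ(x·x' + y·y')).
    """
    mc = mobile_xy.mean(axis=0)
    rc = ref_xy.mean(axis=0)
    m = mobile_xy - mc
    r = ref_xy - rc
    num = np.sum(m[:, 0] * r[:, 1] - m[:, 1] * r[:, 0])
    den = np.sum(m[:, 0] * r[:, 0] + m[:, 1] * r[:, 1])
    theta = np.arctan2(num, den)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    trans = rc - rot @ mc
    return theta, np.array([rot[0, 0], rot[0, 1], rot[1, 0], rot[1, 1], trans[0], trans[1]])


def align_protein_xy(traj: Trajectory, ref_frame: int = 0) -> Trajectory:
    """Align the protein's in-plane position and rotation across frames.

    Every frame receives the z-rotation + xy-translation minimising the
    protein-particle RMSD to the reference frame; all particles (protein
    and lipids) are co-transformed and z coordinates are untouched.
    Idempotent to numerical precision.
    """
    prot = traj.topology.protein_mask()
    if prot.sum() < 3:
        raise ValueError("alignment needs at least 3 protein particles")
    if not (0 <= ref_frame < traj.n_frames):
        raise ValueError(f"ref_frame {ref_frame} out of range")
    out = traj.copy()
    ref_xy = traj.coordinates[ref_frame][prot][:, :2]
    for f in range(traj.n_frames):
        mob_xy = out.coordinates[f][prot][:, :2]
        _, p = _in_plane_rotation(mob_xy, ref_xy)
        rot = np.array([[p[0], p[1]], [p[2], p[3]]])
        trans = p[4:6]
        xy = out.coordinates[f][:, :2]
        out.coordinates[f][:, :2] = xy @ rot.T + trans
    return out


def occupancy_volume(
    traj: Trajectory,
    species: str,
    config: AnalysisConfig,
    head_names=None,
) -> OccupancyGrid:
    """Grid the box and compute per-cell head-group occupancy fractions.

    The grid is anchored at the origin (the minimum box corner of the
    reference frame) and covers the maximal box extent across frames with
    half-open cells [lo, hi), so a bead belongs to exactly one cell.
    Coordinates are wrapped into the primary box image first.
    """
    from .contacts import _resolve_heads

    head_names, head_mask = _resolve_heads(traj, species, head_names)
    head_idx = np.where(head_mask)[0]
    spacing = config.grid_spacing
    extent = traj.box.max(axis=0)
    shape = tuple(int(np.ceil(e / spacing)) for e in extent)
    counts = np.zeros(shape, dtype=np.int64)
    for f in range(traj.n_frames):
        pos = traj.coordinates[f, head_idx] % traj.box[f]
        cells = np.floor(pos / spacing).astype(int)
        cells = np.minimum(cells, np.array(shape) - 1)
        uniq = np.unique(cells, axis=0)
        counts[uniq[:, 0], uniq[:, 1], uniq[:, 2]] += 1
    return OccupancyGrid(
        origin=np.zeros(3),
        spacing=spacing,
        shape=shape,
        occupancy=counts / traj.n_frames,
        species=species,
        n_frames=traj.n_frames,
    )


def iso_threshold(
    species: str,
    config: AnalysisConfig,
    n_species_molecules: int | None = None,
    n_reference_molecules: int | None = None,
    compensate: bool = False,
) -> float:
    """Iso-occupancy surface threshold for a species.

    Returns the configured per-species threshold (10% ceramide, 20%
    cholesterol).  The optional compensation mode scales the base threshold
    linearly by the molecule-count ratio — a documented heuristic for
    comparing species present in different copy numbers — clipped to (0, 1).
    """
    base = {
        "ceramide": config.iso_threshold_ceramide,
        "cholesterol": config.iso_threshold_cholesterol,
    }.get(species)
    if base is None:
        raise ValueError(f"no iso-occupancy threshold configured for {species!r}")
    if not compensate:
        return base
    if not n_species_molecules or not n_reference_molecules:
        raise ValueError("compensation mode needs positive molecule counts")
    if n_species_molecules < 0 or n_reference_molecules < 0:
        raise ValueError("molecule counts must be positive")
    scaled = base * n_species_molecules / n_reference_molecules
    return float(np.clip(scaled, np.nextafter(0, 1), np.nextafter(1, 0)))


# ---------------------------------------------------------------------------
# OpenDX scalar-field export
# ---------------------------------------------------------------------------

def export_grid(grid: OccupancyGrid, path) -> None:
    """Write the grid as an OpenDX regular scalar field (text)."""
    nx, ny, nz = grid.shape
    o = grid.origin
    d = grid.spacing
    lines = [
        f"# occupancy grid, species={grid.species}, n_frames={grid.n_frames}",
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
        f"delta {d:.6f} 0.000000 0.000000",
        f"delta 0.000000 {d:.6f} 0.000000",
        f"delta 0.000000 0.000000 {d:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.occupancy.ravel(order="C")  # x fastest-varying last: DX order
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_grid(path) -> OccupancyGrid:
    """Read back a grid written by :func:`export_grid`."""
    shape = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = 0
    reading = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if reading:
                if line.startswith("attribute") or line.startswith("object"):
                    reading = False
                    continue
                values.extend(float(t) for t in line.split())
                if len(values) >= n_items:
                    reading = False
                continue
            if line.startswith("object 1 class gridpositions"):
                shape = tuple(int(t) for t in line.split()[-3:])
            elif line.startswith("origin"):
                origin = np.array([float(t) for t in line.split()[1:4]])
            elif line.startswith("delta"):
                deltas.append([float(t) for t in line.split()[1:4]])
            elif "data follows" in line:
                n_items = int(line.split()[-3])
                reading = True
    if shape is None or origin is None or len(values) < n_items:
        raise ValueError(f"malformed DX file: {path}")
    spacing = float(deltas[0][0])
    occ = np.array(values[:n_items]).reshape(shape, order="C")
    return OccupancyGrid(
        origin=origin,
        spacing=spacing,
        shape=shape,
        occupancy=occ,
        species="unknown",
        n_frames=1,
    )
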