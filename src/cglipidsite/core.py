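"""Core domain types and geometry shared by every analysis stage.

Coordinates are stored internally in angstrom (Å): every distance cutoff in
the analysis (7 Å residue contacts, 8 Å site contacts, 5 Å grid spacing) is
defined on that scale.  Readers convert from nm-based trajectory formats.
Boxes are restricted to orthorhombic cells, which keeps the minimum-image
convention exact; triclinic input is rejected explicitly.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Role",
    "ParticleTopology",
    "Trajectory",
    "AnalysisConfig",
    "DEFAULT_ROLE_MAP",
    "load_trajectory",
    "min_image_displacement",
    "min_image_distance",
    "pairwise_min_image_distances",
    "kabsch_superpose",
    "barrel_rmsd",
    "pairing_from_alignment",
]

DEFAULT_FRAME_INTERVAL_PS = 600.0


class Role(enum.Enum):
    """Coarse classification of a particle for selection purposes."""

    PROTEIN = "protein"
    LIGAND = "ligand"
    OTHER = "other"


#: Martini-style defaults mapping particle / residue names to roles.  Bead
#: naming varies across force-field versions, so this table is user-editable:
#: pass an override mapping to :func:`load_trajectory`.
DEFAULT_ROLE_MAP: dict[str, Role] = {
    # protein backbone / side-chain beads
    "BB": Role.PROTEIN,
    "SC1": Role.PROTEIN,
    "SC2": Role.PROTEIN,
    "SC3": Role.PROTEIN,
    "SC4": Role.PROTEIN,
    # lipid head-group beads
    "AM1": Role.LIGAND,  # ceramide amide head
    "AM2": Role.LIGAND,
    "ROH": Role.LIGAND,  # cholesterol hydroxyl
    "PO4": Role.LIGAND,  # phosphocholine phosphate
    "NC3": Role.LIGAND,  # phosphocholine choline
}

#: Default head-group bead names per ligand species label.
DEFAULT_SPECIES_HEADS: dict[str, tuple[str, ...]] = {
    "ceramide": ("AM1", "AM2"),
    "cholesterol": ("ROH",),
    "phosphatidylcholine": ("PO4", "NC3"),
}

_AA3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "GLH", "ASH",
}


@dataclass(frozen=True)
class ParticleTopology:
    """Per-particle metadata for a coarse-grain system.

    Particle ids are implicit array indices (0-based, contiguous).
    """

    particle_names: np.ndarray  # (n,) str
    residue_ids: np.ndarray  # (n,) int
    residue_names: np.ndarray  # (n,) str
    molecule_ids: np.ndarray  # (n,) int
    roles: np.ndarray  # (n,) object (Role)

    def __post_init__(self) -> None:
        n = len(self.particle_names)
        for name in ("residue_ids", "residue_names", "molecule_ids", "roles"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"topology field {name!r} has wrong length")
        # residue ids within one molecule must be non-decreasing
        for mol in np.unique(self.molecule_ids):
            rid = self.residue_ids[self.molecule_ids == mol]
            if np.any(np.diff(rid) < 0):
                raise ValueError(f"residue ids decrease within molecule {mol}")

    @property
    def n_particles(self) -> int:
        return len(self.particle_names)

    def mask_role(self, role: Role) -> np.ndarray:
        return np.array([r is role for r in self.roles], dtype=bool)

    def protein_mask(self) -> np.ndarray:
        return self.mask_role(Role.PROTEIN)

    def head_mask(self, head_names: tuple[str, ...] | list[str]) -> np.ndarray:
        return np.isin(self.particle_names, list(head_names))

    def ligand_molecule_ids(self, head_names) -> np.ndarray:
        """Molecule ids owning at least one of the named head particles."""
        return np.unique(self.molecule_ids[self.head_mask(head_names)])


@dataclass
class Trajectory:
    """Frames × particles × 3 coordinates (Å) with per-frame orthorhombic box.

    Time of frame *i* is ``i * frame_interval`` (ps); frame indexing is
    0-based.  The default sampling interval is 600 ps.
    """

    coordinates: np.ndarray  # (n_frames, n_particles, 3), Å
    box: np.ndarray  # (n_frames, 3), Å
    frame_interval: float  # ps
    topology: ParticleTopology

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (frames, particles, 3)")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.box.shape != (self.coordinates.shape[0], 3):
            raise ValueError("box record count must equal frame count")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive in every frame")
        if self.coordinates.shape[1] != self.topology.n_particles:
            raise ValueError("coordinate particle count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[1]

    @property
    def total_time(self) -> float:
        """Total sampled time in ps (n_frames × frame_interval)."""
        return self.n_frames * self.frame_interval

    def copy(self) -> "Trajectory":
        return replace(
            self, coordinates=self.coordinates.copy(), box=self.box.copy()
        )


@dataclass
class AnalysisConfig:
    """Every numeric parameter of the contact / event / volume analyses.

    Defaults reproduce the published analysis settings: 7 Å residue-contact
    cutoff, 8 Å site cutoff with ≥2 of 3 residue groups (58–60, 73–75,
    81–83), a 5-frame/3-vote smoothing filter, a 15% occupancy threshold
    for binding-site calls, 5 Å grid spacing, iso-occupancy thresholds of
    10% (ceramide) and 20% (cholesterol), and 10 000-resample bootstrap
    confidence intervals at the 95% level.
    """

    contact_cutoff: float = 7.0  # Å
    event_cutoff: float = 8.0  # Å
    min_groups_in_contact: int = 2
    site_groups: tuple[tuple[int, int], ...] = ((58, 60), (73, 75), (81, 83))
    smoothing_window: int = 5
    smoothing_min_true: int = 3
    occupancy_threshold: float = 0.15
    grid_spacing: float = 5.0  # Å
    iso_threshold_ceramide: float = 0.10
    iso_threshold_cholesterol: float = 0.20
    bootstrap_resamples: int = 10_000
    ci_level: float = 0.95

    def validate(self) -> list[str]:
        """Return a list of all invariant violations (empty when valid)."""
        errs: list[str] = []
        for name in ("contact_cutoff", "event_cutoff", "grid_spacing"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be > 0")
        if self.smoothing_window % 2 == 0:
            errs.append("smoothing_window must be odd")
        if self.smoothing_window < 1:
            errs.append("smoothing_window must be >= 1")
        if not (1 <= self.smoothing_min_true <= self.smoothing_window):
            errs.append("smoothing_min_true must be in [1, smoothing_window]")
        for name in (
            "occupancy_threshold",
            "iso_threshold_ceramide",
            "iso_threshold_cholesterol",
            "ci_level",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                errs.append(f"{name} must be a fraction in (0, 1)")
        if self.min_groups_in_contact not in (1, 2, 3):
            errs.append("min_groups_in_contact must be 1, 2 or 3")
        if self.bootstrap_resamples < 1:
            errs.append("bootstrap_resamples must be >= 1")
        if len(self.site_groups) != 3:
            errs.append("site_groups must contain exactly three ranges")
        return errs

    def __post_init__(self) -> None:
        errs = self.validate()
        if errs:
            raise ValueError("; ".join(errs))


# ---------------------------------------------------------------------------
# Periodic-boundary geometry
# ---------------------------------------------------------------------------

def min_image_displacement(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement ``q - p`` in an orthorhombic box (Å)."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box components must be positive")
    d = np.asarray(q, dtype=float) - np.asarray(p, dtype=float)
    return d - box * np.round(d / box)


def min_image_distance(p, q, box) -> float:
    """Minimum-image Euclidean distance between two points (Å).

    Symmetric in ``p`` and ``q``; never exceeds half the box diagonal.
    """
    return float(np.linalg.norm(min_image_displacement(p, q, box)))


def pairwise_min_image_distances(a: np.ndarray, b: np.ndarray, box) -> np.ndarray:
    """(n, m) matrix of minimum-image distances between point sets a and b."""
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box components must be positive")
    d = a[:, None, :] - b[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


# ---------------------------------------------------------------------------
# Rigid-body superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, ref: np.ndarray):
    """Optimal rotation R and translation t mapping ``mobile`` onto ``ref``.

    Minimises RMSD over paired points: ``ref ≈ mobile @ R.T + t``.  Uses the
    SVD (Kabsch) solution with the proper-rotation determinant correction.
    """
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    if mobile.shape != ref.shape or mobile.ndim != 2:
        raise ValueError("paired coordinate sets must share shape (n, 3)")
    if len(mobile) < 3:
        raise ValueError("superposition needs at least 3 paired particles")
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    h = (mobile - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = rc - rot @ mc
    return rot, trans


def barrel_rmsd(
    struct_a: np.ndarray,
    struct_b: np.ndarray,
    pairing: np.ndarray | list[tuple[int, int]],
) -> float:
    """RMSD (Å) over paired particles after optimal rigid superposition.

    ``pairing`` is an explicit list of (index_in_a, index_in_b) pairs — the
    operation never guesses correspondences.  Invariant under any rigid
    transformation of either structure; zero iff the structures are
    congruent on the pairing.
    """
    pairing = np.asarray(pairing, dtype=int)
    if pairing.ndim != 2 or pairing.shape[1] != 2 or len(pairing) == 0:
        raise ValueError("pairing must be a non-empty list of index pairs")
    if len(pairing) < 3:
        raise ValueError("fewer than 3 pairs: superposition is degenerate")
    a = np.asarray(struct_a, float)[pairing[:, 0]]
    b = np.asarray(struct_b, float)[pairing[:, 1]]
    rot, trans = kabsch_superpose(b, a)
    moved = b @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((a - moved) ** 2, axis=1))))


def pairing_from_alignment(
    resids_a: np.ndarray,
    seq_a: str,
    resids_b: np.ndarray,
    seq_b: str,
) -> np.ndarray:
    """Build an index pairing from a global pairwise sequence alignment.

    ``resids_*`` give the residue order of the coordinate rows; ``seq_*``
    the matching one-letter sequences.  Returns (n, 2) row-index pairs for
    aligned, non-gap positions.  Requires Biopython.
    """
    from Bio import Align

    if len(resids_a) != len(seq_a) or len(resids_b) != len(seq_b):
        raise ValueError("sequence length must match residue count")
    aligner = Align.PairwiseAligner(scoring="blastp")
    aligner.mode = "global"
    aln = aligner.align(seq_a, seq_b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
    return np.asarray(pairs, dtype=int)


# ---------------------------------------------------------------------------
# Trajectory loading (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _infer_roles(names, resnames, role_map) -> np.ndarray:
    roles = np.empty(len(names), dtype=object)
    for i, (nm, rn) in enumerate(zip(names, resnames)):
        if nm in role_map:
            roles[i] = role_map[nm]
        elif rn in _AA3:
            roles[i] = Role.PROTEIN
        else:
            roles[i] = Role.OTHER
    return roles


def _check_orthorhombic(dims, frame: int) -> None:
    if dims is None or np.any(np.asarray(dims[:3]) <= 0):
        raise ValueError(f"frame {frame}: missing or non-positive box")
    if not np.allclose(dims[3:6], 90.0, atol=1e-3):
        raise ValueError(
            f"frame {frame}: triclinic box unsupported (angles {dims[3:6]})"
        )


def load_trajectory(
    coords_path,
    traj_path=None,
    frame_interval: float = DEFAULT_FRAME_INTERVAL_PS,
    role_map: dict[str, Role] | None = None,
) -> Trajectory:
    """Read a GRO/PDB topology and optional XTC/TRR/DCD trajectory.

    Returns a :class:`Trajectory` in Å with roles inferred from particle
    and residue names via ``role_map`` (Martini-style defaults).  Without
    ``traj_path`` the result is a single-frame trajectory.

    Raises ``ValueError`` on a particle-count mismatch between topology and
    trajectory and ``OSError`` (with the frame index where known) on
    unreadable or truncated input.
    """
    import MDAnalysis as mda

    role_map = DEFAULT_ROLE_MAP if role_map is None else role_map
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if traj_path is None:
                u = mda.Universe(str(coords_path))
            else:
                u = mda.Universe(str(coords_path), str(traj_path))
        except (ValueError, IOError) as exc:
            msg = str(exc)
            if "same number of atoms" in msg or "number of atoms" in msg:
                raise ValueError(
                    f"particle-count mismatch between {coords_path} and "
                    f"{traj_path}: {msg}"
                ) from exc
            raise

    atoms = u.atoms
    names = atoms.names.astype(str)
    resnames = atoms.resnames.astype(str)
    resids = atoms.resids.astype(int)
    # molecule id: contiguous runs of (segindex, resid-of-molecule); for CG
    # systems each residue of a lipid is the molecule, proteins are one
    # molecule per segment.  Use MDAnalysis fragments when bonds exist,
    # otherwise fall back to per-residue molecules for non-protein and
    # per-segment for protein particles.
    roles = _infer_roles(names, resnames, role_map)
    mol_ids = np.empty(len(names), dtype=int)
    next_mol = 0
    prev_key = None
    for i in range(len(names)):
        if roles[i] is Role.PROTEIN:
            key = ("prot", atoms.segindices[i])
        else:
            key = ("res", atoms.segindices[i], atoms.resindices[i])
        if key != prev_key:
            cur = next_mol
            next_mol += 1
            prev_key = key
        mol_ids[i] = cur

    topo = ParticleTopology(
        particle_names=names,
        residue_ids=resids,
        residue_names=resnames,
        molecule_ids=mol_ids,
        roles=roles,
    )

    frames = []
    boxes = []
    try:
        for k, ts in enumerate(u.trajectory):
            _check_orthorhombic(ts.dimensions, k)
            frames.append(ts.positions.copy().astype(float))
            boxes.append(np.asarray(ts.dimensions[:3], dtype=float))
    except (OSError, IOError) as exc:
        raise OSError(
            f"error reading trajectory at frame {len(frames)}: {exc}"
        ) from exc

    return Trajectory(
        coordinates=np.stack(frames),
        box=np.stack(boxes),
        frame_interval=float(frame_interval),
        topology=topo,
    )
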