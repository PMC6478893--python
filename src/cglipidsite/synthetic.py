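"""Synthetic coarse-grain trajectories with known binding kinetics.

Real production trajectories of the membrane system are multi-gigabyte and
not redistributable, so every pipeline stage is exercised on synthetic data
with exact ground truth.  The generator emulates the analysed system's
observables, not its physics: a static β-barrel-like protein (19
pseudo-strand columns of backbone beads on a cylinder) sits in a bilayer
plane inside an orthorhombic box, and ligand head beads (named AM1, 16 by
default) diffuse in the membrane plane.  A single binding site alternates
between bound and unbound states following a two-state (telegraph) Markov
chain with known on/off rates; during bound intervals the scheduled ligand
is placed within the event cutoff of at least two site residue groups,
while unbound ligands are kept well clear of the site.  Binding is thus
*scheduled* rather than emergent, which is what makes exact ground-truth
oracle tests possible.

Frames are sampled every 600 ps by default, matching the analysis cadence
of the production simulations.  Discrete-time geometric state durations
approximate the exponential law; validity requires k_off·Δt < 0.5 and the
approximation bias (time-weighted mean (2−p)/k_off instead of 2/k_off)
vanishes at fine sampling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .core import ParticleTopology, Role, Trajectory
from .kinetics import SiteDefinition

__all__ = [
    "KineticsSpec",
    "BarrelGeometry",
    "GroundTruthEvent",
    "GroundTruth",
    "generate_telegraph_series",
    "ground_truth_summary",
    "build_synthetic_trajectory",
    "generate_synthetic_trajectory",
    "validate_ground_truth_geometry",
]

PS_PER_US = 1.0e6


@dataclass(frozen=True)
class KineticsSpec:
    """Ground-truth two-state kinetics for the synthetic binding site."""

    k_on: float  # μs⁻¹, site-level binding rate
    k_off: float  # μs⁻¹, unbinding rate
    n_frames: int
    frame_interval: float = 600.0  # ps
    n_ligands: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rates must be positive")
        if self.n_frames < 10:
            raise ValueError("n_frames must be at least 10")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_ligands < 1:
            raise ValueError("need at least one ligand")
        if self.k_off * self.dt_us >= 0.5 or self.k_on * self.dt_us >= 0.5:
            raise ValueError(
                "k·Δt must stay below 0.5 for the discrete-time approximation"
            )

    @property
    def dt_us(self) -> float:
        return self.frame_interval / PS_PER_US

    @property
    def p_bind(self) -> float:
        """Per-frame unbound → bound transition probability."""
        return self.k_on * self.dt_us

    @property
    def p_unbind(self) -> float:
        return self.k_off * self.dt_us

    @property
    def stationary_bound_fraction(self) -> float:
        return self.k_on / (self.k_on + self.k_off)


@dataclass(frozen=True)
class BarrelGeometry:
    """Pseudo-barrel and box parameters for the synthetic system (Å)."""

    radius: float = 12.0
    n_columns: int = 19
    particles_per_column: int = 3
    z_spacing: float = 4.0
    box: tuple[float, float, float] = (100.0, 100.0, 60.0)
    site_offset: float = 4.5  # radial offset of the bound-ligand anchor
    step_sigma: float = 1.5  # per-frame random-walk step s.d.
    exclusion_radius: float = 26.0  # unbound ligands stay outside this radius
    jitter: float = 0.3  # s.d. of bound-position jitter, clipped at 0.8 Å

    def __post_init__(self) -> None:
        if self.exclusion_radius <= self.radius + self.site_offset + 8.0:
            raise ValueError(
                "exclusion radius too small to keep unbound ligands clear of the site"
            )
        if min(self.box[0], self.box[1]) / 2.0 <= self.exclusion_radius + 2.0:
            raise ValueError("box too small for the ligand exclusion zone")


@dataclass(frozen=True)
class GroundTruthEvent:
    ligand_id: int
    start_frame: int
    n_frames: int
    end_censored: bool


@dataclass
class GroundTruth:
    """Scheduled events plus the analytic values they should recover."""

    events: list[GroundTruthEvent]
    stationary_bound_fraction: float
    analytic_time_weighted_mean: float  # ps
    spec: KineticsSpec
    site_series: np.ndarray | None = None

    @property
    def retained_events(self) -> list[GroundTruthEvent]:
        return [e for e in self.events if not e.end_censored]

    @property
    def retained_durations(self) -> np.ndarray:
        """Durations (ps) of events not still bound at the end of the run."""
        return np.array(
            [e.n_frames * self.spec.frame_interval for e in self.retained_events]
        )


# ---------------------------------------------------------------------------
# Telegraph series
# ---------------------------------------------------------------------------

def generate_telegraph_series(
    spec: KineticsSpec,
    rng: np.random.Generator | None = None,
    start_state: int | None = None,
    min_run_frames: int = 1,
):
    """Simulate one two-state site series with per-frame transition rules.

    State durations are drawn run-by-run from the geometric law implied by
    the per-frame probabilities p_bind = k_on·Δt and p_unbind = k_off·Δt —
    exactly equivalent to stepping the Markov chain frame by frame.  The
    start state is drawn from the stationary distribution unless given.
    ``min_run_frames > 1`` conditions every run to last at least that many
    frames (used to build smoothing-neutral fixtures whose event lists are
    invariant under the majority filter); the default leaves the chain
    untouched.

    Returns ``(series, events)``: a 0/1 array of length n_frames and the
    list of maximal bound runs as (start_frame, n_frames, end_censored).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if min_run_frames < 1:
        raise ValueError("min_run_frames must be >= 1")
    n = spec.n_frames
    if start_state is None:
        state = int(rng.random() < spec.stationary_bound_fraction)
    else:
        state = int(start_state)
    series = np.zeros(n, dtype=np.uint8)
    events: list[tuple[int, int, bool]] = []
    t = 0
    while t < n:
        p_leave = spec.p_unbind if state == 1 else spec.p_bind
        run = (min_run_frames - 1) + int(rng.geometric(p_leave))
        end = min(t + run, n)
        if state == 1:
            series[t:end] = 1
            events.append((t, end - t, end == n))
        t = end
        state = 1 - state
    return series, events


def ground_truth_summary(spec: KineticsSpec) -> GroundTruth:
    """Analytic stationary bound fraction and time-weighted mean (ps).

    For exponential residence times with rate k_off, the time-weighted
    mean E[T²]/E[T] equals 2/k_off.
    """
    return GroundTruth(
        events=[],
        stationary_bound_fraction=spec.stationary_bound_fraction,
        analytic_time_weighted_mean=2.0 / spec.k_off * PS_PER_US,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Trajectory synthesis
# ---------------------------------------------------------------------------

#: Residue ids of the three binding-site groups, placed on three spatially
#: adjacent pseudo-strands (sequence-distant strands being neighbours in
#: space is exactly the β-barrel situation the site definition describes).
SITE_GROUP_RESIDS = (
    (58, 59, 60),
    (73, 74, 75),
    (81, 82, 83),
)


def default_site_definition(event_cutoff: float = 8.0, min_groups: int = 2) -> SiteDefinition:
    return SiteDefinition(
        groups=tuple(tuple(g) for g in SITE_GROUP_RESIDS),
        event_cutoff=event_cutoff,
        min_groups=min_groups,
    )


def _protein_layout(geom: BarrelGeometry):
    """Residue id, column and level for every protein bead, plus positions.

    Columns 0–2 carry the site groups 58–60, 73–75 and 81–83 (one residue
    per level); the remaining columns carry residues 1–48.
    """
    resids = []
    columns = []
    levels = []
    for col in range(geom.n_columns):
        for lev in range(geom.particles_per_column):
            if col < 3:
                rid = SITE_GROUP_RESIDS[col][lev]
            else:
                rid = 3 * (col - 3) + lev + 1
            resids.append(rid)
            columns.append(col)
            levels.append(lev)
    order = np.argsort(resids, kind="stable")
    return (
        np.asarray(resids)[order],
        np.asarray(columns)[order],
        np.asarray(levels)[order],
    )


def _protein_positions(geom: BarrelGeometry, columns, levels) -> np.ndarray:
    cx, cy, _ = (b / 2.0 for b in geom.box)
    z_mid = geom.box[2] / 2.0
    theta = 2.0 * np.pi * columns / geom.n_columns
    x = cx + geom.radius * np.cos(theta)
    y = cy + geom.radius * np.sin(theta)
    z = z_mid + (levels - (geom.particles_per_column - 1) / 2.0) * geom.z_spacing
    return np.column_stack([x, y, z])


def _site_anchor(geom: BarrelGeometry) -> np.ndarray:
    """Bound-ligand anchor: radially outside the middle site column (73–75)."""
    cx, cy, _ = (b / 2.0 for b in geom.box)
    theta = 2.0 * np.pi * 1 / geom.n_columns
    r = geom.radius + geom.site_offset
    return np.array([cx + r * np.cos(theta), cy + r * np.sin(theta), geom.box[2] / 2.0])


def _min_image_xy_r(pos_xy, center_xy, box_xy) -> np.ndarray:
    d = pos_xy - center_xy
    d -= box_xy * np.round(d / box_xy)
    return np.sqrt((d**2).sum(axis=-1))


def build_synthetic_trajectory(
    spec: KineticsSpec,
    geom: BarrelGeometry | None = None,
    min_run_frames: int = 1,
) -> tuple[Trajectory, GroundTruth]:
    """Build the synthetic system in memory.

    The site-level telegraph series schedules binding; each bound run is
    assigned to a ligand chosen at random (at most one ligand bound per
    frame, keeping ground truth unambiguous).  Unbound ligands perform 2-D
    periodic random walks outside an exclusion disc around the barrel, so
    they can never register a site contact; the scheduled ligand sits at
    the site anchor with sub-Å jitter on every bound frame.
    """
    geom = geom or BarrelGeometry()
    rng = np.random.default_rng(spec.seed)
    series, raw_events = generate_telegraph_series(
        spec, rng=rng, min_run_frames=min_run_frames
    )

    resids, columns, levels = _protein_layout(geom)
    prot_pos = _protein_positions(geom, columns, levels)
    n_prot = len(resids)
    n_lig = spec.n_ligands
    anchor = _site_anchor(geom)
    box = np.asarray(geom.box)
    box_xy = box[:2]
    center_xy = box_xy / 2.0
    z_lig = box[2] / 2.0

    # assign each bound run to a ligand
    events = []
    owner = np.full(spec.n_frames, -1, dtype=int)
    for start, nfr, censored in raw_events:
        lig = int(rng.integers(0, n_lig))
        events.append(GroundTruthEvent(lig, start, nfr, censored))
        owner[start : start + nfr] = lig

    # initial unbound positions on the allowed annulus
    lig_xy = np.empty((n_lig, 2))
    placed = 0
    while placed < n_lig:
        cand = rng.uniform(0.0, box_xy, size=2)
        if _min_image_xy_r(cand, center_xy, box_xy) > geom.exclusion_radius + 2.0:
            lig_xy[placed] = cand
            placed += 1

    coords = np.empty((spec.n_frames, n_prot + n_lig, 3))
    coords[:, :n_prot, :] = prot_pos[None, :, :]
    steps = rng.normal(0.0, geom.step_sigma, size=(spec.n_frames, n_lig, 2))
    jitters = np.clip(
        rng.normal(0.0, geom.jitter, size=(spec.n_frames, 3)), -0.8, 0.8
    )
    prev_owner = -1
    for f in range(spec.n_frames):
        # advance free ligands, rejecting steps into the exclusion disc
        prop = (lig_xy + steps[f]) % box_xy
        ok = _min_image_xy_r(prop, center_xy, box_xy) > geom.exclusion_radius
        lig_xy[ok] = prop[ok]
        if owner[f] != prev_owner and prev_owner >= 0:
            # previous event's ligand re-enters the membrane pool
            while True:
                cand = rng.uniform(0.0, box_xy, size=2)
                if _min_image_xy_r(cand, center_xy, box_xy) > geom.exclusion_radius + 2.0:
                    lig_xy[prev_owner] = cand
                    break
        frame_xy = lig_xy.copy()
        frame_z = np.full(n_lig, z_lig)
        if owner[f] >= 0:
            bound = anchor + jitters[f]
            frame_xy[owner[f]] = bound[:2]
            frame_z[owner[f]] = bound[2]
        coords[f, n_prot:, 0] = frame_xy[:, 0]
        coords[f, n_prot:, 1] = frame_xy[:, 1]
        coords[f, n_prot:, 2] = frame_z
        prev_owner = owner[f]

    names = np.array(["BB"] * n_prot + ["AM1"] * n_lig)
    residue_ids = np.concatenate([resids, 200 + np.arange(n_lig)])
    residue_names = np.array(["ALA"] * n_prot + ["CER"] * n_lig)
    molecule_ids = np.concatenate(
        [np.zeros(n_prot, dtype=int), 1 + np.arange(n_lig)]
    )
    roles = np.array([Role.PROTEIN] * n_prot + [Role.LIGAND] * n_lig, dtype=object)
    topo = ParticleTopology(
        particle_names=names,
        residue_ids=residue_ids.astype(int),
        residue_names=residue_names,
        molecule_ids=molecule_ids,
        roles=roles,
    )
    traj = Trajectory(
        coordinates=coords,
        box=np.tile(box, (spec.n_frames, 1)),
        frame_interval=spec.frame_interval,
        topology=topo,
    )
    gt = GroundTruth(
        events=events,
        stationary_bound_fraction=spec.stationary_bound_fraction,
        analytic_time_weighted_mean=2.0 / spec.k_off * PS_PER_US,
        spec=spec,
        site_series=series,
    )
    return traj, gt


def generate_synthetic_trajectory(
    spec: KineticsSpec,
    outdir,
    geom: BarrelGeometry | None = None,
    min_run_frames: int = 1,
    basename: str = "synthetic",
):
    """Write GRO + XTC + ground-truth TSV + spec-echo YAML to ``outdir``.

    Returns ``(paths dict, GroundTruth)``.  Files are readable by
    :func:`cglipidsite.core.load_trajectory`.
    """
    import MDAnalysis as mda

    geom = geom or BarrelGeometry()
    traj, gt = build_synthetic_trajectory(spec, geom, min_run_frames)
    os.makedirs(outdir, exist_ok=True)
    topo = traj.topology

    # one MDAnalysis residue per topology residue, in particle order
    res_keys = []
    atom_resindex = []
    for mol, rid in zip(topo.molecule_ids, topo.residue_ids):
        key = (mol, rid)
        if not res_keys or res_keys[-1] != key:
            res_keys.append(key)
        atom_resindex.append(len(res_keys) - 1)
    resnames = []
    resids = []
    seen = -1
    for i, idx in enumerate(atom_resindex):
        if idx != seen:
            resnames.append(str(topo.residue_names[i]))
            resids.append(int(topo.residue_ids[i]))
            seen = idx
    u = mda.Universe.empty(
        n_atoms=topo.n_particles,
        n_residues=len(res_keys),
        atom_resindex=np.asarray(atom_resindex),
        residue_segindex=np.zeros(len(res_keys), dtype=int),
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in topo.particle_names])
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", resids)
    dims = np.array([*traj.box[0], 90.0, 90.0, 90.0])

    gro_path = os.path.join(outdir, f"{basename}.gro")
    xtc_path = os.path.join(outdir, f"{basename}.xtc")
    tsv_path = os.path.join(outdir, f"{basename}_ground_truth.tsv")
    yaml_path = os.path.join(outdir, f"{basename}_spec.yaml")

    u.atoms.positions = traj.coordinates[0]
    u.dimensions = dims
    u.atoms.write(gro_path)
    with mda.Writer(xtc_path, n_atoms=topo.n_particles) as w:
        for f in range(traj.n_frames):
            u.atoms.positions = traj.coordinates[f]
            u.trajectory.ts.dimensions = dims
            u.trajectory.ts.frame = f
            u.trajectory.ts.time = f * spec.frame_interval
            w.write(u.atoms)

    with open(tsv_path, "w") as fh:
        fh.write("ligand_id\tstart_frame\tn_frames\tend_censored\n")
        for e in gt.events:
            fh.write(
                f"{e.ligand_id}\t{e.start_frame}\t{e.n_frames}\t{int(e.end_censored)}\n"
            )
    with open(yaml_path, "w") as fh:
        yaml.safe_dump(
            {
                "k_on_per_us": spec.k_on,
                "k_off_per_us": spec.k_off,
                "n_frames": spec.n_frames,
                "frame_interval_ps": spec.frame_interval,
                "n_ligands": spec.n_ligands,
                "seed": spec.seed,
                "min_run_frames": min_run_frames,
                "stationary_bound_fraction": gt.stationary_bound_fraction,
                "analytic_time_weighted_mean_ps": gt.analytic_time_weighted_mean,
            },
            fh,
        )
    paths = {
        "gro": gro_path,
        "xtc": xtc_path,
        "ground_truth": tsv_path,
        "spec": yaml_path,
    }
    return paths, gt


# ---------------------------------------------------------------------------
# Independent geometric validator
# ---------------------------------------------------------------------------

def validate_ground_truth_geometry(
    traj: Trajectory,
    gt: GroundTruth,
    site: SiteDefinition | None = None,
    head_names=("AM1",),
    clearance: float = 4.0,
) -> None:
    """Check frame-by-frame that the emitted geometry encodes the schedule.

    On every bound frame the scheduled ligand head must lie within the
    event cutoff of ≥ min_groups site groups; on every frame each unbound
    ligand must stay beyond event_cutoff + clearance of all group
    particles.  Raises ``AssertionError`` on the first violation.
    """
    from .core import pairwise_min_image_distances

    site = site or default_site_definition()
    topo = traj.topology
    group_idx = [
        np.where(np.isin(topo.residue_ids, list(g)) & topo.protein_mask())[0]
        for g in site.groups
    ]
    lig_head = {
        int(m): np.where(
            (topo.molecule_ids == m) & topo.head_mask(head_names)
        )[0]
        for m in topo.ligand_molecule_ids(head_names)
    }
    owner = np.full(traj.n_frames, -1, dtype=int)
    lig_ids = sorted(lig_head)
    for e in gt.events:
        owner[e.start_frame : e.start_frame + e.n_frames] = lig_ids[e.ligand_id]
    for f in range(traj.n_frames):
        for m, idx in lig_head.items():
            heads = traj.coordinates[f, idx]
            dmins = [
                pairwise_min_image_distances(
                    traj.coordinates[f, gi], heads, traj.box[f]
                ).min()
                for gi in group_idx
            ]
            if m == owner[f]:
                n_close = sum(d <= site.event_cutoff for d in dmins)
                assert n_close >= site.min_groups, (
                    f"frame {f}: bound ligand {m} touches only {n_close} groups"
                )
            else:
                assert min(dmins) > site.event_cutoff + clearance, (
                    f"frame {f}: unbound ligand {m} too close to the site "
                    f"({min(dmins):.2f} Å)"
                )
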