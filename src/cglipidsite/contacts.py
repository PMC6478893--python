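"""Residue-discriminated contact occupancy.

For each protein residue, the occupancy of a ligand species is the fraction
of trajectory frames in which *any* head-group bead of *any* molecule of
that species lies within the contact cutoff (7 Å by default, minimum-image)
of any particle of the residue.  An occupancy of 1.0 therefore means a
contact during the entire analysed time; the union over molecules caps the
value at 1.  No smoothing is applied at this stage — the smoothing filter
belongs to the binding-duration analysis only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    AnalysisConfig,
    DEFAULT_SPECIES_HEADS,
    Trajectory,
    pairwise_min_image_distances,
)

__all__ = [
    "ContactMap",
    "residue_contact_occupancy",
    "call_binding_site",
    "write_contact_table",
    "read_contact_table",
]


@dataclass
class ContactMap:
    """Per-residue contact occupancy fractions for one ligand species."""

    residue_ids: np.ndarray  # (r,) int, ordered as in the topology
    residue_names: np.ndarray  # (r,) str
    occupancy: np.ndarray  # (r,) float in [0, 1]
    n_frames: int
    species: str
    head_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.residue_ids) == 0:
            raise ValueError("ContactMap requires at least one residue")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if np.any(self.occupancy < 0) or np.any(self.occupancy > 1):
            raise ValueError("occupancy values must lie in [0, 1]")

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.residue_ids.tolist(), self.occupancy.tolist()))


def _resolve_heads(traj: Trajectory, species: str, head_names=None):
    if head_names is None:
        try:
            head_names = DEFAULT_SPECIES_HEADS[species]
        except KeyError:
            raise ValueError(
                f"unknown species {species!r}: supply head_names explicitly"
            ) from None
    mask = traj.topology.head_mask(head_names)
    if not mask.any():
        raise ValueError(
            f"species {species!r} (heads {head_names}) absent from topology"
        )
    return tuple(head_names), mask


def residue_contact_occupancy(
    traj: Trajectory,
    config: AnalysisConfig,
    species: str,
    head_names=None,
    contact_matrix: bool = False,
):
    """Compute per-residue head-group contact occupancy for one species.

    Counts, for every protein residue, the frames in which any head bead of
    the species is within ``config.contact_cutoff`` of any particle of that
    residue, and normalises by the total frame count.  With
    ``contact_matrix=True`` also returns the per-frame 0/1 matrix
    (residues × frames) for debugging.
    """
    topo = traj.topology
    head_names, head_mask = _resolve_heads(traj, species, head_names)
    prot_mask = topo.protein_mask()
    if not prot_mask.any():
        raise ValueError("no protein residues present in topology")

    prot_idx = np.where(prot_mask)[0]
    prot_resids = topo.residue_ids[prot_idx]
    # stable order of first appearance in the topology
    order = np.unique(prot_resids, return_index=True)[1]
    resid_list = prot_resids[np.sort(order)]
    resid_pos = {r: i for i, r in enumerate(resid_list)}
    res_of_particle = np.array([resid_pos[r] for r in prot_resids])
    res_names = np.empty(len(resid_list), dtype=object)
    for i, r in zip(prot_idx, prot_resids):
        res_names[resid_pos[r]] = topo.residue_names[i]

    head_idx = np.where(head_mask)[0]
    counts = np.zeros(len(resid_list), dtype=int)
    matrix = (
        np.zeros((len(resid_list), traj.n_frames), dtype=np.uint8)
        if contact_matrix
        else None
    )
    cutoff = config.contact_cutoff
    for f in range(traj.n_frames):
        d = pairwise_min_image_distances(
            traj.coordinates[f, prot_idx], traj.coordinates[f, head_idx], traj.box[f]
        )
        near = (d <= cutoff).any(axis=1)
        hit = np.zeros(len(resid_list), dtype=bool)
        np.logical_or.at(hit, res_of_particle[near], True)
        counts += hit
        if matrix is not None:
            matrix[:, f] = hit

    cmap = ContactMap(
        residue_ids=resid_list.astype(int),
        residue_names=np.array([str(x) for x in res_names]),
        occupancy=counts / traj.n_frames,
        n_frames=traj.n_frames,
        species=species,
        head_names=head_names,
    )
    return (cmap, matrix) if contact_matrix else cmap


def call_binding_site(cmap: ContactMap, config: AnalysisConfig) -> list[int]:
    """Residues whose occupancy strictly exceeds the background threshold.

    The 15% default threshold marks the occupancy of non-binding-site
    residues; ties at the threshold are *not* called.  Residue order is
    preserved.
    """
    thr = config.occupancy_threshold
    return [int(r) for r, o in zip(cmap.residue_ids, cmap.occupancy) if o > thr]


def write_contact_table(cmap: ContactMap, path) -> None:
    """Write a TSV of per-residue occupancies (6-decimal round-trip)."""
    df = pd.DataFrame(
        {
            "residue_id": cmap.residue_ids,
            "residue_name": cmap.residue_names,
            "species": cmap.species,
            "occupancy": np.round(cmap.occupancy, 6),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_contact_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
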