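"""Binding-event detection, smoothing, censoring and residence-time statistics.

A site contact for binding-duration analysis is stricter than a residue
contact: a frame is in-contact when a ligand head bead is within the event
cutoff (8 Å) of at least two of three residue groups defined on the
β-strands composing the site (residues 58–60, 73–75 and 81–83 by default).
Because a sharp cutoff underestimates long events whenever the ligand
briefly drifts past the threshold, the binary series is filtered with a
five-frame majority vote (≥3 in-contact frames set the centre frame
in-contact) before events are extracted.  Events still bound at the end of
a run are end-censored and disregarded from duration statistics.

Pipeline order is fixed: raw_contact_series → majority_smooth →
extract_events.  Residue occupancy (contacts module) is never smoothed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AnalysisConfig, Trajectory, pairwise_min_image_distances

__all__ = [
    "SiteDefinition",
    "BindingEvent",
    "BindingEventSet",
    "ResidenceHistogram",
    "raw_contact_series",
    "majority_smooth",
    "extract_events",
    "detect_events",
    "residence_time_distribution",
    "default_log_bins",
    "time_weighted_mean",
    "write_event_table",
    "write_histogram_table",
]


@dataclass(frozen=True)
class SiteDefinition:
    """Three residue-id groups plus the multi-group contact criterion."""

    groups: tuple[tuple[int, ...], ...] = (
        tuple(range(58, 61)),
        tuple(range(73, 76)),
        tuple(range(81, 84)),
    )
    event_cutoff: float = 8.0  # Å
    min_groups: int = 2

    def __post_init__(self) -> None:
        if len(self.groups) != 3:
            raise ValueError("a site is defined by exactly three residue groups")
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("site groups must be non-empty")
        seen: set[int] = set()
        for g in self.groups:
            if seen & set(g):
                raise ValueError("site groups must be mutually disjoint")
            seen |= set(g)
        if self.min_groups not in (1, 2, 3):
            raise ValueError("min_groups must be 1, 2 or 3")
        if self.event_cutoff <= 0:
            raise ValueError("event_cutoff must be positive")

    @classmethod
    def from_config(cls, config: AnalysisConfig) -> "SiteDefinition":
        groups = tuple(
            tuple(range(lo, hi + 1)) for lo, hi in config.site_groups
        )
        return cls(
            groups=groups,
            event_cutoff=config.event_cutoff,
            min_groups=config.min_groups_in_contact,
        )


@dataclass(frozen=True)
class BindingEvent:
    ligand_id: int
    start_frame: int
    n_frames: int
    duration: float  # ps

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.duration <= 0:
            raise ValueError("events must span at least one frame")


@dataclass
class BindingEventSet:
    """Retained binding events plus censoring bookkeeping for one or more ligands."""

    events: list[BindingEvent]
    n_discarded_end_censored: int
    n_discarded_start_censored: int
    total_time: float  # ps
    series: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def durations(self) -> np.ndarray:
        return np.array([e.duration for e in self.events], dtype=float)

    @property
    def bound_time(self) -> float:
        return float(self.durations.sum()) if self.events else 0.0


@dataclass
class ResidenceHistogram:
    """Log-binned residence times; y is bound-time fraction per bin.

    Each event contributes its *duration* (not a count) to the bin holding
    it, normalised by the total simulation time, so the sum over all bins
    equals the fraction of total time spent in retained binding events.
    """

    bin_edges: np.ndarray  # (k+1,) ps, strictly increasing
    y: np.ndarray  # (k,) dimensionless fractions

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.y < 0):
            raise ValueError("histogram fractions must be non-negative")

    @property
    def bound_fraction(self) -> float:
        return float(self.y.sum())


# ---------------------------------------------------------------------------
# Site-contact series
# ---------------------------------------------------------------------------

def raw_contact_series(
    traj: Trajectory,
    site: SiteDefinition,
    ligand: int,
    head_names,
) -> np.ndarray:
    """Per-frame 0/1 site-contact series for one ligand molecule.

    Frame *i* is in-contact iff at least ``site.min_groups`` of the three
    residue groups each have ≥1 particle within ``site.event_cutoff``
    (minimum-image) of ≥1 head particle of the ligand.
    """
    topo = traj.topology
    head_mask = topo.head_mask(head_names) & (topo.molecule_ids == ligand)
    if not head_mask.any():
        raise ValueError(
            f"ligand molecule {ligand} has no head particle named {head_names}"
        )
    head_idx = np.where(head_mask)[0]

    group_idx = []
    for g in site.groups:
        idx = np.where(np.isin(topo.residue_ids, list(g)) & topo.protein_mask())[0]
        if len(idx) == 0:
            raise ValueError(f"site group {g} maps to no protein residues")
        group_idx.append(idx)

    series = np.zeros(traj.n_frames, dtype=np.uint8)
    for f in range(traj.n_frames):
        heads = traj.coordinates[f, head_idx]
        n_hit = 0
        for idx in group_idx:
            d = pairwise_min_image_distances(
                traj.coordinates[f, idx], heads, traj.box[f]
            )
            if (d <= site.event_cutoff).any():
                n_hit += 1
        series[f] = 1 if n_hit >= site.min_groups else 0
    return series


def majority_smooth(series, window: int = 5, min_true: int = 3) -> np.ndarray:
    """Majority-vote filter removing spuriously brief contacts and losses.

    Each output frame is set in-contact iff ≥ ``min_true`` frames of the
    ``window``-frame neighbourhood (centred; edges replicate-padded) are
    in-contact.  A constant series is returned unchanged.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if min_true > window or min_true < 1:
        raise ValueError("min_true must be in [1, window]")
    s = np.asarray(series, dtype=np.uint8)
    if s.ndim != 1 or len(s) == 0:
        raise ValueError("series must be a non-empty 1-D binary array")
    half = window // 2
    padded = np.concatenate(
        [np.repeat(s[0], half), s, np.repeat(s[-1], half)]
    ).astype(int)
    csum = np.concatenate([[0], np.cumsum(padded)])
    votes = csum[window:] - csum[:-window]
    return (votes >= min_true).astype(np.uint8)


# ---------------------------------------------------------------------------
# Event extraction with censoring
# ---------------------------------------------------------------------------

def extract_events(
    series,
    frame_interval: float,
    ligand_id: int = 0,
    discard_start_censored: bool = False,
) -> BindingEventSet:
    """Extract maximal in-contact runs as binding events.

    A run touching the final frame is still in progress when sampling ends
    (end-censored): it is excluded from the event list and counted in
    ``n_discarded_end_censored``.  Optionally, runs that already span frame
    0 (whose true start is unknown) can be discarded too; the published
    rule discards end-censored events only, which is the default.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    s = np.asarray(series, dtype=np.uint8)
    if s.ndim != 1 or len(s) == 0:
        raise ValueError("series must be a non-empty 1-D binary array")
    padded = np.concatenate([[0], s, [0]]).astype(int)
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]  # exclusive
    events: list[BindingEvent] = []
    n_end = 0
    n_start = 0
    for a, b in zip(starts, ends):
        if b == len(s):  # run includes the final frame
            n_end += 1
            continue
        if discard_start_censored and a == 0:
            n_start += 1
            continue
        events.append(
            BindingEvent(
                ligand_id=ligand_id,
                start_frame=int(a),
                n_frames=int(b - a),
                duration=float((b - a) * frame_interval),
            )
        )
    return BindingEventSet(
        events=events,
        n_discarded_end_censored=n_end,
        n_discarded_start_censored=n_start,
        total_time=float(len(s) * frame_interval),
        series={ligand_id: s},
    )


def detect_events(
    traj: Trajectory,
    site: SiteDefinition,
    head_names,
    smoothing_window: int = 5,
    smoothing_min_true: int = 3,
    ligands=None,
    discard_start_censored: bool = False,
) -> BindingEventSet:
    """Full per-ligand pipeline: contact series → smoothing → events.

    Runs every ligand molecule owning a named head particle (or the given
    subset) and pools the resulting events into one set.
    """
    topo = traj.topology
    if ligands is None:
        ligands = topo.ligand_molecule_ids(head_names)
    all_events: list[BindingEvent] = []
    series: dict[int, np.ndarray] = {}
    n_end = 0
    n_start = 0
    for lig in ligands:
        raw = raw_contact_series(traj, site, int(lig), head_names)
        smooth = majority_smooth(raw, smoothing_window, smoothing_min_true)
        ev = extract_events(
            smooth,
            traj.frame_interval,
            ligand_id=int(lig),
            discard_start_censored=discard_start_censored,
        )
        all_events.extend(ev.events)
        series[int(lig)] = smooth
        n_end += ev.n_discarded_end_censored
        n_start += ev.n_discarded_start_censored
    return BindingEventSet(
        events=sorted(all_events, key=lambda e: (e.start_frame, e.ligand_id)),
        n_discarded_end_censored=n_end,
        n_discarded_start_censored=n_start,
        total_time=traj.total_time,
        series=series,
    )


# ---------------------------------------------------------------------------
# Residence-time distribution and time-weighted statistics
# ---------------------------------------------------------------------------

def default_log_bins(
    frame_interval: float, total_time: float, bins_per_decade: int = 8
) -> np.ndarray:
    """Logarithmic bin edges spanning [frame_interval, total_time]."""
    if total_time <= frame_interval:
        raise ValueError("total_time must exceed frame_interval")
    lo = np.log10(frame_interval)
    hi = np.log10(total_time)
    n = max(1, int(np.ceil((hi - lo) * bins_per_decade)))
    return np.logspace(lo, hi, n + 1)


def residence_time_distribution(
    events: BindingEventSet,
    total_time: float | None = None,
    bins=None,
) -> ResidenceHistogram:
    """Log-histogram of event durations weighted by duration.

    Each event adds its full duration to the bin containing it; dividing by
    ``total_time`` makes y the fraction of total system time spent in
    events of that duration, so Σy recovers the overall bound-time
    fraction.
    """
    if total_time is None:
        total_time = events.total_time
    durations = events.durations
    if len(durations) and total_time < durations.max():
        raise ValueError("total_time is smaller than the longest event")
    if bins is None:
        bins = default_log_bins(
            min(durations) if len(durations) else total_time / 10.0, total_time
        )
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    if len(durations):
        out = (durations < bins[0]) | (durations > bins[-1])
        if out.any():
            bad = np.where(out)[0][0]
            raise ValueError(
                f"event {bad} (duration {durations[bad]} ps) lies outside "
                f"the bin range [{bins[0]}, {bins[-1]}]"
            )
    sums, _ = np.histogram(durations, bins=bins, weights=durations)
    return ResidenceHistogram(bin_edges=bins, y=sums / float(total_time))


def time_weighted_mean(durations) -> float:
    """Time-weighted average Σd²/Σd of event durations.

    Weights every event by its own length, so long events dominate — the
    mean answers "how long is the event a randomly chosen *bound instant*
    belongs to".  For exponential durations with rate k_off the population
    value is 2/k_off.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("durations must be non-empty")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    return float(np.sum(d * d) / np.sum(d))


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def write_event_table(events: BindingEventSet, path) -> None:
    """TSV of retained events (durations in ns) plus censoring counts."""
    df = pd.DataFrame(
        {
            "ligand_id": [e.ligand_id for e in events.events],
            "start_frame": [e.start_frame for e in events.events],
            "n_frames": [e.n_frames for e in events.events],
            "duration_ns": [e.duration / 1000.0 for e in events.events],
            "censored_flag": 0,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# n_discarded_end_censored={events.n_discarded_end_censored}\n")
        fh.write(
            f"# n_discarded_start_censored={events.n_discarded_start_censored}\n"
        )
        fh.write(f"# total_time_ns={events.total_time / 1000.0:.6f}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_histogram_table(hist: ResidenceHistogram, path) -> None:
    df = pd.DataFrame(
        {
            "bin_lo_ns": hist.bin_edges[:-1] / 1000.0,
            "bin_hi_ns": hist.bin_edges[1:] / 1000.0,
            "y": hist.y,
        }
    )
    df.to_csv(path, sep="\t", index=False)
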