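# Methods

This note documents the models and numerical choices behind `cglipidsite`:
what each stage computes, the parameters that matter, what the synthetic
generator does and does not emulate, and the known limitations of the
statistics.

## Contact model

All geometry uses minimum-image distances in orthorhombic boxes
(triclinic cells are rejected; the bilayer systems the package targets are
rectangular, and restricting to orthorhombic keeps the minimum image exact
with no nearest-neighbour search over periodic copies). Coordinates are
held in Å because every cutoff is defined on that scale; readers convert
from nm-based formats (GRO/XTC) on load.

**Residue occupancy** counts, per residue and species, frames with *any*
head bead of *any* molecule of the species within the contact cutoff
(default 7 Å) of *any* particle of the residue — an any-molecule union, so
occupancy is capped at 1 and "1.0" means contact during the entire
analysed time. Only head-group beads are tested (AM1/AM2, ROH, PO4/NC3 by
default; the species → bead-name table is user-editable because bead
naming varies across coarse-grain force-field versions). Occupancy is
*never* smoothed: the majority filter below belongs to duration analysis
only, where cutoff flicker fragments long events; for occupancy a
flickering frame is simply a frame without contact.

**Site-residue calls** use a strict inequality at the background threshold
(default 15%): the threshold is defined by the occupancy of non-site
residues, and ties at background should not be called.

## Binding events

A sharp single-cutoff definition underestimates long binding events
whenever the ligand briefly drifts past the threshold without leaving the
site. Two defences are used, in fixed order:

1. **Multi-group criterion.** A frame is in-contact when a head bead is
   within the event cutoff (8 Å) of at least `min_groups` (2) of three
   residue groups on the β-strands composing the site (58–60, 73–75,
   81–83 by default). Requiring two of three groups tolerates local
   excursions while anchoring the ligand to the site.
2. **Majority smoothing.** A 5-frame window sets the centre frame
   in-contact iff ≥ 3 window frames are in-contact. Edge frames are
   handled by replicate-padding two frames at each boundary — the choice
   that preserves constant series and treats both ends symmetrically. The
   filter removes every isolated feature of ≤ 2 frames inside a constant
   background and leaves all runs of ≥ 3 frames intact (series whose runs
   all have length ≥ 3 are fixed points).

Maximal in-contact runs of the smoothed series become events with duration
`n_frames × frame_interval` (a 1-frame event lasts one frame interval;
frame *i* is at time *i*·Δt, 0-based, Δt = 600 ps by default). An event
that includes the final frame is still in progress when sampling stops
(end-censored): it is counted but excluded from duration statistics.
Events already in contact at frame 0 are *retained* by default — for a
stationary exponential process their observed residual durations are again
exponential (memorylessness), so they are unbiased; a
`discard_start_censored` flag exists for bias studies.

The residence-time distribution histograms event durations on log-spaced
bins (default 8 per decade spanning [Δt, T]), each event contributing its
*duration* — not a count — normalised by the total simulation time, so the
y-values sum exactly to the retained bound-time fraction. This
conservation identity is enforced to 1e-12 in tests. Pooling across runs
of different lengths is done by normalising per run and then summing
duration-weighted contributions.

## Occupancy volumes

The protein is first aligned across frames by the z-rotation +
xy-translation (closed-form 2-D Kabsch) minimising protein RMSD to a
reference frame; z is never touched, because a full 3-D superposition
would tilt the membrane normal. All particles are co-transformed. The box
is then gridded at 5 Å with half-open cells anchored at the origin, and a
cell's value is the fraction of frames with ≥ 1 head bead of the species
inside (several beads in one cell count once, keeping values ≤ 1). The sum
over cells therefore equals the time-average number of distinct occupied
cells per frame — the invariant the tests assert against brute force.
Iso-surface thresholds default to 10% (ceramide) and 20% (cholesterol);
an optional linear molecule-count compensation
(`threshold × n_species/n_reference`) is provided but off by default — it
is one heuristic reading of count compensation, and the printed per-species
thresholds are taken as authoritative. Grids export as text OpenDX fields.

## Statistics

Residence times are summarised by the **time-weighted mean** Σd²/Σd — the
expected duration of the event a randomly chosen *bound instant* belongs
to. For exponential durations with rate k_off its population value is
2/k_off. Confidence intervals use a percentile bootstrap (default 10⁴
resamples of events with replacement; a single seeded generator per
invocation, the seed recorded in the output, makes reports
bit-reproducible). BCa is available behind a flag. The resampling unit is
the event, not the frame.

**Known limitation — CI undercoverage.** The percentile bootstrap of
Σd²/Σd undercovers for heavy-tailed duration samples: at n = 50
exponential events the measured coverage of the nominal 95% interval is
≈ 0.81 (BCa is no better, and duration-weighted resampling variants are
substantially worse). The statistic is dominated by the largest sampled
durations, whose variability the bootstrap understates. The CIs are
reported as the method defines them; they should be read as optimistic
for small event counts.

**Known limitation — finite-window censoring bias.** Discarding
end-censored events removes precisely the long events that dominate
Σd²/Σd. For exponential durations f(d) observed in a window T, completed
events have expected time-weighted mean ∫d²(T−d)f dd / ∫d(T−d)f dd: at
T = 6/k_off this is 1.53/k_off·2 ≈ 23% below the asymptotic 2/k_off, and
the bias only vanishes for T ≫ 1/k_off (≈ 2% at T = 60/k_off). Recovered
time-weighted means from short windows are therefore systematically low —
a property of the censoring rule itself, reproduced exactly by the
synthetic fixtures.

Sample comparisons use the one-tailed Mann–Whitney–Wilcoxon U test in its
continuity-corrected normal approximation with tie correction; the test
direction is a required argument, never a default. An exact-enumeration
mode (all C(n, n_b) group assignments, feasible for n_a + n_b ≲ 14) is
provided and cross-checked against an independent implementation in the
tests. The normal approximation tracks enumeration to ≤ 0.02 once both
groups have ≥ 3 observations; with 1–2 observations in a group the
approximation can deviate by up to ≈ 0.065 — unavoidable at such sizes,
and a reason to prefer the exact mode there. If all values are tied across
both samples the test is degenerate and returns p = 0.5 with a warning.

## Synthetic data

The generator emulates the *observables* of a protein–lipid binding
simulation, not its physics. A static pseudo-barrel (19 columns of 3
backbone beads on a 12 Å-radius cylinder, in a 100 × 100 × 60 Å box)
carries the three site groups on three spatially adjacent columns —
sequence-distant strands being spatial neighbours is exactly the β-barrel
situation. Sixteen single-bead ligand heads (AM1) move in the membrane
plane: unbound ligands random-walk (σ = 1.5 Å/frame, periodic) outside a
26 Å exclusion disc so they can never register a site contact, and during
bound intervals the scheduled ligand sits at an anchor 4.5 Å outside the
middle site column with sub-Å jitter, within 8 Å of all three groups.

Binding is **scheduled** by a two-state telegraph chain with per-frame
probabilities p_bind = k_on·Δt and p_unbind = k_off·Δt (state runs drawn
from the equivalent geometric law; validity guarded by k·Δt < 0.5). One
site, at most one ligand bound per frame, keeps ground truth unambiguous.
Scheduling (rather than emergent binding from potentials) is what makes
exact oracle tests possible: the pipeline must recover the scheduled event
list *exactly* on fixtures built with `min_run_frames=3`, which conditions
every state run to ≥ 3 frames so the event list is a fixed point of the
majority filter (the conditioning shifts each geometric run by 2 frames —
negligible against typical run lengths, and not used for kinetic-recovery
statistics, which use the unconditioned chain).

What the generator does *not* emulate — and what passing tests therefore
do not establish about real systems: emergent binding energetics,
competition between ligands, membrane undulations and leaflet asymmetry,
protein flexibility, and finite bead sizes. The tests establish that the
*analysis* is correct, not that any particular system binds.

Default study conditions for kinetic recovery were fixed by a power
analysis before any acceptance run: k_off = 1 μs⁻¹, k_on = 3 μs⁻¹,
Δt = 600 ps, 16 independent site series × 10⁴ frames × 20 seeds. At these
rates the occupancy estimator's autocorrelation time is
1/((k_on+k_off)Δt) ≈ 417 frames, giving a grand-mean standard error of
≈ 0.007 over the 320 series — so a ±0.02 check is a ≈ 3σ test — while
per-seed occupancy at any rate pair with k_off = 1 μs⁻¹ has s.e. ≥ 0.05
and is not a meaningful target.

## Structure comparison

`barrel_rmsd` computes RMSD after optimal rigid superposition (SVD Kabsch
with determinant correction) over an *explicit* index pairing — the
operation never guesses correspondences; a helper builds pairings from a
global sequence alignment (Biopython) when residue numbering differs. For
the VDAC1/VDAC2 comparison the β-barrel region is taken as all Cα after
the N-terminal helix (residues ≥ 26); the exact strand definition used for
the published 1.7 Å figure is not recorded, so the check carries a
±0.3 Å tolerance. The reference structures (PDB 4C69, 4BUM) are fetched
on first use or read from `tests/data/`.

## Problem sizes

Test fixtures use 10²–10⁴ frames and ≤ 73 particles, chosen so the full
suite runs in seconds while still resolving the statistical bands above;
the analysis code paths are identical at production scale, streaming
frames through the same vectorised per-frame kernels.
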