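# cglipidsite

Analysis toolkit for locating and quantifying lipid binding sites on
membrane proteins in coarse-grain molecular-dynamics trajectories — built
around the workflow used to characterise the ceramide head-group site on
voltage-dependent anion channels (VDACs), and applicable to any
protein–lipid system with named head-group beads (ceramide AM1/AM2,
cholesterol ROH, phosphatidylcholine PO4/NC3, …).

## What it computes

Given a topology (GRO/PDB) and trajectory (XTC/TRR/DCD), the package
performs the two standard post-processing analyses for protein–lipid
interactions, plus the statistics needed to compare them:

1. **Residue-discriminated contact occupancy.** For every protein residue
   *r* and lipid species *s*,

   occ(r, s) = (frames with any head bead of *s* within 7 Å of any bead of
   *r*, minimum image) / (total frames),

   so occ = 1 means contact throughout the sampled time. Residues above a
   15% background threshold are called as site residues.

2. **Binding-event kinetics with censoring.** A per-ligand site contact
   requires a head bead within 8 Å of ≥ 2 of 3 residue groups (defaults
   58–60, 73–75, 81–83, the β-strands composing the VDAC site). The binary
   series is filtered with a 5-frame/3-vote majority window to remove
   spuriously brief contacts or losses, maximal in-contact runs become
   events, and events still bound at the last frame are end-censored and
   disregarded. Durations are summarised as the time-weighted mean
   `Σdᵢ²/Σdᵢ` with a 10 000-resample percentile-bootstrap 95% CI, as a
   duration-weighted log-binned residence-time distribution whose Σy is
   the bound-time fraction, and compared between samples with a
   continuity-corrected one-tailed Mann–Whitney–Wilcoxon U test (exact
   enumeration available for small samples).

3. **Occupancy volumes.** After aligning the protein's in-plane position
   and rotation (z-rotation + xy-translation only, preserving the membrane
   normal), the box is gridded at 5 Å and each cell records the fraction
   of frames it holds a head bead. Grids export as OpenDX scalar fields
   (VMD/ChimeraX-loadable) with iso-occupancy thresholds of 10%
   (ceramide) / 20% (cholesterol).

4. **Synthetic ground truth.** Because production CG-MD trajectories are
   huge and not redistributable, `cglipidsite.synthetic` generates
   pseudo-barrel trajectories in which a two-state (telegraph) Markov
   chain with known k_on/k_off schedules the binding. Every stage of the
   pipeline can therefore be checked against exact ground truth, including
   the analytic stationary bound fraction k_on/(k_on+k_off) and the
   analytic time-weighted mean residence 2/k_off.

## Worked example

Generate a synthetic system (fast kinetics: k_on = k_off = 200 μs⁻¹,
5000 frames at 600 ps) and run the full pipeline:

```sh
cglipidsite simulate --config kinetics.yaml --outdir fixtures --seed 7
cglipidsite run --config pipeline.yaml
```

with `kinetics.yaml` holding `{k_on: 200.0, k_off: 200.0, n_frames: 5000}`
and `pipeline.yaml`:

```yaml
topology: fixtures/synthetic.gro
trajectory: fixtures/synthetic.xtc
output_dir: out
species: {ceramide: [AM1]}
primary_species: ceramide
resamples: 10000
seed: 7
```

This prints

```
loaded 5000 frames × 73 particles
ceramide: 5 residues above the 15% occupancy threshold
pipeline complete; manifest at out/manifest.json
```

and `out/stats.json` contains

```json
{
  "ci_high_ns": 9.995381244973855,
  "ci_low_ns": 7.6496113697779204,
  "n_events": 241,
  "n_resamples": 10000,
  "seed": 7,
  "time_weighted_mean_ns": 8.799913606911447
}
```

Reading: the called site residues (59, 73–75, 82 in the manifest) are the
residue groups the generator placed the bound ligand against; 241 retained
binding events give a time-weighted mean residence of 8.8 ns with 95% CI
[7.6, 10.0] ns, consistent with the discrete-time analytic value
(2 − k_off·Δt)/k_off ≈ 9.4 ns for the generating rates; the bound-time
fraction recovered from the residence histogram (0.463 in the manifest)
matches the telegraph stationary fraction 0.5 to sampling error. The run
also writes `contacts_ceramide.tsv`, `events.tsv`, `hist.tsv` and
`occupancy_ceramide.dx`.

Other subcommands: `contacts`, `events`, `occupancy`, `compare`, `rmsd`,
each a thin wrapper over one library function.

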