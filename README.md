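# dynsurf

Analysis pipeline for **dynamic-surface micropatterned cell migration
assays** — experiments in which cells are confined to microcontact-printed
patterns on an electroactive self-assembled monolayer, the surrounding
surface is electrochemically switched on by immobilizing RGD peptide
ligands, and the released cells are followed as they migrate and grow.

It is written for researchers analyzing such assays (or building methods
on top of them) and covers the four quantitative stages of the readout,
each usable independently from Python:

1. **Zone-resolved nuclear labeling index (NLI).** Nuclei are binned by
   migration distance from the pattern boundary (circle: annuli; line:
   parallel bands; half-open `(lo, hi]` intervals). Per zone,
   `NLI (%) = 100 · n_BrdU+ / n_total`, reported as the mean of per-chip
   ratios over replicate chips, ± SEM across chips. Inputs are either
   nucleus tables or two-channel (DAPI/BrdU) images, from which nuclei are
   detected as smoothed local maxima and labeled by greedy nearest-first
   channel matching.
2. **Trajectory-based migration velocity.** Positions are resampled to an
   hourly grid, per-hour displacements are summed into a cumulative path
   length, and the mean velocity is the OLS slope of cumulative distance
   on time; per-condition summaries are mean ± SEM over cells.
3. **Cyclic-voltammetry ligand quantification.** Peak detection on
   baseline-corrected sweeps; faradaic charge by chord-baseline trapezoid
   integration, `Q = (1/ν)∫|i − i_base| dE`; surface coverage
   `Γ = Q / (nFA)` (F = 96485 C/mol); pseudo-first-order immobilization
   kinetics `f(t) = 1 − e^{−kt}` fitted by nonlinear least squares.
4. **Two-color expression filtering.** Per-spot `M = log2(Cy5/Cy3)`,
   `A = ½·log2(Cy5·Cy3)`; per-chip lowess correction of M on A; a
   one-sample t-test of the 4 replicate log-ratios per condition; gene
   selection at ≥ 2.5-fold change (either direction) with p < 0.05 in at
   least one of 5 conditions; average-linkage clustering on
   1 − Pearson correlation of condition profiles.

A first-class synthetic-data generator (`dynsurf.simulate`) emulates
every raw data type — patterned nuclei with distance-dependent labeling
probability, persistent-random-walk trajectories with condition-dependent
speed, multi-peak voltammograms whose faradaic charge encodes a known
coverage, exponential conversion kinetics, and log-normal two-channel
intensities with planted differential expression — so the entire pipeline
runs, and is tested, at desk scale with known ground truth.

## Worked example

`examples/ligand_density.py` generates the two diagnostic voltammograms,
quantifies the monolayer, and fits the immobilization rate:

```
hydroquinone_quinone: oxidation 540 mV, reduction 320 mV
oxime: reduction 480 mV, oxidation 620 mV
reductive charge Q = 4.438e-05 C
surface coverage Gamma = Q/(nFA) = 2.30e-10 mol/cm^2
immobilization rate constant k = 0.0397 min^-1 (SE 0.0009)
```

The peak potentials identify which monolayer is on the electrode
(reactant quinone couple vs product RGD-oxime), the integrated reductive
charge converts to a molar surface density of 2.3 × 10⁻¹⁰ mol/cm², and k
sets the conversion half-time (ln 2 / k ≈ 17 min).

`examples/migration_velocity.py` runs the tracking stage per condition:

```
          dynamic_linear:  12.5 +/- 0.4 um/hr  (n=12)
          dynamic_cyclic:  11.1 +/- 0.4 um/hr  (n=12)
  nondynamic_linear_2pct:   7.7 +/- 0.2 um/hr  (n=12)
  nondynamic_cyclic_2pct:   3.1 +/- 0.1 um/hr  (n=12)
```

Cells released from patterns (dynamic) migrate at ~12 µm/hr regardless of
ligand affinity, while cells seeded directly onto the same high-affinity
cyclic-RGD chemistry crawl at ~3 µm/hr — the migration-memory contrast
the assay was designed to expose.

The other examples cover the zone-resolved NLI profile
(`nli_zones.py`), the image-based detection path (`image_pipeline.py`),
and expression filtering/clustering (`expression_filter.py`). A thin CLI
mirrors the library (`dynsurf simulate|nli|track|echem|expr --help`).

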