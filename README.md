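# dnuptake

Quantitative machinery for studies of cell-surface-binding-enhanced uptake
of DNA nanostructures (DNs): a Helfrich membrane-wrapping energy model that
asks whether cholesterol-anchor adhesion can pay for passive engulfment,
and the image- and gel-quantification pipelines behind the typical readouts
of such studies — cell-surface vs. internalized fluorescence, internalization
efficiency, intranuclear delivery, and gel-band stability fractions —
exercised end-to-end on synthetic data with known ground truth.

It is written for researchers who anchor DNs (spheres, rods, flat tiles) to
cell membranes via cholesterol tags and quantify their fate by dual-color
fluorescence microscopy, confocal imaging, and agarose gel electrophoresis.

## The model

The membrane is a tensionless elastic continuum with bending energy

```
E_bend = (κ/2) ∮ (c1 + c2)² dA        [κ in kBT]
```

Complete engulfment forces the membrane onto the particle's shape:

| shape | closed form | κ = 25 kBT |
|---|---|---|
| sphere (any radius) | 8πκ | 628.3 kBT |
| spherocylinder rod, radius R, tip-to-tip L | πκ(L−2R)/R + 8πκ | 9447.2 kBT (R=3.5, L=400 nm) |
| tile w×h×t, rim as half-cylinder of radius t/2 | πκ·2(w+h)/t | 13351.8 kBT (96×74×2 nm) |

Adhesion from anchor insertion is `E_adh = n·x·kBT` (x ≈ 13 per
cholesterol). Wrapping is feasible only when `E_adh ≥ E_bend`; for a sphere
that already demands n ≥ 48 anchors — an order of magnitude more than the
4–10 overhangs typically installed — so passive, adhesion-driven uptake is
ruled out for every default scenario, and active endocytic processes must
do the work.

The quantification side implements: whole-frame surface-signal integration
and white top-hat punctate internal-signal extraction with
`efficiency = I_int / (I_int + I_surf)`; Otsu-segmented, eroded nuclear
ROIs with per-area intranuclear intensity and per-cell intranuclear /
whole-cell efficiency; lane densitometry with morphological baseline
removal and intact-band fractions; and one-way ANOVA with Tukey HSD tiers.

## Worked example

```sh
$ dnuptake mechanics
```

```
 shape orientation  n_anchors  e_bending  e_adhesion  n_threshold_int  feasible
sphere  horizontal          4      628.3        52.0               49     False
sphere  horizontal         10      628.3       130.0               49     False
   rod  horizontal          4     9447.2        52.0              727     False
   ...
  tile    vertical         10    13351.8       130.0             1028     False
```

Every default scenario is infeasible: even ten anchors supply 130 kBT
against a minimum bending bill of 628 kBT.

Quantifying a simulated dual-channel field (8 cells, shot noise, flat
background of 4 counts) against its recorded ground truth:

```python
from dnuptake import synthetic, uptake

spec = synthetic.CellImageSpec(seed=11)
surface, internal, nuclei, truth = synthetic.make_cell_image(spec)
res = uptake.quantify(surface, internal,
                      surface_background=spec.background_offset,
                      internal_background=spec.background_offset)
```

prints (via f-strings)

```
i_surface  = 4.665e+06   (truth 4.47e+06)
i_internal = 3.304e+06   (truth 3.2e+06)
efficiency = 0.415
```

Both integrated intensities land within 5% of the programmed truth; the
efficiency is the internalized fraction of total measured signal, not the
fraction of particles internalized.

Other subcommands — `simulate`, `quantify-uptake`, `quantify-nuclear`,
`quantify-gel`, `stats` — take YAML/JSON configs and write CSV; see
`dnuptake --help`.

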