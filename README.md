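# smsleak

Predict and quantify slice-leakage and in-plane aliasing artefacts in
simultaneous multi-slice (SMS / multiband) echo-planar fMRI.

## The problem

SMS-EPI excites M slices at once and separates them computationally
(slice-GRAPPA).  When separation is imperfect — as during abrupt local
signal change such as forceful eye blinks — signal from one slice *leaks*
into the other M−1 simultaneously acquired slices.  Combined with in-plane
GRAPPA acceleration, the leaked signal lands at geometrically fixed
positions: within each simultaneous slice, one alias at the CAIPIRINHA
field-of-view shift

&nbsp;&nbsp;&nbsp;&nbsp;y_alias = y_source + (FOV/3)·m  (mod FOV),&nbsp;&nbsp;m = 1…M,

and, when the in-plane factor R > 1, a second one a further FOV/2 along
the phase-encode axis.  `smsleak` computes these positions for a given
source voxel, builds the diameter-7 (29-voxel) in-plane disk masks used to
interrogate them, and quantifies artefact intensity with two statistics:

- **variance map** — per-voxel temporal sample variance of the 4D series;
- **block statistic** — each voxel's volume-to-volume signal change,
  normalised by that voxel's maximum absolute change over the whole run
  (a percentage in [−100, 100]); the mean absolute percentage change over
  a mask is computed separately for task-on and task-off blocks, and the
  artefact intensity is the on-minus-off difference.

A synthetic 4D generator produces head-phantom runs with a block-locked
"eye" fluctuation and known injected leakage, providing ground truth for
validation. It is intended for fMRI methodologists and QC pipelines
piloting SMS protocols.

## Worked example

```sh
python examples/predict_artifact_locations.py
```

For the reference protocol (96×96×68 grid of 2 mm voxels, 192 mm FOV,
MB4, GRAPPA 2, FOV/3 CAIPI shift, anterior–posterior phase encoding) and
an eye source at voxel (32, 91, 18), the simultaneous slice group is
[1, 18, 35, 52] and the eight predicted artefact positions are:

```
 label   class  m   x   y slice
     A   caipi  1  32  27    35
    Ag  grappa  1  32  75    35
     B   caipi  2  32  59    52
    Bg  grappa  2  32  11    52
     C   caipi  3  32  91     1
    Cg  grappa  3  32  43     1
     D   caipi  4  32  27    18
    Dg  grappa  4  32  75    18
```

Rows A–D are the CAIPI aliases (one per simultaneous slice, taken in
cyclic order after the source slice), Ag–Dg the corresponding GRAPPA
ghosts 48 voxels (FOV/2) further on; the x coordinate never moves because
aliasing acts only along the phase-encode axis.

`examples/quantify_simulated_blinking_run.py` simulates a desk-scale
blinking run (20 s forceful-blinking / 20 s rest blocks, 200 volumes at
TR 1.5 s) with a 0.2 leak fraction and reports the block statistic per
region — alias disks score on−off differences around 17–18 percentage
points while control disks stay below 1 — and
`examples/phase_encode_axis_comparison.py` shows why left–right phase
encoding is safer for the eyes: it moves 199 of 213 predicted alias
voxels outside the head, versus 52 of 231 for anterior–posterior.

## Command line

```sh
smsleak predict  --config geom.cfg --source 32,91,18 --table locations.csv --out masks.nii.gz
smsleak variance --series run.nii.gz --out var.nii.gz
smsleak quantify --series run.nii.gz --masks masks.nii.gz --design design.csv --out report.csv
smsleak simulate --config scenario.cfg --seed 1 --out sim.nii.gz --truth truth.nii.gz
```

Configs are flat `key = value` or YAML files (`nx, ny, nz, voxel_size_mm,
mb_factor, grappa_factor, caipi_denominator, pe_axis, tr_s`); designs are
CSV with `label, onset_s, duration_s`.  Exit codes: 0 success, 1 user
error, 2 internal error.

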