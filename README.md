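# perispect

Serial metabolic and volumetric evaluation of perihematomal tissue after
intracerebral hemorrhage (ICH), as a tested, reproducible pipeline.

After an ICH, the hematoma is surrounded by a rim of perihematomal edema
(PHE) that resolves over days to weeks. Whether the tissue that recovers
from edema regains *metabolic* integrity can be probed non-invasively with
proton MR spectroscopy: N-acetylaspartate (NAA, 2.01 ppm) marks neuronal
health, creatine (Cr, 3.03 ppm) energy metabolism, and choline (Cho,
3.19 ppm) membrane turnover. This package implements every computational
stage of such a longitudinal study — for three tissue classes (PHE,
adjacent tissue with no edema = ATNE, and the contralesional hemisphere)
at days 1, 7 and 14 — together with forward simulators that generate every
input with known ground truth, so the whole chain is testable without any
animal data.

## What it computes

**Absolute quantification.** For each CSI voxel, the metabolite peak area
`Am` and the unsuppressed water area `Aw` give the concentration

```
Cm = (Am / Aw) · [Nw (1−e^(−TR/T1w)) e^(−TE/T2w)] /
                 [Nm (1−e^(−TR/T1m)) e^(−TE/T2m)] · Cw
```

with proton counts `N`, relaxation times `T1/T2`, and tissue water
concentration `Cw` (mM). Spectra are automatically phase-corrected
(peak-anchored zero/first-order estimate) and integrated over 0.16 ppm
windows with a linear baseline; finite-window capture and Cr/Cho
cross-talk are undone analytically using the prior lineshapes.

**Volumetry.** Hematoma (FLAIR-hypointense) and edema (hyperintense) masks
grow from single seed voxels by a running-mean region-growing rule; volumes
are voxel counts × voxel volume, with percent change versus day 1.

**Inference.** Concentrations follow a linear mixed model
`value ~ region * day` with random intercepts for animal and
animal × region (nested covariance); volumes use `volume ~ day` with an
animal intercept. REML fits, containment degrees of freedom, and the
standard contrast set (each region vs contralesional per day, day-14 vs
day-1 per region).

**Simulation.** The `synthdata` module renders PRESS-CSI spectrum pairs
(9×9 grid, TR/TE = 2000/144 ms, 2000 Hz bandwidth, 15 mm voxels) by
*inverting* the quantification equation, concentric-ellipsoid FLAIR
phantoms with exact label volumes, and longitudinal cohort tables with
animal-level random effects.

## Worked example

```bash
perispect run --config configs/demo.yaml --verbose
```

simulates a 4-animal cohort (CSI grids at SNR 30, shrinking lesion
phantoms), quantifies, segments and models it in about half a minute,
writing tables, figures and a manifest under `runs/demo/`. The run prints
per-stage QC (`quantify.n_voxels: 36`, `segment.n_border_leaks: 0`, all
mixed models converged) and the contrast table shows the pattern built
into the generator, e.g. for NAA:

```
contrast              estimate      se       p   significant
PHE day 14 vs day 1     4.2125  1.4524  0.0095   True
ATNE day 14 vs day 1   -0.7306  1.4524  0.6211   False
```

i.e. NAA in the edematous rim recovers by ~4 mM between day 1 and day 14
(p ≈ 0.01) while the non-edematous adjacent tissue shows no recovery; the
measured edema volume falls 28.0% by day 7 and 84.6% by day 14.

The numbered scripts under `analysis/` run the same stages at full study
scale (12 animals, SNR 20) with a narrative summary per step:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_quantify_spectra.py
...
python 06_recover_published_means.py
```

## Layout

- `src/perispect/` — the library: `params`, `synthdata`, `spectra`,
  `quant`, `volumetry`, `stats`, `experiments`, `pipeline`, `io`, `cli`
- `analysis/` — numbered study drivers over the library
- `configs/` — run configurations; `src/perispect/data/priors.yaml` holds
  the (replaceable) relaxation priors
- `docs/methods.md` — model assumptions, defaults, numerical choices and
  limitations
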