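# Methods

This note documents the models, defaults and numerical choices behind
`perispect`, and what the synthetic-data experiments do and do not show.

## Forward spectral model

Each CSI voxel is rendered directly in the frequency domain as a sum of
complex Lorentzian lines (absorption + i·dispersion) on an ascending ppm
axis centred on water at 4.7 ppm. Defaults mirror the acquisition the
pipeline targets: TR/TE = 2000/144 ms, 2000 Hz bandwidth, 2048 complex
points (≈0.0077 ppm/point at 3 T, 127.74 Hz/ppm), 9×9 grid, 15 mm
isotropic voxels. A Lorentzian shape is the natural choice for in vivo
PRESS at TE 144 ms; Gaussian/Voigt shapes are a possible config extension,
not implemented. No macromolecule baseline, no lactate, no k-space or
chemical-shift-displacement physics — the simulator reproduces what the
quantification stage must invert, not scanner physics. The ppm axis is
stored ascending; plots follow the reversed display convention.

The metabolite peak area is set by inverting the water-referenced
concentration equation, `Am = Cm · Aw / (R · Cw)` with `R` the
relaxation/proton factor below, so a perfect measurement chain returns the
injected concentration identically; the unsuppressed companion spectrum
carries the water line (area `Aw` = 1000 a.u. × a per-voxel water scale).
Zero- and first-order phase errors rotate both spectra about the water
pivot (4.7 ppm), as a shared receiver phase would.

**Noise and SNR.** One complex Gaussian noise level is added to both
spectra of a voxel, as a single receiver produces one thermal noise floor.
SNR is quoted the way MRS reports it: reference-peak height over the
real-channel noise SD, where the reference peak is the tallest metabolite
line of the suppressed spectrum (water, for a metabolite-free voxel). The
unsuppressed water line therefore enjoys a much higher effective SNR, as
on a scanner. Defining SNR against the water peak *of the suppressed
spectrum* would put metabolite peaks ~20× below the noise floor at SNR 20
and make single-voxel quantification meaningless.

## Relaxation priors

The correction `R = [Nw(1−e^(−TR/T1w))e^(−TE/T2w)] /
[Nm(1−e^(−TR/T1m))e^(−TE/T2m)]` needs T1/T2 for each resonance and for
tissue water, plus `Cw`. These are not universal constants; the shipped
`data/priors.yaml` holds literature-style 3 T stand-ins (NAA 2.01 ppm,
3 protons, T1/T2 = 1400/250 ms; Cr 3.03 ppm, 3, 1300/160; Cho 3.19 ppm,
9, 1150/220; water 1100/80 ms) and is explicitly replaceable — a site
should substitute its own table. `Cw` defaults to 55 510 mM × a tissue
water fraction of 0.71; both are configurable. Because the simulator and
the quantifier share the priors, recovery tests validate the *pipeline*,
not the priors themselves.

## Phase correction

Automatic phasing is anchored on the known resonance positions. The
complex spectrum is summed over a ±0.04 ppm window at each expected peak;
for an isolated Lorentzian the dispersive part is odd about the centre and
cancels, so the argument of the sum is the local phase error. Overlapping
neighbours leak dispersion into each other's windows, so the per-peak
complex amplitudes are first separated by solving the small linear system
of unit lines rendered on the same axis. A magnitude-weighted least-squares
line through the per-peak phases gives (φ0, φ1), pivoted on water.

A spectrum-wide objective was evaluated first — minimising the integrated
negative real part over 1.8–3.4 ppm, coarse grid plus refinement — and
rejected: for a spectrum of three sparse Lorentzians the penalty is
*exactly zero* along a manifold of wrong (φ0, φ1) pairs, because the
dispersive tails of different peaks cancel each other's negative lobes;
absorption-maximising tie-breaks are biased by the dispersive wings.
The anchored estimator recovers injected phases to ≪1° on clean spectra
and degrades gracefully with noise; spectra whose strongest anchor falls
below 5× the noise floor (robust SD over the signal-free 0.2–1.2 ppm
band) are flagged `low_confidence`, never silently trusted.

The water line is integrated after removing the first-order ramp estimated
from the suppressed companion (same receiver) and self-phasing the
remaining zero order from the complex value at the peak maximum; without
the ramp removal a 20°/ppm error biases the water area by ~1% through the
odd×odd dispersion term.

## Integration and window corrections

Peak areas are trapezoidal integrals of the real part over
center ± 0.08 ppm (default keeps the Cr and Cho windows disjoint) minus a
straight baseline through two anchors, each the mean over a 0.04 ppm band
just outside the window. Band-averaged anchors keep the baseline from
amplifying point noise (single-sample anchors cost ~2× in area SD at
SNR 20). The un-modelled tails this operator discards, and the few percent
each of Cr and Cho leaks into the other's window, are undone by solving
`observed = M · true` where `M[k, l]` is the area a unit Lorentzian *l*
(prior position and linewidth) receives in window *k* when pushed through
the *same* integration code — operator-exact by construction, and exact
for noiseless Lorentzian inputs (round-trip error is at machine
precision; the acceptance margin of 0.5% covers discretisation). The
closed-form capture/leakage expressions are kept alongside as independent
oracles; they agree with the rendered operator to ~1% (window snapping on
the sampled axis).

Integration windows and the baseline rule are declared defaults of this
package, not reconstructions of the original manual procedure.

## Lesion phantom and volumetry

The phantom is three nested ellipsoids: brain (default 70.3 ml, mild
anisotropy 1.15:1:0.87), an edema ellipsoid of volume hematoma + edema,
and the hematoma core (defaults 2.38 and 1.00 ml, lesion anisotropy
1.1:1:0.9, offset into one hemisphere), rendered by centre-inclusion at
0.5 mm (tests also use 1.0 mm). Semi-axes are solved analytically from the
target volumes, so label-count volumes track targets to ≪1% at 0.5 mm.
Intensities are FLAIR-like (edema 180 > brain 100 > hematoma 30 >
background 0). Irregular lesion shapes, partial-volume blur and bias
fields are *not* modelled: volumetric tests show the segmentation
machinery is correct, not that it handles real FLAIR contrast.

Region growing accepts, per sweep, every connected neighbour (6- or
26-neighbourhood; 26 default) within an absolute tolerance (default 25
intensity units) of the running region mean — batch sweeps, so results are
deterministic. A fixed-seed-intensity mode exists for strict
tolerance-monotonicity. Masks touching the image border are flagged as
possible leaks (manual mask editing is out of scope; QC flags replace it).
ICV is a threshold halfway between the background floor and the 99th
intensity percentile, closed morphologically and hole-filled, which pulls
the hypointense hematoma back into the head mask.

## Cohort generator and variance decomposition

Concentration tables follow `value = mean(region, day, metabolite) +
animal + animal×region + residual`, all effects Gaussian and drawn
independently per metabolite. The day-1/day-14 NAA and Cr cell means are
the published group means; day-7 cells and all Cho cells are not printed
numerically in the source study and are figure-level stand-ins. The
variance split is not published either; the defaults
`sd_animal = sd_animal_region = 0.8`, `sd_resid = 2.2` mM (total ≈2.5,
matching the printed per-cell SDs of ~2–3 mM) put most variance in the
residual, which is how single-voxel MRS behaves — measurement noise
dominates animal-level biology. Lesion-volume cohorts use a per-animal
lognormal size factor (25%) and 15% proportional residual around day means
that reproduce the published reductions (edema −23.1%/−82.7%, hematoma
−15.7%/−38.3%).

## Mixed models

Concentrations: REML fit of `value ~ region * day` (categorical, reference
= contralesional and day 1) with a random animal intercept and an
animal×region variance component — the nested covariance in which
same-animal measurements correlate and same-animal-same-region ones more
so. Random effects are intercept-only (slopes are neither identifiable nor
implied by the design). Volumes: `volume ~ day` with an animal intercept.
The ambiguous region label "PHNE" that sometimes appears for the
non-edematous adjacent tissue is read as ATNE throughout.

Contrast t-tests use containment degrees of freedom for the balanced
split-plot layout: time and region×time contrasts test against the
residual stratum (df = N − ar − (d−1) − (r−1)(d−1), = 66 for 12 animals ×
3 regions × 3 days), region contrasts against the animal×region stratum
(df = (a−1)(r−1) = 22). On balanced data this reproduces the classical
exact partition; a Satterthwaite approximation would coincide there and is
not exposed by the backend. Fitting tries lbfgs first, then the default
and CG optimizers; a fit that still reports non-convergence, or a variance
component at the zero boundary, is flagged on the result. No multiplicity
correction is applied to the contrast set by default (matching the
reporting style the pipeline mirrors); a Holm adjustment is available as
`holm_adjust`.

Calibration was verified two ways: fixed effects and variance components
agree with R `lme4` to ≈10⁻⁶ on the same data, and the interaction
contrast's type-I error converges to 0.049 over 10 000 null cohorts
(checked against an exact split-plot ANOVA oracle, t-statistic ratio
1.003 ± 0.021). The calibration test uses 3000 null cohorts so the
binomial Monte-Carlo noise (±2 SE ≈ 0.8 points) stays inside the 4–6%
acceptance band; at 1000 cohorts the noise alone would dominate the
margin.

## Problem sizes and determinism

Recovery experiments use 100 noise realizations per condition at SNR 20
(SE of the mean ≈0.5–0.7% of the target, comfortably inside the 2%
tolerance), 100 cohorts for the qualitative contrast pattern, 3000 for
type-I calibration, and 0.5 mm voxels for the reference phantom. All
generators take explicit seeds (numpy `default_rng`); per-item streams are
spawned via `SeedSequence`, so every table and spectrum is bit-reproducible
given the seed, and pipeline runs with equal seeds produce byte-identical
CSVs.

## Known limitations

- The pipeline's accuracy statements are conditional on the prior table:
  wrong T1/T2/Cw or linewidths bias concentrations multiplicatively, and
  nothing in the data can detect that (no relaxation estimation, no
  partial-volume/CSF correction).
- Tissue water content is assumed equal across regions; the only guard is
  the water-ratio QC table (lesional vs contralesional `Aw` per day),
  mirroring how such studies argue the reference is stable.
- Simulated lineshapes, phases and noise are idealised; passing recovery
  tests demonstrates the correctness of the computational chain, not
  performance on real spectra with drift, eddy currents or baseline
  distortions.
- The phantom geometry is convex and noiseless by default; region growing
  on real FLAIR would need tolerance tuning and occasionally the manual
  editing this package deliberately replaces with QC flags.
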