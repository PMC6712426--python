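# Default relaxation priors for water-referenced absolute quantification
# at 3 T (PRESS-CSI, TR/TE = 2000/144 ms).
#
# These are literature-style stand-in values, versioned with the package and
# intended to be replaced by site-specific measurements: T1/T2 in ms,
# linewidth as FWHM in Hz, ppm referenced to water at 4.7 ppm.
# n_protons counts the protons contributing to the quantified resonance
# (NAA/Cr acetyl/methyl CH3 = 3; Cho trimethylamine N(CH3)3 = 9; water = 2).
version: 1
metabolites:
  NAA:
    ppm: 2.01
    n_protons: 3
    t1: 1400.0
    t2: 250.0
    linewidth: 5.0
  Cr:
    ppm: 3.03
    n_protons: 3
    t1: 1300.0
    t2: 160.0
    linewidth: 5.0
  Cho:
    ppm: 3.19
    n_protons: 9
    t1: 1150.0
    t2: 220.0
    linewidth: 5.0
water:
  ppm: 4.7
  n_protons: 2
  t1: 1100.0
  t2: 80.0
  linewidth: 8.0
  water_fraction: 0.71
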