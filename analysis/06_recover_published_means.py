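"""Parameter-recovery experiments at the published group means.

Since the animal data are not public, the printed group statistics serve as
simulation ground truths: single-voxel spectra are generated at those means
(SNR 20, random zero-order phase), pushed through the full measurement
chain, and the recovered means are compared with what was injected.  The
same is done for the day-1 lesion volumes via phantom segmentation, and for
the qualitative mixed-model contrast pattern over 100 simulated cohorts.
"""

from perispect.experiments import (qualitative_pattern_rate,
                                   recover_concentration,
                                   segment_phantom_volumes)

CELLS = [("NAA", 13.7, "contralesional day 1"),
         ("NAA", 9.70, "PHE day 1"),
         ("NAA", 14.79, "PHE day 14"),
         ("NAA", 9.45, "ATNE day 1"),
         ("Cr", 6.23, "PHE day 14"),
         ("Cr", 9.43, "contralesional day 1")]

if __name__ == "__main__":
    print("concentration recovery (100 noise realizations each, SNR 20):")
    for met, cm, label in CELLS:
        out = recover_concentration(cm, met, seed=1)
        print(f"  {met:3s} {label:22s} truth {cm:6.2f} -> "
              f"recovered {out['mean']:6.2f} +- {out['sd']:.2f} mM")

    vols = segment_phantom_volumes(seed=1)
    print("\nphantom volumetry at 0.5 mm voxels (noiseless):")
    for k, target in vols["targets"].items():
        print(f"  {k:12s} target {target:6.2f} -> segmented {vols[k]:6.2f} ml")

    pat = qualitative_pattern_rate(n_cohorts=100, seed=1)
    print(f"\nmixed-model contrast pattern (PHE day-14 recovery significant, "
          f"ATNE not):\n  reproduced in {pat['rate']:.0%} of 100 cohorts "
          f"(PHE significant {pat['phe_significant']:.0%}, "
          f"ATNE non-significant {pat['atne_nonsignificant']:.0%})")
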