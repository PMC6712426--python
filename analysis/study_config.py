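"""Shared configuration for the numbered analysis scripts.

One cohort of 12 animals imaged at days 1, 7 and 14 — CSI spectra at SNR 20
with random zero-order phase errors, plus FLAIR-like lesion phantoms —
everything written under results/study/.
"""

from perispect.pipeline import RunConfig

STUDY = RunConfig(
    seed=7,
    out_dir="results/study",
    n_animals=12,
    snr=20.0,
    phase0_jitter=30.0,
    phantom_voxel_mm=1.0,
)
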