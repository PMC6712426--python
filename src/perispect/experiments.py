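"""Parameter-recovery experiments.

The study's animal data are not public, so its printed group statistics act
as simulation ground truths: spectra and phantoms are generated at those
values and pushed through the full measurement pipeline, and the recovered
quantities are compared against what was injected.  These routines are used
both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .params import AcquisitionParams, PriorTable, default_priors
from .quant import quantify_voxel
from .synthdata import (GroundTruthVoxel, PhantomSpec, CohortDesign,
                        default_cohort_design, simulate_cohort,
                        simulate_flair_phantom, simulate_spectrum, DAYS)
from .volumetry import SegmentationParams, compute_volumes, segment_phantom
from .stats import fit_lmm


def recover_concentration(cm_true: float, metabolite: str,
                          snr: float = 20.0, n_realizations: int = 100,
                          phase0_range: float = 30.0, seed: int = 0,
                          priors: PriorTable | None = None,
                          acq: AcquisitionParams | None = None) -> dict:
    """Mean concentration recovered by the full phasing + integration +
    water-referencing chain over noise realizations of a single voxel.

    Each realization renders a one-metabolite voxel at the given ground
    truth with complex Gaussian noise at the stated SNR and a random
    zero-order phase error drawn uniformly in ``+-phase0_range`` degrees.
    """
    priors = priors or default_priors()
    acq = acq or AcquisitionParams()
    met = priors[metabolite]
    values = []
    for k in range(n_realizations):
        rng = np.random.default_rng([seed, k])
        truth = GroundTruthVoxel(
            concentrations={metabolite: cm_true}, snr=snr,
            phase0=float(rng.uniform(-phase0_range, phase0_range)))
        sup, uns = simulate_spectrum(truth, [met], priors.water, acq, seed=rng)
        rec = [r for r in quantify_voxel(sup, uns, priors, acq)
               if r.metabolite == metabolite][0]
        values.append(rec.cm)
    values = np.asarray(values)
    return {"mean": float(values.mean()), "sd": float(values.std(ddof=1)),
            "n": n_realizations, "truth": cm_true}


def segment_phantom_volumes(hematoma_ml: float = 1.00, edema_ml: float = 2.38,
                            icv_ml: float = 70.3, voxel_mm: float = 0.5,
                            connectivity: int = 26, seed: int = 0) -> dict:
    """Render a noiseless concentric-ellipsoid phantom at the given targets,
    seed-grow each lesion class from one interior voxel, and report the mask
    volumes in ml (plus the thresholded ICV)."""
    spec = PhantomSpec(voxel_mm=voxel_mm, icv_volume=icv_ml,
                       hematoma_volume=hematoma_ml, edema_volume=edema_ml)
    ph = simulate_flair_phantom(spec, seed=seed)
    img = np.asarray(ph.image.dataobj)
    lab = np.asarray(ph.labels.dataobj)
    seeds = []
    for cls, code in (("hematoma", 3), ("edema", 2)):
        w = np.where(lab == code)
        mid = len(w[0]) // 2
        seeds.append(((int(w[0][mid]), int(w[1][mid]), int(w[2][mid])), cls))
    params = SegmentationParams(seeds=seeds, connectivity=connectivity)
    masks = segment_phantom(img, params)
    vols = compute_volumes(masks, voxel_mm)
    return {"hematoma_ml": vols["hematoma_ml"], "edema_ml": vols["edema_ml"],
            "icv_ml": vols["icv_ml"],
            "targets": {"hematoma_ml": hematoma_ml, "edema_ml": edema_ml,
                        "icv_ml": icv_ml},
            "n_voxels": int(np.prod(img.shape))}


def null_rejection_rate(n_cohorts: int = 3000, n_animals: int = 12,
                        alpha: float = 0.05, seed: int = 0) -> dict:
    """Type-I error of the region x time interaction contrast under the
    null (all cell means equal, random effects at their defaults)."""
    means = {(r, d, "NAA"): 10.0 for r in ("PHE", "ATNE", "CONTRA")
             for d in DAYS}
    rejections = 0
    for k in range(n_cohorts):
        design = CohortDesign(region_time_means=dict(means),
                              n_animals=n_animals,
                              seed=int(np.random.default_rng([seed, k])
                                       .integers(2**31 - 1)))
        fit = fit_lmm(simulate_cohort(design))
        c = fit.contrasts.set_index("contrast")
        p = c.loc["(PHE - CONTRA) x (day 14 - day 1)", "p"]
        rejections += p < alpha
    return {"rate": rejections / n_cohorts, "n": n_cohorts, "alpha": alpha}


def qualitative_pattern_rate(n_cohorts: int = 100, n_animals: int = 12,
                             seed: int = 0) -> dict:
    """Fraction of simulated cohorts (generating means at the published
    values) whose NAA mixed model reproduces the published contrast pattern:
    PHE day-14 recovery significant, ATNE day-14 change not."""
    hits = phe_sig = atne_ns = 0
    for k in range(n_cohorts):
        design = default_cohort_design(seed=seed + k, n_animals=n_animals)
        coh = simulate_cohort(design)
        fit = fit_lmm(coh[coh.metabolite == "NAA"])
        c = fit.contrasts.set_index("contrast")
        a = bool(c.loc["PHE day 14 vs day 1", "significant"])
        b = not bool(c.loc["ATNE day 14 vs day 1", "significant"])
        phe_sig += a
        atne_ns += b
        hits += a and b
    return {"rate": hits / n_cohorts, "phe_significant": phe_sig / n_cohorts,
            "atne_nonsignificant": atne_ns / n_cohorts, "n": n_cohorts}
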