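"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`simulate_spectrum` / :func:`simulate_csi_grid` — multivoxel PRESS-CSI
  spectra (water-suppressed + unsuppressed companion).  Peak areas are set by
  *inverting* the water-referenced quantification equation, so a perfect
  processing chain recovers the injected concentrations exactly in the
  noiseless limit.
* :func:`simulate_flair_phantom` — FLAIR-like 3D volumes: a hypointense
  hematoma ellipsoid wrapped in a hyperintense edema shell inside an
  ellipsoidal brain, with an exact label volume.
* :func:`simulate_cohort` — long-format longitudinal concentration tables
  (animal x region x day x metabolite) with animal and animal-x-region
  random effects, the design the mixed-model stage assumes.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .params import AcquisitionParams, MetaboliteSpec, WaterReference
from .quant import relaxation_factor
from .spectra import PHASE_PIVOT_PPM, Spectrum, apply_phase, complex_lorentzian

REGIONS = ("PHE", "ATNE", "CONTRA")
DAYS = (1, 7, 14)

#: Arbitrary water peak area (a.u.) for a nominal voxel; metabolite areas
#: scale relative to this through the inverted quantification equation.
WATER_AREA_AU = 1000.0


@dataclass
class GroundTruthVoxel:
    """True state of one CSI voxel: concentrations plus nuisance parameters."""

    region: str = "OTHER"
    concentrations: dict[str, float] = field(default_factory=dict)
    phase0: float = 0.0  # degrees
    phase1: float = 0.0  # degrees/ppm about the water pivot
    snr: float = math.inf  # reference-peak height / noise SD (real channel)
    water_scale: float = 1.0

    def __post_init__(self) -> None:
        for name, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {name}: {c}")
        if not self.snr > 0:
            raise ValueError("snr must be positive")


def peak_area_from_truth(cm: float, met: MetaboliteSpec, water: WaterReference,
                         acq: AcquisitionParams,
                         aw: float = WATER_AREA_AU) -> float:
    """Invert the quantification equation: the Am that encodes a given Cm."""
    return cm * aw / (relaxation_factor(met, water, acq) * water.cw)


def simulate_spectrum(truth: GroundTruthVoxel, mets: list[MetaboliteSpec],
                      water: WaterReference, acq: AcquisitionParams,
                      seed: int | np.random.Generator = 0,
                      ) -> tuple[Spectrum, Spectrum]:
    """Render one voxel's (suppressed, unsuppressed) spectrum pair.

    Each metabolite contributes a Lorentzian whose integrated absorption area
    equals ``Cm * Aw / (R * Cw)`` with R the relaxation/proton factor at the
    acquisition TR/TE; the unsuppressed companion holds the water line of
    known area.  Zero/first-order phase errors rotate both spectra; complex
    Gaussian noise is scaled so that the *reference peak* of each spectrum —
    the tallest metabolite line for the suppressed one, water for the
    companion — has height ``truth.snr`` times the noise SD.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ppm = acq.ppm_axis(center_ppm=water.ppm)
    for met in mets:
        if not (ppm.min() < met.ppm < ppm.max()):
            raise ValueError(
                f"metabolite {met.name} at {met.ppm} ppm outside the spectral "
                f"axis [{ppm.min():.2f}, {ppm.max():.2f}] ppm")

    aw = WATER_AREA_AU * truth.water_scale
    suppressed = np.zeros_like(ppm, dtype=complex)
    met_heights = [0.0]
    for met in mets:
        cm = truth.concentrations.get(met.name, 0.0)
        if cm < 0:
            raise ValueError(f"negative concentration for {met.name}")
        if cm == 0:
            continue
        am = peak_area_from_truth(cm, met, water, acq, aw=aw)
        hwhm = met.linewidth / (2.0 * acq.field_ppm_hz)
        suppressed += complex_lorentzian(ppm, met.ppm, am, 2.0 * hwhm)
        met_heights.append(am / (np.pi * hwhm))

    hwhm_w = water.linewidth / (2.0 * acq.field_ppm_hz)
    unsuppressed = complex_lorentzian(ppm, water.ppm, aw, 2.0 * hwhm_w) if aw > 0 \
        else np.zeros_like(ppm, dtype=complex)
    water_height = aw / (np.pi * hwhm_w) if aw > 0 else 0.0

    sup = apply_phase(Spectrum(suppressed, ppm, meta=acq),
                      truth.phase0, truth.phase1, pivot_ppm=PHASE_PIVOT_PPM)
    uns = apply_phase(Spectrum(unsuppressed, ppm, meta=acq),
                      truth.phase0, truth.phase1, pivot_ppm=PHASE_PIVOT_PPM)

    if math.isfinite(truth.snr):
        # One receiver, one thermal noise level for both acquisitions: the
        # SNR is quoted against the reference peak of the suppressed
        # spectrum (its tallest metabolite line; water if the voxel is
        # metabolite-free), the convention in vivo MRS reports.  The
        # unsuppressed water line then enjoys a far higher effective SNR,
        # as it does on a scanner.
        ref = max(met_heights) if max(met_heights) > 0 else water_height
        sd = ref / truth.snr
        n = ppm.size
        sup.values = sup.values + sd * (rng.standard_normal(n)
                                        + 1j * rng.standard_normal(n))
        uns.values = uns.values + sd * (rng.standard_normal(n)
                                        + 1j * rng.standard_normal(n))
    return sup, uns


@dataclass
class CSIGrid:
    """A 2D grid of spectrum pairs plus region labels and acquisition info."""

    suppressed: np.ndarray  # (rows, cols, n_points) complex
    unsuppressed: np.ndarray
    ppm_axis: np.ndarray
    acq: AcquisitionParams
    regions: np.ndarray  # (rows, cols) str
    truth: list | None = None

    def region_voxels(self) -> dict[str, tuple[int, int]]:
        """First voxel index carrying each analysis-region label."""
        out = {}
        nr, nc = self.regions.shape
        for i in range(nr):
            for j in range(nc):
                r = str(self.regions[i, j])
                if r in REGIONS and r not in out:
                    out[r] = (i, j)
        return out


def simulate_csi_grid(truth_map, mets: list[MetaboliteSpec],
                      water: WaterReference, acq: AcquisitionParams,
                      seed: int = 0) -> CSIGrid:
    """Render a full CSI grid, one independent spectrum pair per voxel."""
    truth_arr = np.asarray(truth_map, dtype=object)
    if truth_arr.shape != tuple(acq.grid_shape):
        raise ValueError(f"truth map shape {truth_arr.shape} does not match "
                         f"acquisition grid {tuple(acq.grid_shape)}")
    nr, nc = truth_arr.shape
    children = np.random.SeedSequence(seed).spawn(nr * nc)
    ppm = acq.ppm_axis(center_ppm=water.ppm)
    sup = np.zeros((nr, nc, ppm.size), dtype=complex)
    uns = np.zeros_like(sup)
    regions = np.empty((nr, nc), dtype=object)
    for i in range(nr):
        for j in range(nc):
            truth = truth_arr[i, j]
            rng = np.random.default_rng(children[i * nc + j])
            s, u = simulate_spectrum(truth, mets, water, acq, seed=rng)
            sup[i, j], uns[i, j] = s.values, u.values
            regions[i, j] = truth.region
    return CSIGrid(suppressed=sup, unsuppressed=uns, ppm_axis=ppm, acq=acq,
                   regions=regions, truth=truth_arr.tolist())


# ---------------------------------------------------------------------------
# FLAIR-like lesion phantom
# ---------------------------------------------------------------------------

LABELS = {"background": 0, "brain": 1, "edema": 2, "hematoma": 3}

DEFAULT_INTENSITIES = {"background": 0.0, "brain": 100.0,
                       "edema": 180.0, "hematoma": 30.0}


@dataclass
class PhantomSpec:
    """Concentric-ellipsoid lesion phantom: targets in ml, edges in mm."""

    voxel_mm: float = 0.5
    icv_volume: float = 70.3
    hematoma_volume: float = 1.00
    edema_volume: float = 2.38
    intensities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 0.0
    axis_ratios: tuple[float, float, float] = (1.15, 1.0, 0.87)
    lesion_axis_ratios: tuple[float, float, float] = (1.1, 1.0, 0.9)
    lesion_offset_frac: tuple[float, float, float] = (0.30, 0.25, 0.0)

    def __post_init__(self) -> None:
        if not self.hematoma_volume + self.edema_volume < self.icv_volume:
            raise ValueError("hematoma + edema must be smaller than ICV")
        ints = self.intensities
        if not (ints["edema"] > ints["brain"] > ints["hematoma"] >= ints["background"]):
            raise ValueError("need FLAIR-like ordering: edema > brain > "
                             "hematoma >= background intensity")


def ellipsoid_semi_axes(volume_ml: float, ratios: tuple[float, float, float]
                        ) -> tuple[float, float, float]:
    """Semi-axes (mm) of an ellipsoid with given volume and axis ratios."""
    volume_mm3 = volume_ml * 1000.0
    rx, ry, rz = ratios
    s = (3.0 * volume_mm3 / (4.0 * np.pi * rx * ry * rz)) ** (1.0 / 3.0)
    return (rx * s, ry * s, rz * s)


@dataclass
class PhantomResult:
    image: nib.Nifti1Image
    labels: nib.Nifti1Image
    volumes_ml: dict[str, float]  # exact label-count volumes
    spec: PhantomSpec


def simulate_flair_phantom(spec: PhantomSpec, seed: int = 0) -> PhantomResult:
    """Render the phantom as a NIfTI image/label pair.

    Voxels are assigned by centre-inclusion in three nested ellipsoids:
    brain (ICV), an edema ellipsoid whose volume is hematoma + edema, and
    the hematoma core — so edema is the shell between the last two.  Label
    volumes are exact voxel counts; the rendered volumes track the analytic
    targets to within a fraction of a voxel shell.
    """
    v = spec.voxel_mm
    icv_axes = ellipsoid_semi_axes(spec.icv_volume, spec.axis_ratios)
    outer_axes = ellipsoid_semi_axes(spec.hematoma_volume + spec.edema_volume,
                                     spec.lesion_axis_ratios)
    hem_axes = ellipsoid_semi_axes(spec.hematoma_volume, spec.lesion_axis_ratios)
    for name, target in (("hematoma", spec.hematoma_volume),
                         ("edema", spec.edema_volume),
                         ("intracranial volume", spec.icv_volume)):
        if target > 0 and target * 1000.0 / v**3 < 100:
            raise ValueError(f"{name} target {target} ml not achievable at "
                             f"{v} mm voxels (needs >= 100 voxels)")

    margin = 4.0  # mm of background around the head
    half_extent = max(icv_axes) + margin
    n = int(np.ceil(2 * half_extent / v))
    coords = (np.arange(n) + 0.5) * v - half_extent  # voxel centres, mm
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")

    def inside(cx, cy, cz, axes):
        return ((x - cx) / axes[0]) ** 2 + ((y - cy) / axes[1]) ** 2 \
            + ((z - cz) / axes[2]) ** 2 <= 1.0

    labels = np.zeros((n, n, n), dtype=np.uint8)
    labels[inside(0, 0, 0, icv_axes)] = LABELS["brain"]
    off = tuple(f * a for f, a in zip(spec.lesion_offset_frac, icv_axes))
    lesion_extent = max(outer_axes)
    if any(abs(o) + e > a for o, e, a in zip(off, (lesion_extent,) * 3, icv_axes)):
        raise ValueError("lesion does not fit inside the ICV at this offset")
    if spec.edema_volume > 0:
        labels[inside(*off, outer_axes)] = LABELS["edema"]
    labels[inside(*off, hem_axes)] = LABELS["hematoma"]

    image = np.zeros_like(labels, dtype=np.float64)
    for name, lab in LABELS.items():
        image[labels == lab] = spec.intensities[name]
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + spec.noise_sd * rng.standard_normal(image.shape)

    affine = np.diag([v, v, v, 1.0])
    vol_ml = {name: float(np.count_nonzero(labels == lab)) * v**3 / 1000.0
              for name, lab in LABELS.items() if name != "background"}
    # ICV = everything inside the brain ellipsoid, whatever the tissue class
    vol_ml["icv"] = float(np.count_nonzero(labels > 0)) * v**3 / 1000.0
    return PhantomResult(
        image=nib.Nifti1Image(image.astype(np.float32), affine),
        labels=nib.Nifti1Image(labels, affine),
        volumes_ml=vol_ml, spec=spec)


# ---------------------------------------------------------------------------
# Longitudinal cohort tables
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """Generating model for a 3-region x 3-day longitudinal cohort.

    ``region_time_means`` maps (region, day, metabolite) to the cell mean in
    mM.  Random effects are drawn independently per metabolite: an animal
    intercept (SD ``sd_animal``), an animal-x-region effect
    (``sd_animal_region``) and residual measurement noise (``sd_resid``) —
    the nested covariance the mixed-model stage assumes.
    """

    n_animals: int = 12
    days: tuple[int, ...] = DAYS
    region_time_means: dict[tuple[str, int, str], float] = field(default_factory=dict)
    sd_animal: float = 0.8
    sd_animal_region: float = 0.8
    sd_resid: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sd_animal, self.sd_animal_region, self.sd_resid) < 0:
            raise ValueError("random-effect SDs must be non-negative")
        mets = self.metabolites
        for r in self.regions:
            for d in self.days:
                for m in mets:
                    if (r, d, m) not in self.region_time_means:
                        raise ValueError(f"missing cell mean for {(r, d, m)}")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted({k[0] for k in self.region_time_means}))

    @property
    def metabolites(self) -> tuple[str, ...]:
        return tuple(sorted({k[2] for k in self.region_time_means}))


#: Cell means (mM) used as simulation ground truth.  Day-1/14 NAA and Cr
#: values are the published group means; day-7 cells and all Cho cells are
#: not printed numerically in the source and are figure-level stand-ins.
DEFAULT_COHORT_MEANS: dict[tuple[str, int, str], float] = {}
for _met, _table in {
    "NAA": {"PHE": (9.70, 11.5, 14.79), "ATNE": (9.45, 9.6, 9.99),
            "CONTRA": (13.7, 14.0, 14.5)},
    "Cr": {"PHE": (3.62, 4.5, 6.23), "ATNE": (3.46, 4.0, 5.15),
           "CONTRA": (9.43, 10.0, 10.7)},
    "Cho": {"PHE": (1.2, 1.5, 2.5), "ATNE": (1.1, 1.3, 1.4),
            "CONTRA": (2.6, 2.6, 2.7)},
}.items():
    for _region, _vals in _table.items():
        for _day, _mean in zip(DAYS, _vals):
            DEFAULT_COHORT_MEANS[(_region, _day, _met)] = _mean


def default_cohort_design(seed: int = 0, **overrides) -> CohortDesign:
    kw = dict(region_time_means=dict(DEFAULT_COHORT_MEANS), seed=seed)
    kw.update(overrides)
    return CohortDesign(**kw)


def simulate_cohort(design: CohortDesign) -> pd.DataFrame:
    """Draw one cohort table: animal, region, day, metabolite, value_mM."""
    rng = np.random.default_rng(design.seed)
    regions, mets, days = design.regions, design.metabolites, design.days
    animals = [f"A{k + 1:02d}" for k in range(design.n_animals)]
    a_eff = rng.normal(0.0, design.sd_animal, size=(design.n_animals, len(mets)))
    ar_eff = rng.normal(0.0, design.sd_animal_region,
                        size=(design.n_animals, len(regions), len(mets)))
    rows = []
    for ai, animal in enumerate(animals):
        for ri, region in enumerate(regions):
            for day in days:
                for mi, met in enumerate(mets):
                    mu = design.region_time_means[(region, day, met)]
                    value = (mu + a_eff[ai, mi] + ar_eff[ai, ri, mi]
                             + rng.normal(0.0, design.sd_resid))
                    rows.append({"animal": animal, "region": region,
                                 "day": day, "metabolite": met,
                                 "value_mM": value})
    return pd.DataFrame(rows)


#: Day means (ml) for the lesion-volume cohort: edema shrinking by 23.1% and
#: 82.7%, hematoma by 15.7% and 38.3% relative to day 1; ICV near-constant.
DEFAULT_VOLUME_MEANS = {
    "edema_ml": {1: 2.38, 7: 2.38 * (1 - 0.231), 14: 2.38 * (1 - 0.827)},
    "hematoma_ml": {1: 1.00, 7: 1.00 * (1 - 0.157), 14: 1.00 * (1 - 0.383)},
    "icv_ml": {1: 70.3, 7: 72.9, 14: 74.2},
}


def simulate_volume_cohort(n_animals: int = 12,
                           means: dict | None = None,
                           sd_animal_frac: float = 0.25,
                           sd_resid_frac: float = 0.15,
                           seed: int = 0,
                           days: tuple[int, ...] = DAYS) -> pd.DataFrame:
    """Longitudinal lesion-volume table with a per-animal random scale.

    Animal-to-animal lesion size varies multiplicatively (lognormal with
    the given fractional SD), residual measurement error is additive and
    proportional to the day mean; values are floored at zero.
    """
    means = means or DEFAULT_VOLUME_MEANS
    rng = np.random.default_rng(seed)
    outcomes = list(means)
    scale = np.exp(rng.normal(0.0, sd_animal_frac, size=(n_animals, len(outcomes))))
    rows = []
    for ai in range(n_animals):
        for day in days:
            row = {"animal": f"A{ai + 1:02d}", "day": day}
            for oi, out in enumerate(outcomes):
                mu = means[out][day]
                val = mu * scale[ai, oi] + rng.normal(0.0, sd_resid_frac * mu)
                row[out] = max(val, 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
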