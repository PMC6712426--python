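"""End-to-end orchestration: simulate -> process -> quantify -> segment -> model.

A single YAML config drives a fully deterministic run that mirrors the shape
of a serial imaging study: a cohort of animals, each with a CSI grid and a
FLAIR-like lesion volume at days 1, 7 and 14; voxel concentrations carry
animal-level random effects, lesion volumes shrink over time; the spectral
and volumetric measurements are then pushed through the same mixed-model
inference a real study would use.  Every output lands in one run directory
together with a manifest recording the config hash and QC flags.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import AcquisitionParams, default_priors
from .synthdata import (GroundTruthVoxel, PhantomSpec,
                        default_cohort_design, simulate_cohort, simulate_csi_grid,
                        simulate_flair_phantom, simulate_volume_cohort)
from .quant import quantify_grid
from .spectra import Spectrum, measure_water
from .volumetry import (SegmentationParams, compute_volumes, percent_change,
                        segment_phantom)
from .stats import fit_lmm, fit_volume_model
from . import io as pio


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    n_animals: int = 6
    snr: float = 30.0
    phase0_jitter: float = 20.0  # degrees, uniform
    grid_shape: tuple[int, int] = (3, 3)
    region_voxels: dict[str, tuple[int, int]] = field(default_factory=lambda: {
        "PHE": (0, 1), "ATNE": (1, 0), "CONTRA": (2, 2)})
    phantom_voxel_mm: float = 1.0
    seg_tolerance: float = 25.0
    seg_connectivity: int = 26
    sd_animal: float = 0.8
    sd_animal_region: float = 0.8
    sd_resid: float = 2.2

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        if "region_voxels" in raw:
            raw["region_voxels"] = {k: tuple(v) for k, v in raw["region_voxels"].items()}
        return cls(**raw)

    def acq(self) -> AcquisitionParams:
        return AcquisitionParams(grid_shape=self.grid_shape)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _paths(cfg: RunConfig) -> dict[str, Path]:
    root = pio.ensure_dir(cfg.out_dir)
    return {
        "root": root,
        "data": pio.ensure_dir(root / "data"),
        "tables": pio.ensure_dir(root / "tables"),
        "masks": pio.ensure_dir(root / "masks"),
        "figures": pio.ensure_dir(root / "figures"),
    }


def stage_simulate(cfg: RunConfig) -> dict:
    """Generate the cohort: truth tables, CSI grids and lesion phantoms."""
    p = _paths(cfg)
    priors = default_priors()
    acq = cfg.acq()
    design = default_cohort_design(seed=cfg.seed, n_animals=cfg.n_animals,
                                   sd_animal=cfg.sd_animal,
                                   sd_animal_region=cfg.sd_animal_region,
                                   sd_resid=cfg.sd_resid)
    truth = simulate_cohort(design)
    truth["value_mM"] = truth["value_mM"].clip(lower=0.0)
    truth.to_csv(p["tables"] / "cohort_truth.csv", index=False)

    rng = np.random.default_rng(cfg.seed + 1)
    nr, nc = cfg.grid_shape
    for (animal, day), sub in truth.groupby(["animal", "day"]):
        tmap = np.empty((nr, nc), dtype=object)
        for i in range(nr):
            for j in range(nc):
                tmap[i, j] = GroundTruthVoxel(region="OTHER", concentrations={},
                                              snr=cfg.snr)
        for region, (i, j) in cfg.region_voxels.items():
            conc = {row.metabolite: row.value_mM for row in
                    sub[sub.region == region].itertuples()}
            tmap[i, j] = GroundTruthVoxel(
                region=region, concentrations=conc, snr=cfg.snr,
                phase0=float(rng.uniform(-cfg.phase0_jitter, cfg.phase0_jitter)))
        grid = simulate_csi_grid(tmap, list(priors.metabolites), priors.water,
                                 acq, seed=int(rng.integers(2**31 - 1)))
        pio.save_csi(p["data"] / f"csi_{animal}_day{day:02d}.h5", grid)

    vols = simulate_volume_cohort(n_animals=cfg.n_animals, seed=cfg.seed + 2)
    vols.to_csv(p["tables"] / "volumes_truth.csv", index=False)
    for row in vols.itertuples():
        spec = PhantomSpec(voxel_mm=cfg.phantom_voxel_mm,
                           icv_volume=row.icv_ml,
                           hematoma_volume=row.hematoma_ml,
                           edema_volume=row.edema_ml)
        ph = simulate_flair_phantom(spec, seed=cfg.seed + 3)
        pio.save_nifti_pair(ph.image, ph.labels,
                            p["data"] / f"flair_{row.animal}_day{row.day:02d}.nii.gz",
                            p["data"] / f"labels_{row.animal}_day{row.day:02d}.nii.gz")
    return {"n_grids": truth.groupby(["animal", "day"]).ngroups,
            "n_phantoms": len(vols)}


def stage_quantify(cfg: RunConfig) -> dict:
    """Phase, integrate and water-reference every labelled voxel."""
    p = _paths(cfg)
    priors = default_priors()
    conc_rows, water_rows = [], []
    for path in sorted(p["data"].glob("csi_*.h5")):
        animal, day = path.stem.split("_")[1], int(path.stem.split("day")[-1])
        grid = pio.load_csi(path)
        table = quantify_grid(grid, priors, regions_only=True)
        table.insert(0, "animal", animal)
        table.insert(1, "day", day)
        conc_rows.append(table)
        for region, (i, j) in grid.region_voxels().items():
            pa = measure_water(Spectrum(grid.unsuppressed[i, j], grid.ppm_axis,
                                        meta=grid.acq))
            water_rows.append({"animal": animal, "day": day, "region": region,
                               "aw": pa.area})
    conc = pd.concat(conc_rows, ignore_index=True)
    conc.to_csv(p["tables"] / "concentrations.csv", index=False)
    water = pd.DataFrame(water_rows)
    contra = water[water.region == "CONTRA"].set_index(["animal", "day"])["aw"]
    water["ratio_vs_contra"] = [
        row.aw / contra.loc[(row.animal, row.day)] for row in water.itertuples()]
    water.to_csv(p["tables"] / "water_qc.csv", index=False)
    n_flagged = int((conc["qc_flags"].astype(str) != "").sum())
    return {"n_voxels": len(conc) // 3, "n_flagged_records": n_flagged}


def stage_segment(cfg: RunConfig) -> dict:
    """Seed-grow hematoma and edema on every phantom; summarise volumes."""
    p = _paths(cfg)
    rows = []
    leaks = 0
    for path in sorted(p["data"].glob("flair_*.nii.gz")):
        animal, day = path.stem.split("_")[1], int(path.stem.split("day")[-1].split(".")[0])
        data, zooms = pio.load_volume(path)
        lab, _ = pio.load_volume(str(path).replace("flair_", "labels_"))
        seeds = []
        for cls, code in (("hematoma", 3), ("edema", 2)):
            w = np.where(lab == code)
            if w[0].size == 0:
                continue
            # mimic the rater's click: a voxel well inside the class
            mid = len(w[0]) // 2
            seeds.append(((int(w[0][mid]), int(w[1][mid]), int(w[2][mid])), cls))
        params = SegmentationParams(seeds=seeds, tolerance=cfg.seg_tolerance,
                                    connectivity=cfg.seg_connectivity)
        masks = segment_phantom(data, params)
        for cls, res in masks.items():
            if hasattr(res, "qc_flags") and "mask_touches_border" in res.qc_flags:
                leaks += 1
        rows.append(compute_volumes(masks, zooms[0], animal=animal, day=day))
    vols = pd.DataFrame(rows)
    vols.to_csv(p["tables"] / "volumes_measured.csv", index=False)
    pct = pd.concat([percent_change(vols, c).assign(outcome=c)
                     for c in ("edema_ml", "hematoma_ml", "icv_ml")],
                    ignore_index=True)
    pct.to_csv(p["tables"] / "volume_percent_change.csv", index=False)
    return {"n_volumes": len(vols), "n_border_leaks": leaks}


def stage_model(cfg: RunConfig) -> dict:
    """Mixed models over recovered concentrations and measured volumes."""
    p = _paths(cfg)
    conc = pd.read_csv(p["tables"] / "concentrations.csv")
    conc = conc.rename(columns={"Cm_mM": "value_mM"})
    contrasts = []
    qc = {}
    for met, sub in conc.groupby("metabolite"):
        fit = fit_lmm(sub)
        tab = fit.contrasts.copy()
        tab.insert(0, "response", met)
        contrasts.append(tab)
        qc[f"lmm_{met}_converged"] = fit.converged
        qc[f"lmm_{met}_singular"] = fit.singular
    vols = pd.read_csv(p["tables"] / "volumes_measured.csv")
    for outcome in ("edema_ml", "hematoma_ml", "icv_ml"):
        fit = fit_volume_model(vols, outcome=outcome)
        tab = fit.contrasts.copy()
        tab.insert(0, "response", outcome)
        contrasts.append(tab)
        qc[f"vol_{outcome}_converged"] = fit.converged
    out = pd.concat(contrasts, ignore_index=True)
    out.to_csv(p["tables"] / "contrasts.csv", index=False)
    return qc


def stage_report(cfg: RunConfig, qc: dict) -> dict:
    """Summary figures and the run manifest."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    p = _paths(cfg)
    conc = pd.read_csv(p["tables"] / "concentrations.csv")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, met in zip(axes, ("NAA", "Cr", "Cho")):
        sub = conc[conc.metabolite == met]
        g = sub.groupby(["region", "day"])["Cm_mM"].agg(["mean", "sem"]).reset_index()
        for region, gg in g.groupby("region"):
            ax.errorbar(gg["day"], gg["mean"], yerr=gg["sem"], marker="o",
                        capsize=3, label=region)
        ax.set_title(met)
        ax.set_xlabel("day after ICH")
        ax.set_ylabel("concentration (mM)")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(p["figures"] / "metabolites_by_day.png", dpi=120)
    plt.close(fig)

    vols = pd.read_csv(p["tables"] / "volumes_measured.csv")
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.5))
    for ax, col, title in zip(axes, ("edema_ml", "hematoma_ml"),
                              ("Perihematomal edema", "Hematoma")):
        g = vols.groupby("day")[col].agg(["mean", "sem"]).reset_index()
        ax.errorbar(g["day"], g["mean"], yerr=g["sem"], marker="s", capsize=3)
        ax.set_title(title)
        ax.set_xlabel("day after ICH")
        ax.set_ylabel("volume (ml)")
    fig.tight_layout()
    fig.savefig(p["figures"] / "volumes_by_day.png", dpi=120)
    plt.close(fig)

    import scipy
    import statsmodels
    manifest = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.hash(),
        "versions": {"perispect": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__,
                     "statsmodels": statsmodels.__version__,
                     "pandas": pd.__version__},
        "qc": qc,
        "outputs": sorted(str(q.relative_to(p["root"]))
                          for q in p["root"].rglob("*") if q.is_file()
                          and q.name != "manifest.json"),
    }
    with open(p["root"] / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {"manifest": str(p["root"] / "manifest.json")}


class StageFailure(RuntimeError):
    def __init__(self, stage: str, qc: dict, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause} (qc so far: {qc})")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; abort with stage name and QC context on failure."""
    qc: dict = {}
    stages = [("simulate", stage_simulate), ("quantify", stage_quantify),
              ("segment", stage_segment), ("model", stage_model)]
    for name, fn in stages:
        try:
            qc.update({f"{name}.{k}": v for k, v in fn(config).items()})
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StageFailure(name, qc, exc) from exc
    try:
        qc.update(stage_report(config, qc))
    except Exception as exc:  # noqa: BLE001
        raise StageFailure("report", qc, exc) from exc
    return qc
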