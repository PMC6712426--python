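"""Acquisition parameters and metabolite/water relaxation priors.

The priors shipped in ``data/priors.yaml`` are literature-style 3 T values
for pig/human brain and are explicitly *stand-ins*: the acquisition they
describe (PRESS-CSI, TR/TE = 2000/144 ms) needs T1/T2 of each resonance and
of tissue water to convert peak-area ratios into millimolar concentrations,
and any site would substitute its own table.  Everything downstream treats
the table as data, never as constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

PROTON_WATER_MM = 55_510.0  # pure-water proton-pair concentration, mM


@dataclass(frozen=True)
class AcquisitionParams:
    """PRESS-CSI acquisition settings.

    Parameters
    ----------
    tr, te : float
        Repetition and echo time in ms.  Drive the saturation and T2-decay
        factors of the relaxation correction.
    bandwidth : float
        Spectral width in Hz.
    n_points : int
        Complex points per spectrum.
    field_ppm_hz : float
        Hz per ppm (≈127.74 at 3 T for protons).
    grid_shape : tuple of int
        CSI matrix (rows, cols).
    voxel_size : tuple of float
        Nominal voxel edges in mm.
    """

    tr: float = 2000.0
    te: float = 144.0
    bandwidth: float = 2000.0
    n_points: int = 2048
    field_ppm_hz: float = 127.74
    grid_shape: tuple[int, int] = (9, 9)
    voxel_size: tuple[float, float, float] = (15.0, 15.0, 15.0)

    def __post_init__(self) -> None:
        if not (self.tr > self.te > 0):
            raise ValueError(f"need tr > te > 0, got tr={self.tr}, te={self.te}")
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.n_points < 256:
            raise ValueError("n_points must be >= 256")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel edges must be positive")

    def ppm_axis(self, center_ppm: float = 4.7) -> np.ndarray:
        """Ascending ppm axis spanning the acquisition bandwidth.

        The axis is centred on the water resonance (``center_ppm``); with the
        default 2000 Hz bandwidth at 3 T it covers roughly −3.1 to 12.5 ppm,
        comfortably containing the 0–6 ppm metabolite region.
        """
        freq = np.linspace(-self.bandwidth / 2, self.bandwidth / 2,
                           self.n_points, endpoint=False)
        return center_ppm + freq / self.field_ppm_hz


@dataclass(frozen=True)
class MetaboliteSpec:
    """Per-metabolite prior: chemical shift, proton count, relaxation, width."""

    name: str
    ppm: float
    n_protons: int
    t1: float  # ms
    t2: float  # ms
    linewidth: float  # FWHM, Hz

    def __post_init__(self) -> None:
        if not (0 < self.ppm < 10):
            raise ValueError(f"{self.name}: ppm {self.ppm} outside (0, 10)")
        if self.n_protons < 1:
            raise ValueError(f"{self.name}: n_protons must be >= 1")
        if not (self.t1 > self.t2 > 0):
            raise ValueError(f"{self.name}: need t1 > t2 > 0")
        if self.linewidth <= 0:
            raise ValueError(f"{self.name}: linewidth must be positive")


@dataclass(frozen=True)
class WaterReference:
    """Tissue-water internal reference for absolute quantification.

    ``cw`` is the reference water concentration in tissue (mM):
    55 510 mM of pure water scaled by the tissue water fraction.
    """

    ppm: float = 4.7
    n_protons: int = 2
    t1: float = 1100.0
    t2: float = 80.0
    linewidth: float = 8.0
    water_fraction: float = 0.71
    cw: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_protons != 2:
            raise ValueError("water has 2 protons")
        if not (self.t1 > self.t2 > 0):
            raise ValueError("need t1 > t2 > 0 for water")
        if self.cw is None:
            object.__setattr__(self, "cw", PROTON_WATER_MM * self.water_fraction)
        if self.cw <= 0:
            raise ValueError("cw must be positive")


@dataclass(frozen=True)
class PriorTable:
    """Bundle of metabolite specs plus the water reference."""

    metabolites: tuple[MetaboliteSpec, ...]
    water: WaterReference

    def __getitem__(self, name: str) -> MetaboliteSpec:
        for met in self.metabolites:
            if met.name == name:
                return met
        raise KeyError(name)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.metabolites)


def load_priors(mapping: Mapping) -> PriorTable:
    """Build a :class:`PriorTable` from a parsed YAML mapping."""
    mets = tuple(
        MetaboliteSpec(name=name, **entry)
        for name, entry in mapping["metabolites"].items()
    )
    water = WaterReference(**mapping.get("water", {}))
    return PriorTable(metabolites=mets, water=water)


def load_priors_file(path) -> PriorTable:
    with open(path) as fh:
        return load_priors(yaml.safe_load(fh))


def default_priors() -> PriorTable:
    """The versioned default prior table shipped with the package."""
    text = resources.files("perispect").joinpath("data/priors.yaml").read_text()
    return load_priors(yaml.safe_load(text))
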