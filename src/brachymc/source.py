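"""The Ir-192 HDR source: emission spectrum and GammaMed Plus geometry.

The modelled source is the GammaMed Plus (GMP) HDR design: a 3.5 mm long,
0.6 mm diameter solid cylinder of pure iridium (the active core, with
Ir-192 distributed uniformly through it), inside an AISI 316L stainless
steel capsule of 0.9 mm outer / 0.7 mm inner diameter ending in a
truncated-cone tip, attached to a 0.9 mm diameter AISI 304 steel drive
wire modelled over its first 2 mm.

Coordinate convention (TG43): the source local frame has z along the
source long axis with the origin at the active-core centre; the capsule
tip points toward +z and the drive wire extends toward -z.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "EmissionLine",
    "PhotonSpectrum",
    "SourceGeometry",
    "load_spectrum",
    "build_gmp_source",
    "sample_decay",
]

log = logging.getLogger(__name__)

#: Physical range of the bundled Ir-192 photon lines (MeV).
ENERGY_LINE_MIN = 0.00782
ENERGY_LINE_MAX = 1.3782

#: Default source-side cut: lines below this are flagged (and dropped at
#: sampling time), matching the 10 keV transport cut.
DEFAULT_SOURCE_CUT_MEV = 0.010

BUILTIN_SPECTRA = {"ir192-nndc": "ir192_nndc.txt"}


@dataclass(frozen=True)
class EmissionLine:
    """A discrete photon emission line."""

    energy: float     #: photon energy (MeV)
    intensity: float  #: photons per decay
    below_cut: bool = False  #: flagged if under the source-side cut


@dataclass(frozen=True)
class PhotonSpectrum:
    """An ordered set of discrete emission lines."""

    lines: tuple[EmissionLine, ...]

    def __post_init__(self):
        energies = [ln.energy for ln in self.lines]
        if any(e2 <= e1 for e1, e2 in zip(energies, energies[1:])):
            raise ValueError("lines must be strictly increasing in energy")

    @property
    def energies(self) -> np.ndarray:
        return np.array([ln.energy for ln in self.lines])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([ln.intensity for ln in self.lines])

    @property
    def total_intensity(self) -> float:
        """Photons per decay, all lines (including flagged sub-cut lines)."""
        return float(self.intensities.sum())

    @property
    def mean_energy(self) -> float:
        """Intensity-weighted mean photon energy (MeV)."""
        e, i = self.energies, self.intensities
        return float((e * i).sum() / i.sum())


@dataclass(frozen=True)
class SourceGeometry:
    """Fixed GMP source dimensions (cm) and materials."""

    core_length: float = 0.35
    core_diameter: float = 0.06
    capsule_outer_diameter: float = 0.09
    capsule_inner_diameter: float = 0.07
    wire_length: float = 0.2
    wire_diameter: float = 0.09
    #: truncated-cone capsule tip height (cm); the tip detail is
    #: second-order for dose points >= 2 mm off the tip axis.
    tip_height: float = 0.05
    #: tip end radius (cm) of the cone frustum.
    tip_end_radius: float = 0.025
    core_material: str = "iridium seed"
    capsule_material: str = "316l"
    wire_material: str = "304"
    core_density: float = 22.42
    capsule_density: float = 8.03
    wire_density: float = 5.6

    @property
    def core_radius(self) -> float:
        return self.core_diameter / 2.0

    @property
    def core_half_length(self) -> float:
        return self.core_length / 2.0

    @property
    def core_volume(self) -> float:
        """Active core volume (cm^3)."""
        return math.pi * self.core_radius**2 * self.core_length

    @property
    def capsule_wall_thickness(self) -> float:
        return (self.capsule_outer_diameter - self.capsule_inner_diameter) / 2.0


def load_spectrum(
    path_or_builtin: str | Path = "ir192-nndc",
    source_cut_mev: float = DEFAULT_SOURCE_CUT_MEV,
) -> PhotonSpectrum:
    """Load a photon emission spectrum.

    ``path_or_builtin`` is either the name of a bundled spectrum
    (``"ir192-nndc"``) or a path to a two-column text table
    (energy MeV, photons per decay; '#' comments).  Lines below
    ``source_cut_mev`` are retained but flagged; the decay sampler drops
    them while still counting them toward histories.
    """
    key = str(path_or_builtin)
    if key in BUILTIN_SPECTRA:
        text = resources.files("brachymc.data").joinpath(BUILTIN_SPECTRA[key]).read_text()
    else:
        text = Path(path_or_builtin).read_text()
    lines: list[EmissionLine] = []
    for row_index, raw in enumerate(text.splitlines()):
        stripped = raw.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.replace(",", " ").split()
        if len(parts) != 2:
            raise ValueError(f"spectrum row {row_index}: expected two columns, got {raw!r}")
        try:
            energy, intensity = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ValueError(f"spectrum row {row_index}: non-numeric entry in {raw!r}") from exc
        if intensity <= 0:
            raise ValueError(f"spectrum row {row_index}: non-positive intensity {intensity}")
        if not ENERGY_LINE_MIN <= energy <= ENERGY_LINE_MAX:
            raise ValueError(
                f"spectrum row {row_index}: energy {energy} MeV outside "
                f"[{ENERGY_LINE_MIN}, {ENERGY_LINE_MAX}] MeV")
        lines.append(EmissionLine(energy, intensity, below_cut=energy < source_cut_mev))
    spectrum = PhotonSpectrum(tuple(sorted(lines, key=lambda ln: ln.energy)))
    below = sum(ln.intensity for ln in spectrum.lines if ln.below_cut)
    log.info(
        "loaded spectrum %s: %d lines, %.4f photons/decay total, "
        "%.4f photons/decay below the %g MeV source cut (flagged)",
        key, len(spectrum.lines), spectrum.total_intensity, below, source_cut_mev)
    return spectrum


def build_gmp_source(tip_height: float = 0.05) -> SourceGeometry:
    """The GammaMed Plus source geometry (fixed published dimensions)."""
    return SourceGeometry(tip_height=tip_height)


def sample_decay(spectrum: PhotonSpectrum, geometry: SourceGeometry, rng, size: int = 1):
    """Sample decay photons: position uniform in the active core,
    direction isotropic, energy by line intensity, statistical weight 1.

    Returns ``(positions (n,3) cm, directions (n,3), energies (n,) MeV,
    weights (n,))``.  Sampled energies are exact members of the line set.
    """
    gen = getattr(rng, "generator", rng)
    n = int(size)
    # position: uniform in the core cylinder
    r = geometry.core_radius * np.sqrt(gen.random(n))
    phi = 2.0 * np.pi * gen.random(n)
    z = geometry.core_length * (gen.random(n) - 0.5)
    positions = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    # direction: isotropic
    cos_t = 2.0 * gen.random(n) - 1.0
    sin_t = np.sqrt(1.0 - cos_t**2)
    psi = 2.0 * np.pi * gen.random(n)
    directions = np.column_stack([sin_t * np.cos(psi), sin_t * np.sin(psi), cos_t])
    # energy: categorical by intensity
    p = spectrum.intensities / spectrum.total_intensity
    idx = gen.choice(len(p), size=n, p=p)
    energies = spectrum.energies[idx]
    return positions, directions, energies, np.ones(n)
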