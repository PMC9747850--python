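"""Voxelized photon Monte Carlo: containers and the run driver.

Two scoring modes mirror standard practice for kerma-approximation
engines:

* ``analog`` -- interaction sites deposit the locally transferred energy
  (Compton electron energy, full photoelectric energy); the estimate is
  energy imparted per voxel mass.
* ``tle`` -- every photon flight segment credits each crossed voxel with
  ``E * (mu_en/rho)(E, material) * chord / V_voxel`` of collisional
  kerma, recorded as dose to medium under the charged-particle
  equilibrium assumption.

Photons below the energy cut (default 10 keV) are terminated with local
deposition.  Statistical uncertainty is accumulated history by history
(first and second moments of the per-history voxel score).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from ..coefficients import default_table, incoherent_coefficient, mixture_coefficient
from ..materials import Material, material_library
from ..source import PhotonSpectrum, SourceGeometry
from . import _kernels

__all__ = [
    "VoxelPhantom",
    "RunConfig",
    "DoseGrid",
    "SourcePlacement",
    "run_simulation",
    "estimate_uncertainty",
    "MAX_HISTORIES_SOFT",
    "material_energy_tables",
]

log = logging.getLogger(__name__)

#: Single-run history ceiling (soft warning): the practical per-run
#: maximum of the general-purpose MC workflows this engine mirrors;
#: shard by seed beyond it.
MAX_HISTORIES_SOFT = int(2.1e9)


@dataclass
class VoxelPhantom:
    """A regular voxel grid of material indices.

    ``origin_cm`` locates the corner of voxel (0,0,0) in the frame used
    by the source placement (conventionally the source centre frame).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    origin_cm: tuple[float, float, float]
    material_index: np.ndarray            # (nx, ny, nz) int16
    materials: list[Material]

    def __post_init__(self):
        self.material_index = np.ascontiguousarray(self.material_index, dtype=np.int16)
        if self.material_index.shape != tuple(self.shape):
            raise ValueError("material_index shape mismatch")
        if self.material_index.min() < 0 or self.material_index.max() >= len(self.materials):
            raise ValueError("material_index refers outside the material list")

    @property
    def spacing_cm(self) -> tuple[float, float, float]:
        return tuple(s / 10.0 for s in self.spacing_mm)

    @property
    def voxel_volume_cm3(self) -> float:
        sx, sy, sz = self.spacing_cm
        return sx * sy * sz

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates (cm) along one axis."""
        n = self.shape[axis]
        s = self.spacing_cm[axis]
        return self.origin_cm[axis] + (np.arange(n) + 0.5) * s

    def material_counts(self) -> dict[str, int]:
        counts = np.bincount(self.material_index.ravel(), minlength=len(self.materials))
        return {m.name: int(c) for m, c in zip(self.materials, counts)}


@dataclass(frozen=True)
class RunConfig:
    """Monte Carlo run settings."""

    n_histories: int
    seed: int
    energy_cut: float = 0.010       #: MeV; photons below are terminated locally
    scoring: str = "tle"            #: "tle" or "analog"
    primaries_only: bool = False
    woodcock: bool = False          #: delta tracking (analog mode only)
    rng_name: str = "mt19937"

    def __post_init__(self):
        if self.n_histories < 1:
            raise ValueError("n_histories must be >= 1")
        if self.scoring not in ("tle", "analog"):
            raise ValueError("scoring must be 'tle' or 'analog'")
        if self.n_histories > MAX_HISTORIES_SOFT:
            warnings.warn(
                f"n_histories {self.n_histories:.3g} exceeds the single-run "
                f"ceiling {MAX_HISTORIES_SOFT:.2g}; consider sharding", stacklevel=2)


@dataclass(frozen=True)
class SourcePlacement:
    """Where the source sits in the phantom frame.

    ``axis`` is the direction of the source long axis (+z of the source
    local frame); emission positions are sampled in the active core.
    """

    geometry: SourceGeometry
    spectrum: PhotonSpectrum
    position_cm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)


@dataclass
class DoseGrid:
    """Per-voxel dose to medium per simulated history with k=1 relative
    statistical uncertainty (NaN-flagged where no dose was scored)."""

    dose_per_history: np.ndarray
    rel_uncertainty: np.ndarray
    n_histories: int
    scoring: str
    spacing_mm: tuple[float, float, float]
    origin_cm: tuple[float, float, float]
    seed: int | None = None
    energy_accounting: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(self.dose_per_history < 0):
            raise ValueError("dose must be non-negative")


def estimate_uncertainty(sum_x: np.ndarray, sum_x2: np.ndarray, n_histories: int):
    """k=1 relative standard error of the mean from history-by-history
    first and second moments.  Entries with zero mean are NaN-flagged;
    n < 2 is rejected."""
    if n_histories < 2:
        raise ValueError("uncertainty undefined for fewer than 2 histories")
    n = float(n_histories)
    mean = sum_x / n
    var = np.maximum(sum_x2 / n - mean**2, 0.0) / (n - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt(var) / mean
    return np.where(mean > 0, rel, np.nan)


def _axis_rotation(axis) -> np.ndarray:
    """Rotation matrix mapping the source local frame (+z long axis) to
    the phantom frame with the long axis along ``axis``."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, a)
    c = float(z @ a)
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def material_energy_tables(materials: list[Material], n_grid: int = 256):
    """Per-material linear attenuation, mass energy-absorption and
    photoelectric-fraction tables on a shared log-energy grid, for the
    compiled kernels.  Voids get identically zero attenuation."""
    table = default_table()
    e_lo, e_hi = table.energies[0], table.energies[-1]
    loge = np.linspace(np.log(e_lo), np.log(e_hi), n_grid)
    e = np.exp(loge)
    nmat = len(materials)
    mu_lin = np.zeros((nmat, n_grid))
    muen_mass = np.zeros((nmat, n_grid))
    p_pe = np.zeros((nmat, n_grid))
    for i, mat in enumerate(materials):
        if mat.is_void:
            continue
        mu_mass = mixture_coefficient(mat, e, "attenuation", table)
        mu_lin[i] = mu_mass * mat.density
        muen_mass[i] = mixture_coefficient(mat, e, "energy_absorption", table)
        mu_inc = np.minimum(incoherent_coefficient(mat, e), mu_mass)
        p_pe[i] = 1.0 - mu_inc / mu_mass
    return loge[0], loge[1] - loge[0], mu_lin, muen_mass, p_pe


def run_simulation(
    phantom: VoxelPhantom,
    source: SourcePlacement,
    config: RunConfig,
) -> DoseGrid:
    """Run a voxel Monte Carlo simulation and return the dose grid.

    The source active-core centre must lie inside the phantom bounds.
    """
    pos = np.asarray(source.position_cm, dtype=float)
    lo = np.asarray(phantom.origin_cm)
    hi = lo + np.asarray(phantom.spacing_cm) * np.asarray(phantom.shape)
    if np.any(pos <= lo) or np.any(pos >= hi):
        raise ValueError("source position outside phantom bounds")
    if config.woodcock and config.scoring != "analog":
        raise ValueError("Woodcock tracking is an analog-mode option")

    loge0, dloge, mu_lin, muen_mass, p_pe = material_energy_tables(phantom.materials)
    energies = source.spectrum.energies
    intens = source.spectrum.intensities
    cdf = np.cumsum(intens) / intens.sum()
    rot = _axis_rotation(source.axis)

    nx, ny, nz = phantom.shape
    nvox = nx * ny * nz
    dose_sum = np.zeros(nvox)
    dose_sum2 = np.zeros(nvox)
    accounting = np.zeros(4)  # emitted, deposited, escaped, void-banked (MeV)

    _kernels.run_voxel_kernel(
        int(config.seed) % (2**31 - 1),
        int(config.n_histories),
        energies, cdf,
        float(source.geometry.core_radius), float(source.geometry.core_half_length),
        pos, rot,
        phantom.material_index.ravel(), nx, ny, nz,
        np.asarray(phantom.origin_cm, dtype=float),
        np.asarray(phantom.spacing_cm, dtype=float),
        loge0, dloge, mu_lin, muen_mass, p_pe,
        np.array([0.0 if m.is_void else m.density for m in phantom.materials]),
        float(config.energy_cut),
        1 if config.scoring == "tle" else 0,
        1 if config.primaries_only else 0,
        1 if config.woodcock else 0,
        dose_sum, dose_sum2, accounting,
    )

    n = config.n_histories
    vol = phantom.voxel_volume_cm3
    dens = np.array([0.0 if m.is_void else m.density
                     for m in phantom.materials])[phantom.material_index]
    # kernel accumulates per-voxel scores in MeV*cm (TLE: E*muen_mass*chord)
    # or MeV (analog energy imparted); convert to Gy per history.
    mev_to_j = 1.602176634e-13
    if config.scoring == "tle":
        conv = mev_to_j * 1.0e3 / vol  # (cm2/g -> m2/kg) x (1/cm3)
        dose = dose_sum.reshape(phantom.shape) * conv / n
        rel = estimate_uncertainty(dose_sum, dose_sum2, n).reshape(phantom.shape)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            conv = mev_to_j / (dens * vol * 1.0e-3)  # J / kg
        conv = np.where(dens > 1e-12, conv, 0.0)
        dose = dose_sum.reshape(phantom.shape) * conv / n
        rel = estimate_uncertainty(dose_sum, dose_sum2, n).reshape(phantom.shape)

    emitted, deposited, escaped, void_banked = accounting
    if void_banked > 0:
        log.warning("%.3g MeV banked in void voxels (zero-density deposition)", void_banked)
    return DoseGrid(
        dose_per_history=dose,
        rel_uncertainty=rel,
        n_histories=n,
        scoring=config.scoring,
        spacing_mm=phantom.spacing_mm,
        origin_cm=phantom.origin_cm,
        seed=config.seed,
        energy_accounting={
            "emitted_mev": float(emitted),
            "deposited_mev": float(deposited),
            "escaped_mev": float(escaped),
            "void_banked_mev": float(void_banked),
        },
    )
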