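"""Per-element photon interaction coefficient tables and mixture rules.

The bundled CSV tables (one per element, 10 keV - 1.4 MeV) hold the mass
attenuation coefficient mu/rho and the mass energy-absorption coefficient
mu_en/rho of the package's transport model (free-electron Klein-Nishina
incoherent scattering + parameterized photoelectric absorption; see
:mod:`brachymc.physics`).  They are (re)generated by
``scripts/make_coefficient_tables.py``.

Interpolation between grid points is linear in log-log space, the
standard practice for photon cross-section grids; no extrapolation is
performed outside the tabulated range.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import ATOMIC_NUMBERS, ATOMIC_WEIGHTS, N_AVOGADRO
from .materials import Material
from .physics import kn_total

__all__ = [
    "CoefficientTable",
    "load_coefficient_table",
    "mixture_coefficient",
    "interaction_probabilities",
]

ENERGY_MIN_MEV = 0.010
ENERGY_MAX_MEV = 1.40


@dataclass(frozen=True)
class CoefficientTable:
    """Element-wise mu/rho and mu_en/rho on a shared ascending energy grid."""

    energies: np.ndarray              # (n,) MeV, ascending
    mu_rho: dict[str, np.ndarray]     # element -> (n,) cm^2/g
    mu_en_rho: dict[str, np.ndarray]  # element -> (n,) cm^2/g

    def __post_init__(self):
        e = self.energies
        if np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        if e[0] > ENERGY_MIN_MEV or e[-1] < ENERGY_MAX_MEV:
            raise ValueError("energy grid must cover [0.010, 1.40] MeV")
        for el in self.mu_rho:
            if np.any(self.mu_rho[el] <= 0) or np.any(self.mu_en_rho[el] <= 0):
                raise ValueError(f"{el}: coefficients must be positive")
            if np.any(self.mu_en_rho[el] > self.mu_rho[el] * (1 + 1e-12)):
                raise ValueError(f"{el}: mu_en/rho exceeds mu/rho")

    @property
    def elements(self) -> list[str]:
        return sorted(self.mu_rho)


def load_coefficient_table(directory: str | Path | None = None) -> CoefficientTable:
    """Load per-element CSVs (``energy_mev,mu_rho,mu_en_rho``); bundled
    tables by default."""
    if directory is None:
        root = resources.files("brachymc.data").joinpath("coefficients")
        paths = sorted(p for p in root.iterdir() if p.name.endswith(".csv"))
    else:
        paths = sorted(Path(directory).glob("*.csv"))
    energies = None
    mu: dict[str, np.ndarray] = {}
    mu_en: dict[str, np.ndarray] = {}
    for p in paths:
        el = p.name.rsplit(".", 1)[0]
        with p.open("rb") as fh:
            arr = np.loadtxt(fh, delimiter=",", comments="#")
        if energies is None:
            energies = arr[:, 0]
        elif not np.allclose(arr[:, 0], energies, rtol=0, atol=0):
            raise ValueError(f"{el}: energy grid differs from shared grid")
        mu[el] = arr[:, 1]
        mu_en[el] = arr[:, 2]
    if energies is None:
        raise FileNotFoundError("no coefficient CSVs found")
    return CoefficientTable(energies=energies, mu_rho=mu, mu_en_rho=mu_en)


_table_cache: CoefficientTable | None = None


def default_table() -> CoefficientTable:
    global _table_cache
    if _table_cache is None:
        _table_cache = load_coefficient_table(None)
    return _table_cache


def _loglog_interp(e_query: np.ndarray, e_grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    return np.exp(np.interp(np.log(e_query), np.log(e_grid), np.log(values)))


def mixture_coefficient(
    material: Material,
    energy_mev,
    kind: str = "attenuation",
    table: CoefficientTable | None = None,
):
    """Mass coefficient of a mixture: ``sum_i w_i (mu/rho)_i(E)`` with
    log-log interpolation per element.

    ``kind`` is ``"attenuation"`` or ``"energy_absorption"``.  Energies
    outside the tabulated range raise; voids have no meaningful
    coefficient and are rejected (transport treats them as zero density).
    """
    if material.is_void:
        raise ValueError("void materials have no interaction coefficients; "
                         "transport bypasses them as zero density")
    if kind not in ("attenuation", "energy_absorption"):
        raise ValueError(f"unknown kind {kind!r}")
    table = table or default_table()
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    if np.any(e < table.energies[0]) or np.any(e > table.energies[-1]):
        raise ValueError(
            f"energy outside tabulated range "
            f"[{table.energies[0]:g}, {table.energies[-1]:g}] MeV")
    source = table.mu_rho if kind == "attenuation" else table.mu_en_rho
    out = np.zeros_like(e)
    for el, w in material.fractions.items():
        if w == 0.0:
            continue
        out += w * _loglog_interp(e, table.energies, source[el])
    result = out if np.ndim(energy_mev) else float(out[0])
    return result


def incoherent_coefficient(material: Material, energy_mev):
    """Free-electron Klein-Nishina incoherent mu/rho (cm^2/g) of a mixture,
    from the closed-form cross-section (no table interpolation)."""
    e = np.asarray(energy_mev, dtype=float)
    z_over_a = sum(
        w * ATOMIC_NUMBERS[el] / ATOMIC_WEIGHTS[el] for el, w in material.fractions.items()
    )
    return z_over_a * N_AVOGADRO * kn_total(e)


def interaction_probabilities(
    material: Material,
    energy_mev,
    table: CoefficientTable | None = None,
):
    """Partition of the total interaction coefficient into the incoherent
    (Compton) and absorption (photoelectric) channels.

    Returns ``(p_compton, p_photoelectric)`` summing to 1.  The Compton
    part is the closed-form Klein-Nishina coefficient, the photoelectric
    part the remainder of the tabulated total -- the same partition the
    transport kernels sample from.
    """
    mu_tot = np.asarray(mixture_coefficient(material, energy_mev, "attenuation", table))
    mu_inc = np.minimum(incoherent_coefficient(material, energy_mev), mu_tot)
    p_c = mu_inc / mu_tot
    p_pe = 1.0 - p_c
    if np.ndim(energy_mev):
        return p_c, p_pe
    return float(p_c), float(p_pe)
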