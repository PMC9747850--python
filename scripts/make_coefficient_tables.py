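"""Regenerate the bundled per-element coefficient CSVs.

Writes ``src/brachymc/data/coefficients/<El>.csv`` with columns
``energy_mev,mu_rho,mu_en_rho`` on a shared log grid 10 keV - 1.4 MeV,
with extra bracketing points at the Mo and Ir K edges.  The values are
those of the package's transport model (see brachymc.physics): exact
free-electron Klein-Nishina incoherent scattering plus the parameterized
photoelectric cross-section.
"""

from pathlib import Path

import numpy as np

from brachymc.constants import ATOMIC_NUMBERS, K_EDGES_MEV
from brachymc.physics import element_mu_en_rho, element_mu_rho

OUT = Path(__file__).resolve().parent.parent / "src" / "brachymc" / "data" / "coefficients"


def energy_grid() -> np.ndarray:
    grid = np.geomspace(0.010, 1.40, 61)
    extra = []
    for edge in K_EDGES_MEV.values():
        extra += [edge * (1 - 1e-6), edge * (1 + 1e-6)]
    return np.unique(np.concatenate([grid, extra]))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    e = energy_grid()
    for el in sorted(ATOMIC_NUMBERS):
        mu = element_mu_rho(el, e)
        mu_en = element_mu_en_rho(el, e)
        path = OUT / f"{el}.csv"
        with path.open("w") as fh:
            fh.write("# generated by scripts/make_coefficient_tables.py\n")
            fh.write(f"# element {el} (Z={ATOMIC_NUMBERS[el]}); "
                     "model: free-electron KN + parameterized photoelectric\n")
            fh.write("# energy_mev,mu_rho_cm2_g,mu_en_rho_cm2_g\n")
            for row in zip(e, mu, mu_en):
                fh.write(f"{row[0]:.6e},{row[1]:.6e},{row[2]:.6e}\n")
    print(f"wrote {len(ATOMIC_NUMBERS)} element tables with {len(e)} grid points to {OUT}")


if __name__ == "__main__":
    main()
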