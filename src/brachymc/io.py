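"""Dose-grid and profile I/O.

Native round-trip format is HDF5 (array + run metadata attributes).
External dose grids -- e.g. a treatment-planning-system export -- are
accepted as a flat binary (float64) or CSV file with a JSON sidecar
declaring ``shape``, ``spacing_mm`` and ``origin_cm``; DICOM RT-Dose is
deliberately out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .compare import Profile
from .transport.voxel import DoseGrid

__all__ = ["save_dose_grid", "load_dose_grid", "load_external_grid", "profile_to_csv"]


def save_dose_grid(grid: DoseGrid, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("dose_per_history", data=grid.dose_per_history,
                          compression="gzip")
        fh.create_dataset("rel_uncertainty", data=grid.rel_uncertainty,
                          compression="gzip")
        fh.attrs["n_histories"] = grid.n_histories
        fh.attrs["scoring"] = grid.scoring
        fh.attrs["spacing_mm"] = grid.spacing_mm
        fh.attrs["origin_cm"] = grid.origin_cm
        fh.attrs["seed"] = -1 if grid.seed is None else grid.seed
        fh.attrs["energy_accounting"] = json.dumps(grid.energy_accounting)


def load_dose_grid(path: str | Path) -> DoseGrid:
    with h5py.File(path, "r") as fh:
        seed = int(fh.attrs["seed"])
        return DoseGrid(
            dose_per_history=fh["dose_per_history"][...],
            rel_uncertainty=fh["rel_uncertainty"][...],
            n_histories=int(fh.attrs["n_histories"]),
            scoring=str(fh.attrs["scoring"]),
            spacing_mm=tuple(fh.attrs["spacing_mm"]),
            origin_cm=tuple(fh.attrs["origin_cm"]),
            seed=None if seed < 0 else seed,
            energy_accounting=json.loads(fh.attrs["energy_accounting"]),
        )


def load_external_grid(data_path: str | Path, sidecar_path: str | Path | None = None):
    """Load an externally produced 3D dose grid.

    ``data_path`` is ``.bin`` (flat float64, C order) or ``.csv``
    (flattened, one value per line); the JSON sidecar (default:
    ``data_path`` with ``.json`` suffix) declares ``shape``,
    ``spacing_mm`` and ``origin_cm``.

    Returns ``(dose array, spacing_mm, origin_cm)``.
    """
    data_path = Path(data_path)
    sidecar = Path(sidecar_path) if sidecar_path else data_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    shape = tuple(int(v) for v in meta["shape"])
    if data_path.suffix == ".csv":
        flat = np.loadtxt(data_path, delimiter=",").ravel()
    else:
        flat = np.fromfile(data_path, dtype=np.float64)
    if flat.size != int(np.prod(shape)):
        raise ValueError(f"grid size {flat.size} does not match declared shape {shape}")
    return (flat.reshape(shape), tuple(float(v) for v in meta["spacing_mm"]),
            tuple(float(v) for v in meta["origin_cm"]))


def profile_to_csv(profile: Profile, path: str | Path) -> None:
    arr = np.column_stack([profile.positions_cm, profile.dose,
                           profile.rel_uncertainty, profile.excluded])
    header = "position_cm,dose,rel_uncertainty,excluded"
    np.savetxt(path, arr, delimiter=",", header=header, comments="")
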