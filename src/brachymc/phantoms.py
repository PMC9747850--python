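"""Synthetic data: the six slab phantoms and controlled profile pairs.

The slab phantoms reproduce the published comparison geometry: five
stacked slabs -- backscatter B1 (101 mm), medium M1 (11 mm), source slab
SS (11 mm), medium M2 (11 mm), backscatter B2 (101 mm; absent in
phantom 6) -- each 101 x 101 mm laterally, voxelized at 1 mm^3, with
the source centred in the SS slab and its long axis parallel to the
x-y plane of the slab (along +x here); slabs stack along +z.  Voxel
boundaries are half-open with centres at (i + 1/2) mm, so the 101 and
11 mm thicknesses map to whole voxel counts exactly.

``generate_profile_pair`` produces reference/evaluated profile pairs
with known shift, scale and multiplicative noise, the ground truth for
exercising the gamma stage without any external dose grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .materials import Material, material_library
from .rng import RandomStream
from .source import SourceGeometry, build_gmp_source
from .tg43 import TG43Parameters, tg43_dose
from .transport._kernels import _region_of
from .transport.voxel import VoxelPhantom

__all__ = [
    "PhantomSpec",
    "SyntheticPair",
    "PHANTOM_SLABS",
    "build_slab_phantom",
    "generate_profile_pair",
    "generate_tg43_grid",
]

#: Slab materials per phantom id: (B1, M1, SS, M2, B2 or None).
PHANTOM_SLABS: dict[int, tuple[str, str, str, str, str | None]] = {
    1: ("water", "peek", "water", "air", "water"),
    2: ("water", "cartilage", "water", "bone", "water"),
    3: ("water", "titanium", "water", "lung", "water"),
    4: ("water", "adipose", "water", "muscle", "water"),
    5: ("water", "water", "stainless steel", "water", "water"),
    6: ("water", "water", "pmma", "water", None),
}

SLAB_THICKNESS_MM = (101, 11, 11, 11, 101)
LATERAL_MM = 101

#: Hardware region index -> material name (region 4 keeps the slab medium).
_HARDWARE = {0: "iridium seed", 1: "air", 2: "316l", 3: "304"}


@dataclass(frozen=True)
class PhantomSpec:
    """Declarative slab stack for one comparison phantom."""

    phantom_id: int
    slabs: tuple[str, ...]           # material names in stacking order
    thicknesses_mm: tuple[int, ...]
    lateral_mm: int = LATERAL_MM

    @property
    def extent_mm(self) -> int:
        return sum(self.thicknesses_mm)


@dataclass
class SyntheticPair:
    """A reference/evaluated profile pair with known ground truth."""

    positions_cm: np.ndarray
    reference: np.ndarray
    evaluated: np.ndarray
    shift_mm: float
    scale: float
    noise_sd: float
    seed: int | None


def phantom_spec(phantom_id: int) -> PhantomSpec:
    if phantom_id not in PHANTOM_SLABS:
        raise ValueError(f"unknown phantom id {phantom_id}; expected 1..6")
    slabs = PHANTOM_SLABS[phantom_id]
    names = tuple(s for s in slabs if s is not None)
    thick = tuple(t for s, t in zip(slabs, SLAB_THICKNESS_MM) if s is not None)
    return PhantomSpec(phantom_id=phantom_id, slabs=names, thicknesses_mm=thick)


def build_slab_phantom(
    phantom_id: int,
    carve_source: bool = True,
    geometry: SourceGeometry | None = None,
    subsamples: int = 10,
) -> VoxelPhantom:
    """Voxelize one of the six slab phantoms at 1 mm^3.

    The frame origin is the source centre: x along the source axis,
    z along the slab stack.  With ``carve_source``, the source hardware
    (core, capsule, drive wire) is carved into the SS slab by majority
    vote over ``subsamples^3`` sub-voxel points, the resolution
    compromise a 1 mm grid forces on 0.9 mm hardware.
    """
    spec = phantom_spec(phantom_id)
    geometry = geometry or build_gmp_source()
    lib = material_library()

    slab_names = list(spec.slabs)
    mat_names = list(dict.fromkeys(slab_names))  # unique, ordered
    for name in _HARDWARE.values():
        if name not in mat_names:
            mat_names.append(name)
    materials = [lib[name] for name in mat_names]
    index_of = {name: i for i, name in enumerate(mat_names)}

    nxy = spec.lateral_mm
    nz = spec.extent_mm
    grid = np.empty((nxy, nxy, nz), dtype=np.int16)
    z0 = 0
    for name, t in zip(slab_names, spec.thicknesses_mm):
        grid[:, :, z0:z0 + t] = index_of[name]
        z0 += t
    # source centre: middle of the SS slab (third slab)
    z_src_mm = SLAB_THICKNESS_MM[0] + SLAB_THICKNESS_MM[1] + SLAB_THICKNESS_MM[2] / 2.0
    origin_cm = (-nxy / 20.0, -nxy / 20.0, -z_src_mm / 10.0)

    if carve_source:
        _carve_hardware(grid, origin_cm, geometry, index_of, subsamples)
    return VoxelPhantom(
        shape=(nxy, nxy, nz), spacing_mm=(1.0, 1.0, 1.0),
        origin_cm=origin_cm, material_index=grid, materials=materials)


def _carve_hardware(grid, origin_cm, geom: SourceGeometry, index_of, subsamples):
    """Majority-vote sub-voxel material assignment around the source.

    The source local frame has its long axis along the phantom x axis.
    """
    cav_r = geom.capsule_inner_diameter / 2.0
    cav_hl = geom.core_half_length + 0.005
    cap_r = geom.capsule_outer_diameter / 2.0
    cap_ztop = cav_hl
    cap_zlo = -(cav_hl + 0.05)
    wire_r = geom.wire_diameter / 2.0
    wire_zhi = cap_zlo
    wire_zlo = cap_zlo - geom.wire_length
    # bounding box in the source frame (z axis = phantom x)
    ax_lo, ax_hi = wire_zlo, cap_ztop + geom.tip_height
    rad = cap_r
    s = subsamples
    offs = (np.arange(s) + 0.5) / s * 0.1  # cm inside a 1 mm voxel

    nx, ny, nz = grid.shape
    ix_lo = max(int((ax_lo - origin_cm[0]) * 10.0), 0)
    ix_hi = min(int((ax_hi - origin_cm[0]) * 10.0) + 1, nx)
    iy_lo = max(int((-rad - origin_cm[1]) * 10.0), 0)
    iy_hi = min(int((rad - origin_cm[1]) * 10.0) + 1, ny)
    iz_lo = max(int((-rad - origin_cm[2]) * 10.0), 0)
    iz_hi = min(int((rad - origin_cm[2]) * 10.0) + 1, nz)
    for ix in range(ix_lo, ix_hi):
        for iy in range(iy_lo, iy_hi):
            for iz in range(iz_lo, iz_hi):
                x0 = origin_cm[0] + ix * 0.1
                y0 = origin_cm[1] + iy * 0.1
                z0 = origin_cm[2] + iz * 0.1
                votes = np.zeros(5, dtype=np.int64)
                for dx in offs:
                    for dy in offs:
                        for dz in offs:
                            # source local: z_loc = phantom x, (x,y)_loc = (y,z)
                            reg = _region_of(
                                y0 + dy, z0 + dz, x0 + dx,
                                geom.core_radius, geom.core_half_length,
                                cav_r, cav_hl, cap_r, cap_zlo, cap_ztop,
                                geom.tip_height, geom.tip_end_radius,
                                wire_r, wire_zlo, wire_zhi)
                            votes[reg] += 1
                total = votes.sum()
                # a voxel mostly filled by hardware takes the dominant
                # hardware material (core/capsule/wire mixes would
                # otherwise always lose a plain plurality to the medium)
                if votes[:4].sum() * 2 >= total:
                    win = int(np.argmax(votes[:4]))
                    grid[ix, iy, iz] = index_of[_HARDWARE[win]]


def generate_profile_pair(
    shape: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    shift_mm: float = 0.0,
    scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    x_min_cm: float = -5.0,
    x_max_cm: float = 5.0,
) -> SyntheticPair:
    """A reference/evaluated pair on a 1 mm grid.

    ``reference(x) = shape(x)``; ``evaluated(x) = scale * shape(x -
    shift) * (1 + noise)`` with relative Gaussian noise of standard
    deviation ``noise_sd``.  ``shape`` must be positive on the support.
    """
    x = np.arange(x_min_cm, x_max_cm + 1e-9, 0.1)
    if callable(shape):
        ref = np.asarray(shape(x), dtype=float)
        ev = np.asarray(shape(x - shift_mm / 10.0), dtype=float)
    else:
        ref = np.asarray(shape, dtype=float)
        if shift_mm != 0.0:
            raise ValueError("array-valued shapes support shift only via a callable")
        ev = ref.copy()
    if np.any(ref <= 0):
        raise ValueError("shape must be positive on its support")
    ev = scale * ev
    if noise_sd > 0:
        rng = RandomStream(0 if seed is None else seed)
        ev = ev * (1.0 + noise_sd * rng.generator.standard_normal(ev.shape))
    return SyntheticPair(positions_cm=x, reference=ref, evaluated=ev,
                         shift_mm=shift_mm, scale=scale, noise_sd=noise_sd, seed=seed)


def generate_tg43_grid(
    params: TG43Parameters,
    s_k: float = 1.0,
    shape=(101, 101, 101),
    spacing_mm=(1.0, 1.0, 1.0),
    origin_cm=(-5.05, -5.05, -5.05),
    source_axis=(1.0, 0.0, 0.0),
    allow_edge: bool = True,
) -> np.ndarray:
    """Forward-computed TG43 dose-rate grid (cGy/h), the stand-in for an
    externally supplied dose grid in end-to-end pipeline tests.

    Positions where (r, theta) falls outside the parameter tables use
    nearest-edge values when ``allow_edge`` (the planning-system
    convention); points on the active segment are NaN.
    """
    ax = np.asarray(source_axis, float)
    ax = ax / np.linalg.norm(ax)
    centers = [origin_cm[a] + (np.arange(shape[a]) + 0.5) * spacing_mm[a] / 10.0
               for a in range(3)]
    xx, yy, zz = np.meshgrid(*centers, indexing="ij")
    pos = np.stack([xx, yy, zz], axis=-1)
    z = pos @ ax
    rho = np.linalg.norm(pos - z[..., None] * ax, axis=-1)
    r = np.sqrt(rho**2 + z**2)
    theta = np.rad2deg(np.arctan2(rho, z))
    on_segment = (rho < 1e-9) & (r <= params.active_length / 2.0)
    r_safe = np.where(on_segment | (r == 0), np.nan, r)
    dose = tg43_dose(params, s_k, r_safe.ravel(), theta.ravel(), allow_edge=allow_edge)
    return np.asarray(dose).reshape(shape)
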