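"""Transport engines: ray traversal, closed-form kerma oracles,
conservation, determinism and uncertainty scaling."""

import math

import numpy as np
import pytest

from brachymc.coefficients import mixture_coefficient
from brachymc.source import EmissionLine, PhotonSpectrum
from brachymc.transport import (
    RunConfig,
    SourcePlacement,
    VoxelPhantom,
    estimate_uncertainty,
    run_simulation,
    run_tg43_sphere,
    score_air_kerma_strength,
    trace_voxels,
)
from conftest import water_cube

MEV_TO_GY = 1.602176634e-13 * 1.0e3  # MeV * cm2/g -> Gy (per 1/cm2 fluence)


def _box_length_oracle(start, direction, lo, hi):
    """Slab-method ray/box intersection length."""
    tmin, tmax = -np.inf, np.inf
    for a in range(3):
        if abs(direction[a]) < 1e-300:
            if not (lo[a] < start[a] < hi[a]):
                return 0.0
            continue
        t1 = (lo[a] - start[a]) / direction[a]
        t2 = (hi[a] - start[a]) / direction[a]
        tmin = max(tmin, min(t1, t2))
        tmax = min(tmax, max(t1, t2))
    return max(0.0, tmax - max(tmin, 0.0))


class TestTraceVoxels:
    def test_axis_aligned_row(self, library):
        ph = water_cube(library, 10)
        chords = trace_voxels((-2.0, -0.45, -0.45), (1.0, 0.0, 0.0), ph)
        assert len(chords) == 10
        assert all(c == pytest.approx(0.1, abs=1e-12) for _, c in chords)
        assert [ijk[0] for ijk, _ in chords] == list(range(10))

    def test_diagonal_single_voxel(self, library):
        ph = VoxelPhantom(shape=(1, 1, 1), spacing_mm=(1, 1, 1),
                          origin_cm=(0, 0, 0),
                          material_index=np.zeros((1, 1, 1), np.int16),
                          materials=[library["water"]])
        d = np.array([1.0, 1.0, 0.0]) / math.sqrt(2)
        chords = trace_voxels((-0.05, -0.05, 0.05), d, ph)
        assert len(chords) == 1
        assert chords[0][1] == pytest.approx(math.sqrt(2) * 0.1, abs=1e-12)

    def test_chords_partition_box_intersection(self, library):
        ph = water_cube(library, 25)
        lo = np.array(ph.origin_cm)
        hi = lo + 2.5
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            start = rng.uniform(-4, 4, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            total = sum(c for _, c in trace_voxels(start, d, ph))
            worst = max(worst, abs(total - _box_length_oracle(start, d, lo, hi)))
        assert worst < 1e-9

    def test_missing_ray_returns_empty(self, library):
        ph = water_cube(library, 10)
        assert trace_voxels((10.0, 10.0, 10.0), (1.0, 0.0, 0.0), ph) == []


def _shell_compare(grid, phantom, mono_e, mu, muen, r_cm, half=0.15):
    """Mean MC voxel dose over a thin spherical shell vs the mean of the
    primary-kerma closed form at the same voxel centres."""
    axes = [phantom.voxel_centers(a) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    sel = np.abs(r - r_cm) < half
    exact = (mono_e * MEV_TO_GY * muen * np.exp(-mu * r[sel])
             / (4 * np.pi * r[sel] ** 2))
    return grid.dose_per_history[sel].mean(), exact.mean()


class TestVoxelEngine:
    def test_tle_primary_kerma_closed_form(self, library, mono_300kev, point_geometry):
        ph = water_cube(library, 61)
        src = SourcePlacement(point_geometry, mono_300kev, (0, 0, 0))
        grid = run_simulation(
            ph, src, RunConfig(n_histories=300_000, seed=21,
                               scoring="tle", primaries_only=True))
        mu = mixture_coefficient(library["water"], 0.3)
        muen = mixture_coefficient(library["water"], 0.3, "energy_absorption")
        for r in (1.0, 2.0):
            mc, exact = _shell_compare(grid, ph, 0.3, mu, muen, r)
            assert mc == pytest.approx(exact, rel=0.01)

    def test_same_seed_bit_identical(self, library, mono_300kev, point_geometry):
        ph = water_cube(library, 21)
        src = SourcePlacement(point_geometry, mono_300kev, (0, 0, 0))
        cfg = RunConfig(n_histories=20_000, seed=9, scoring="tle")
        a = run_simulation(ph, src, cfg)
        b = run_simulation(ph, src, cfg)
        assert np.array_equal(a.dose_per_history, b.dose_per_history)
        assert np.array_equal(a.rel_uncertainty, b.rel_uncertainty,
                              equal_nan=True)

    def test_analog_energy_conservation(self, library, spectrum, gmp):
        ph = water_cube(library, 41)
        src = SourcePlacement(gmp, spectrum, (0, 0, 0))
        grid = run_simulation(ph, src, RunConfig(n_histories=50_000, seed=13,
                                                 scoring="analog"))
        acc = grid.energy_accounting
        balance = (acc["deposited_mev"] + acc["escaped_mev"]
                   + acc["void_banked_mev"])
        assert balance == pytest.approx(acc["emitted_mev"], rel=1e-9)

    def test_void_deposition_banked(self, library, mono_300kev, point_geometry):
        ph = water_cube(library, 21)
        mats = ph.materials + [library["vacuum"]]
        idx = ph.material_index.copy()
        idx[14:, :, :] = 1  # vacuum shell on one side
        ph = VoxelPhantom(shape=ph.shape, spacing_mm=ph.spacing_mm,
                          origin_cm=ph.origin_cm, material_index=idx,
                          materials=mats)
        src = SourcePlacement(point_geometry, mono_300kev, (0, 0, 0))
        grid = run_simulation(ph, src, RunConfig(n_histories=50_000, seed=14,
                                                 scoring="analog"))
        acc = grid.energy_accounting
        assert acc["deposited_mev"] + acc["escaped_mev"] + acc["void_banked_mev"] == \
            pytest.approx(acc["emitted_mev"], rel=1e-9)
        # no dose is recorded inside the void
        assert np.all(grid.dose_per_history[14:, :, :] == 0.0)

    def test_tle_and_analog_converge(self, library, mono_300kev, point_geometry):
        ph = water_cube(library, 41)
        src = SourcePlacement(point_geometry, mono_300kev, (0, 0, 0))
        tle = run_simulation(ph, src, RunConfig(n_histories=150_000, seed=15))
        ana = run_simulation(ph, src, RunConfig(n_histories=600_000, seed=16,
                                                scoring="analog"))
        axes = [ph.voxel_centers(a) for a in range(3)]
        xx, yy, zz = np.meshgrid(*axes, indexing="ij")
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        sel = np.abs(r - 1.5) < 0.15
        m_t = tle.dose_per_history[sel].mean()
        m_a = ana.dose_per_history[sel].mean()
        se_t = m_t * np.nanmean(tle.rel_uncertainty[sel]) / math.sqrt(sel.sum())
        se_a = m_a * np.nanmean(ana.rel_uncertainty[sel]) / math.sqrt(sel.sum())
        assert abs(m_t - m_a) < 3 * math.hypot(se_t, se_a) + 0.003 * m_t

    def test_woodcock_matches_chordwise_analog(self, library, mono_300kev,
                                               point_geometry):
        ph = water_cube(library, 31)
        mats = ph.materials + [library["bone"]]
        idx = ph.material_index.copy()
        idx[:, :, 20:] = 1  # water/bone interface
        ph = VoxelPhantom(shape=ph.shape, spacing_mm=ph.spacing_mm,
                          origin_cm=ph.origin_cm, material_index=idx,
                          materials=mats)
        src = SourcePlacement(point_geometry, mono_300kev, (0, 0, 0))
        base = run_simulation(ph, src, RunConfig(n_histories=400_000, seed=17,
                                                 scoring="analog"))
        wood = run_simulation(ph, src, RunConfig(n_histories=400_000, seed=18,
                                                 scoring="analog", woodcock=True))
        sel = base.dose_per_history > np.nanpercentile(base.dose_per_history, 99)
        a = base.dose_per_history[sel].sum()
        b = wood.dose_per_history[sel].sum()
        se_a = np.sqrt(np.nansum((base.dose_per_history[sel]
                                  * base.rel_uncertainty[sel]) ** 2))
        se_b = np.sqrt(np.nansum((wood.dose_per_history[sel]
                                  * wood.rel_uncertainty[sel]) ** 2))
        assert abs(a - b) < 3 * math.hypot(se_a, se_b)

    def test_woodcock_requires_analog(self, library, mono_300kev, point_geometry):
        ph = water_cube(library, 11)
        src = SourcePlacement(point_geometry, mono_300kev, (0, 0, 0))
        with pytest.raises(ValueError, match="analog"):
            run_simulation(ph, src, RunConfig(n_histories=10, seed=1,
                                              scoring="tle", woodcock=True))

    def test_source_outside_bounds_rejected(self, library, mono_300kev,
                                            point_geometry):
        ph = water_cube(library, 11)
        src = SourcePlacement(point_geometry, mono_300kev, (9.0, 0, 0))
        with pytest.raises(ValueError, match="bounds"):
            run_simulation(ph, src, RunConfig(n_histories=10, seed=1))

    def test_history_ceiling_soft_warning(self):
        with pytest.warns(UserWarning, match="ceiling"):
            RunConfig(n_histories=int(3e9), seed=1)


class TestAirKermaStrength:
    def test_point_source_closed_form(self, library, mono_300kev, point_geometry):
        muen_air = mixture_coefficient(library["air"], 0.3, "energy_absorption")
        expected = 0.3 * MEV_TO_GY * muen_air / (4 * np.pi)
        s_k, rel = score_air_kerma_strength(mono_300kev, point_geometry,
                                            1_000_000, seed=31,
                                            march_step_cm=2e-7)
        assert s_k == pytest.approx(expected, rel=0.005)
        assert rel < 0.005

    def test_distance_independence_in_vacuo(self, mono_300kev, point_geometry):
        a, rel_a = score_air_kerma_strength(mono_300kev, point_geometry,
                                            200_000, seed=32, march_step_cm=2e-7)
        b, rel_b = score_air_kerma_strength(mono_300kev, point_geometry,
                                            200_000, seed=33, distance_cm=200.0,
                                            march_step_cm=2e-7)
        assert abs(a - b) < 2 * math.hypot(a * rel_a, b * rel_b)

    def test_inverse_square_across_decade(self, mono_300kev, point_geometry):
        vals = []
        for seed, d in ((34, 10.0), (35, 50.0), (36, 100.0)):
            s_k, rel = score_air_kerma_strength(mono_300kev, point_geometry,
                                                150_000, seed=seed, distance_cm=d,
                                                march_step_cm=2e-7)
            vals.append((s_k, s_k * rel))
        for (v1, u1), (v2, u2) in zip(vals, vals[1:]):
            assert abs(v1 - v2) < 2 * math.hypot(u1, u2)

    def test_gmp_source_strength_positive(self, spectrum, gmp):
        s_k, rel = score_air_kerma_strength(spectrum, gmp, 100_000, seed=37)
        assert s_k > 0 and np.isfinite(s_k)
        assert rel < 0.05


class TestSphereEngine:
    def test_transverse_anisotropy_suppressed_near_axis(self, spectrum, gmp):
        shell = run_tg43_sphere(spectrum, gmp, 400_000, seed=41,
                                radii_cm=(1.0,))
        j90 = int(np.argmin(np.abs(shell.theta_deg - 90.0)))
        d = shell.dose_per_history[0]
        assert d[j90] > 0
        # capsule/wire attenuation: dose near both poles well below transverse
        assert d[0] < 0.9 * d[j90]
        assert d[-1] < 0.9 * d[j90]
        # wire side (theta -> 180) more suppressed than tip side
        assert d[-1] < d[0]

    def test_same_seed_replay(self, spectrum, gmp):
        a = run_tg43_sphere(spectrum, gmp, 50_000, seed=42, radii_cm=(1.0,))
        b = run_tg43_sphere(spectrum, gmp, 50_000, seed=42, radii_cm=(1.0,))
        assert np.array_equal(a.dose_per_history, b.dose_per_history)


class TestUncertainty:
    def test_constant_scores_zero_uncertainty(self):
        n = 10_000
        s = np.array([n * 1.0])
        s2 = np.array([n * 1.0])
        assert estimate_uncertainty(s, s2, n)[0] == 0.0

    def test_bernoulli_half_standard_error(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=10_000).astype(float)
        rel = estimate_uncertainty(np.array([x.sum()]),
                                   np.array([(x**2).sum()]), x.size)[0]
        assert rel == pytest.approx(0.01, rel=0.2)

    def test_quadrupling_histories_halves_uncertainty(self, library, mono_300kev,
                                                      point_geometry):
        ph = water_cube(library, 21)
        src = SourcePlacement(point_geometry, mono_300kev, (0, 0, 0))
        small = run_simulation(ph, src, RunConfig(n_histories=25_000, seed=51))
        large = run_simulation(ph, src, RunConfig(n_histories=100_000, seed=52))
        sel = small.dose_per_history > np.nanpercentile(small.dose_per_history, 95)
        ratio = (np.nanmedian(small.rel_uncertainty[sel])
                 / np.nanmedian(large.rel_uncertainty[sel]))
        assert ratio == pytest.approx(2.0, rel=0.2)

    def test_too_few_histories_rejected(self):
        with pytest.raises(ValueError):
            estimate_uncertainty(np.array([1.0]), np.array([1.0]), 1)
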