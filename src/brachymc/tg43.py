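"""TG43U1 dose formalism for cylindrically symmetric line sources.

Implements the 2D formalism

    D(r, theta) = S_K * Lambda * [G_L(r,theta)/G_L(r0,theta0)]
                  * g_L(r) * F(r,theta)

with the line-source geometry factor ``G_L = beta / (L r sin(theta))``
(``beta`` the angle the active line subtends at the point) and its
on-axis limit ``1/(r^2 - L^2/4)``, the radial dose function ``g_L``
normalized at ``r0 = 1 cm``, and the anisotropy function ``F``
normalized at ``theta0 = 90 deg``.

Units: r in cm, theta in degrees, ``S_K`` in U (1 U = 1 uGy m^2/h =
1 cGy cm^2/h), ``Lambda`` in cGy/(h U), dose rate in cGy/h.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "TG43Parameters",
    "geometry_factor_line",
    "dose_rate_constant",
    "consensus_dose_rate_constant",
    "radial_dose_function",
    "anisotropy_function",
    "tg43_dose",
    "extract_geometry_factor",
    "CONSENSUS_DRC",
    "CONSENSUS_DRC_SOURCES",
]

R0_CM = 1.0
THETA0_DEG = 90.0

#: Published consensus dose-rate constant for the GammaMed Plus source
#: (cGy/(h U), k=1 uncertainty) and the two MC estimates it averages.
CONSENSUS_DRC = (1.117, 0.004)
CONSENSUS_DRC_SOURCES = ((1.118, 0.003), (1.115, 0.003))

_SIN_EPS = 1e-9


def geometry_factor_line(r, theta_deg, L: float):
    """Line-source geometry factor G_L(r, theta) in cm^-2.

    ``beta`` is computed as the difference of the two subtended angles
    via atan2, which is numerically stable through theta -> 0/180 where
    the expression passes smoothly into the on-axis closed form
    ``1/(r^2 - L^2/4)``.  Points on the active segment itself are a
    domain error.
    """
    r_arr = np.asarray(r, dtype=float)
    t_arr = np.asarray(theta_deg, dtype=float)
    r_b, t_b = np.broadcast_arrays(r_arr, t_arr)
    if np.any(r_b <= 0) or np.any((t_b < 0) | (t_b > 180)):
        raise ValueError("require r > 0 and 0 <= theta <= 180 deg")
    theta = np.deg2rad(t_b)
    x = r_b * np.sin(theta)          # distance off the source axis
    z = r_b * np.cos(theta)          # along the axis
    half = L / 2.0
    on_axis = np.abs(x) < _SIN_EPS
    if np.any(on_axis & (r_b <= half)):
        raise ValueError("point lies on the active line segment")
    beta = np.arctan2(x, z - half) - np.arctan2(x, z + half)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = beta / (L * r_b * np.sin(theta))
        g_axis = 1.0 / (r_b**2 - half**2)
    out = np.where(on_axis, g_axis, g)
    return float(out) if np.ndim(r) == 0 and np.ndim(theta_deg) == 0 else out


def dose_rate_constant(
    d_ref: float,
    s_k_per_history: float,
    d_ref_rel_unc: float = 0.0,
    s_k_rel_unc: float = 0.0,
    d_ref_per_history: bool = True,
    s_k_is_per_history: bool = True,
) -> tuple[float, float]:
    """Dose-rate constant Lambda = D(r0, theta0) / S_K.

    Both inputs must share the same per-history normalization; the unit
    bookkeeping (Gy/history over Gy cm^2/history) lands directly in
    cGy h^-1 U^-1 since 1 U = 1 cGy cm^2/h.  Returns ``(Lambda,
    k=1 relative uncertainty)`` with the input k=1 relative
    uncertainties combined in quadrature.
    """
    if d_ref <= 0 or s_k_per_history <= 0:
        raise ValueError("dose and air-kerma strength must be positive")
    if d_ref_per_history != s_k_is_per_history:
        raise ValueError("mismatched normalization: both inputs must be per history")
    lam = d_ref / s_k_per_history
    rel = math.hypot(d_ref_rel_unc, s_k_rel_unc)
    return lam, rel


def consensus_dose_rate_constant(
    sources: tuple[tuple[float, float], ...] = CONSENSUS_DRC_SOURCES,
) -> float:
    """The consensus DRC construction: the mean of the published MC
    estimates, rounded half-up to 3 decimals (1.118, 1.115 -> 1.117)."""
    mean = sum(Decimal(str(v)) for v, _ in sources) / len(sources)
    return float(mean.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def radial_dose_function(r_cm, transverse_doses, L: float):
    """Radial dose function g_L(r) from transverse-axis doses.

    ``g_L(r) = [D(r) G_L(r0)] / [D(r0) G_L(r)]`` at theta0 = 90 deg.
    The r grid must contain r0 = 1 cm exactly (no silent interpolation
    at the reference point); g_L(r0) = 1 exactly by construction.
    """
    r_arr = np.asarray(r_cm, dtype=float)
    d_arr = np.asarray(transverse_doses, dtype=float)
    ref_idx = np.flatnonzero(np.isclose(r_arr, R0_CM, rtol=0, atol=1e-12))
    if ref_idx.size == 0:
        raise ValueError("r grid must include the reference radius r0 = 1 cm")
    i0 = int(ref_idx[0])
    g_ref = geometry_factor_line(R0_CM, THETA0_DEG, L)
    g_r = geometry_factor_line(r_arr, np.full_like(r_arr, THETA0_DEG), L)
    g = d_arr * g_ref / (d_arr[i0] * g_r)
    g[i0] = 1.0
    return g


def anisotropy_function(r_cm, theta_deg, shell_doses, L: float):
    """Anisotropy function F(r, theta) from (r, theta) shell doses.

    ``shell_doses`` has shape (n_r, n_theta); the theta grid must
    contain theta0 = 90 deg.  F(r, theta0) = 1 exactly by construction.
    """
    r_arr = np.asarray(r_cm, dtype=float)
    t_arr = np.asarray(theta_deg, dtype=float)
    d = np.asarray(shell_doses, dtype=float)
    if d.shape != (r_arr.size, t_arr.size):
        raise ValueError("shell_doses must have shape (n_r, n_theta)")
    ref_idx = np.flatnonzero(np.isclose(t_arr, THETA0_DEG, rtol=0, atol=1e-12))
    if ref_idx.size == 0:
        raise ValueError("theta grid must include theta0 = 90 deg")
    j0 = int(ref_idx[0])
    g = geometry_factor_line(r_arr[:, None], t_arr[None, :], L)
    g0 = geometry_factor_line(r_arr, np.full_like(r_arr, THETA0_DEG), L)
    f = d * g0[:, None] / (d[:, j0][:, None] * g)
    f[:, j0] = 1.0
    return f


@dataclass
class TG43Parameters:
    """A complete TG43U1 parameter set for a line source."""

    dose_rate_constant: float          #: Lambda, cGy/(h U)
    active_length: float               #: L, cm
    g_r: np.ndarray                    #: radial grid for g_L (cm), must contain 1.0
    g_values: np.ndarray               #: g_L(r), g_L(1) == 1
    f_r: np.ndarray                    #: radial grid for F (cm)
    f_theta: np.ndarray                #: polar grid for F (deg), must contain 90
    f_values: np.ndarray               #: F(r, theta), shape (n_r, n_theta)
    drc_rel_unc: float = 0.0           #: k=1 relative uncertainty on Lambda
    r0: float = R0_CM
    theta0: float = THETA0_DEG

    def __post_init__(self):
        self.g_r = np.asarray(self.g_r, dtype=float)
        self.g_values = np.asarray(self.g_values, dtype=float)
        self.f_r = np.asarray(self.f_r, dtype=float)
        self.f_theta = np.asarray(self.f_theta, dtype=float)
        self.f_values = np.asarray(self.f_values, dtype=float)
        if self.dose_rate_constant <= 0:
            raise ValueError("Lambda must be positive")
        if np.any(self.g_values <= 0) or np.any(self.f_values <= 0):
            raise ValueError("g_L and F must be positive")
        i0 = np.flatnonzero(np.isclose(self.g_r, self.r0, rtol=0, atol=1e-12))
        if i0.size == 0 or self.g_values[int(i0[0])] != 1.0:
            raise ValueError("g_L must be tabulated with g_L(r0) = 1 exactly")
        j0 = np.flatnonzero(np.isclose(self.f_theta, self.theta0, rtol=0, atol=1e-12))
        if j0.size == 0 or np.any(self.f_values[:, int(j0[0])] != 1.0):
            raise ValueError("F must be tabulated with F(r, theta0) = 1 exactly")


def _interp_g(params: TG43Parameters, r, allow_edge: bool):
    r_arr = np.asarray(r, dtype=float)
    lo, hi = params.g_r[0], params.g_r[-1]
    if not allow_edge and (np.any(r_arr < lo) or np.any(r_arr > hi)):
        raise ValueError(f"r outside g_L table range [{lo}, {hi}] cm")
    return np.interp(np.clip(r_arr, lo, hi), params.g_r, params.g_values)


def _interp_f(params: TG43Parameters, r, theta, allow_edge: bool):
    from scipy.interpolate import RegularGridInterpolator

    r_arr = np.asarray(r, dtype=float)
    t_arr = np.asarray(theta, dtype=float)
    if not allow_edge:
        if (np.any(r_arr < params.f_r[0]) or np.any(r_arr > params.f_r[-1])
                or np.any(t_arr < params.f_theta[0]) or np.any(t_arr > params.f_theta[-1])):
            raise ValueError("(r, theta) outside F table coverage")
    interp = RegularGridInterpolator(
        (params.f_r, params.f_theta), params.f_values,
        method="linear", bounds_error=False, fill_value=None)
    r_c = np.clip(r_arr, params.f_r[0], params.f_r[-1])
    t_c = np.clip(t_arr, params.f_theta[0], params.f_theta[-1])
    pts = np.column_stack([np.ravel(r_c), np.ravel(t_c)])
    return interp(pts).reshape(np.broadcast(r_arr, t_arr).shape)


def tg43_dose(params: TG43Parameters, s_k: float, r, theta_deg, allow_edge: bool = False):
    """Forward TG43U1 dose rate (cGy/h) at (r, theta) for strength ``s_k`` (U).

    g_L is interpolated linearly in r and F bilinearly in (r, theta);
    points beyond the tables raise unless ``allow_edge`` permits
    nearest-edge evaluation.
    """
    g_ref = geometry_factor_line(params.r0, params.theta0, params.active_length)
    g_geo = geometry_factor_line(r, theta_deg, params.active_length)
    g_l = _interp_g(params, r, allow_edge)
    f = _interp_f(params, r, theta_deg, allow_edge)
    dose = s_k * params.dose_rate_constant * (np.asarray(g_geo) / g_ref) * g_l * f
    if np.ndim(r) == 0 and np.ndim(theta_deg) == 0:
        return float(dose)
    return dose


def extract_geometry_factor(
    positions_cm,
    doses,
    L: float,
    source_origin=(0.0, 0.0, 0.0),
    source_axis=(0.0, 0.0, 1.0),
):
    """Remove the line-source geometric falloff from a profile:
    each dose is multiplied by ``G_L(r0, theta0) / G_L(r, theta)``
    (the "D x G0/G" presentation).

    ``positions_cm`` is (n, 3) in the frame of the dose grid; (r, theta)
    are computed from the source pose.  Points on the active segment are
    excluded (NaN) and reported in the returned mask.

    Returns ``(adjusted_doses, multipliers, excluded_mask)``.
    """
    pos = np.atleast_2d(np.asarray(positions_cm, dtype=float)) - np.asarray(source_origin, float)
    axis = np.asarray(source_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    z = pos @ axis
    rho = np.linalg.norm(pos - np.outer(z, axis), axis=1)
    r = np.sqrt(rho**2 + z**2)
    theta = np.rad2deg(np.arctan2(rho, z))
    excluded = (rho < _SIN_EPS) & (r <= L / 2.0 + 1e-12)
    g_ref = geometry_factor_line(R0_CM, THETA0_DEG, L)
    mult = np.full(r.shape, np.nan)
    ok = ~excluded
    mult[ok] = g_ref / geometry_factor_line(r[ok], theta[ok], L)
    adjusted = np.asarray(doses, dtype=float) * mult
    return adjusted, mult, excluded
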