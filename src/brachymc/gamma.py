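"""Profile comparison: point-to-point differences and 1D gamma analysis.

The gamma index combines a dose-difference criterion (percent) and a
distance-to-agreement criterion (mm):

    gamma(x_r) = min_x sqrt[ (|x - x_r| / dta)^2
                             + ((D_e(x) - D_r(x_r)) / (dd * D_norm))^2 ]

With *local* normalization, ``D_norm`` is the reference dose at the
point being evaluated; with global normalization it is the reference
maximum.  The evaluated profile is treated as piecewise linear between
its samples, so the minimum over each segment inside the finite search
window is a closed-form quadratic minimum and the reported gamma is
exact (no dense-search discretization).  The window also caps the
maximum obtainable gamma (window = cap * dta by default, giving a cap
of 2 for the default settings), mirroring the search-limit behaviour of
the common MATLAB implementation of the test.  A point passes when
gamma <= 1; the pass rate is computed over non-excluded points (the
default exclusion removes |position| <= 0.2 cm, the region inside or
adjacent to the source where kerma-based estimates have no clinical
meaning).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = ["GammaCriteria", "GammaResult", "gamma_1d", "point_differences", "round_half_up"]


@dataclass(frozen=True)
class GammaCriteria:
    """Criteria for a 1D gamma analysis."""

    dose_crit: float = 2.0          #: dose-difference criterion, percent
    dist_crit: float = 1.0          #: distance-to-agreement criterion, mm
    normalization: str = "local"    #: "local" or "global"
    cap: float = 2.0                #: maximum obtainable gamma
    search_limit: float | None = None  #: search half-window, mm (default cap*dist_crit)
    exclusion_cm: float = 0.2       #: exclude |position| <= this bound (cm)

    def __post_init__(self):
        if self.dose_crit <= 0 or self.dist_crit <= 0:
            raise ValueError("criteria must be positive")
        if self.cap < 1:
            raise ValueError("gamma cap must be >= 1")
        if self.normalization not in ("local", "global"):
            raise ValueError("normalization must be 'local' or 'global'")

    @property
    def window_mm(self) -> float:
        return self.cap * self.dist_crit if self.search_limit is None else self.search_limit


@dataclass
class GammaResult:
    """Per-point gamma values and the pass rate over non-excluded points."""

    positions_cm: np.ndarray
    gamma: np.ndarray
    excluded: np.ndarray
    criteria: GammaCriteria

    @property
    def pass_mask(self) -> np.ndarray:
        return self.gamma <= 1.0

    @property
    def n_evaluated(self) -> int:
        return int(np.count_nonzero(~self.excluded))

    @property
    def pass_rate(self) -> float:
        """Percent of non-excluded points with gamma <= 1."""
        ok = ~self.excluded
        n = int(np.count_nonzero(ok))
        if n == 0:
            raise ValueError("no non-excluded points")
        return 100.0 * float(np.count_nonzero(self.pass_mask & ok)) / n


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal round-half-up (table formatting convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def point_differences(ref_doses, eval_doses, ref_unc=None, eval_unc=None):
    """Per-point percent difference ``100 (eval - ref) / ref``.

    Profiles must share their position grid (enforced by the caller).
    Returns ``(diff_percent, combined_rel_unc_percent)``; points with
    zero reference dose are NaN-flagged.
    """
    ref = np.asarray(ref_doses, dtype=float)
    ev = np.asarray(eval_doses, dtype=float)
    if ref.shape != ev.shape:
        raise ValueError("profiles must share a common position grid")
    with np.errstate(divide="ignore", invalid="ignore"):
        diff = 100.0 * (ev - ref) / ref
    diff = np.where(ref == 0, np.nan, diff)
    if ref_unc is None and eval_unc is None:
        return diff, None
    ru = np.zeros_like(ref) if ref_unc is None else np.asarray(ref_unc, float)
    eu = np.zeros_like(ev) if eval_unc is None else np.asarray(eval_unc, float)
    return diff, 100.0 * np.hypot(ru, eu)


def _min_gamma_sq_segment(x0_mm, d0, dn, xa, xb, da, db, dta, dd_frac):
    """Exact minimum of gamma^2 over one linear evaluated segment.

    Positions in mm; ``dd_frac = dose_crit/100 * dn`` is the absolute
    dose tolerance.  gamma^2(x) = ((x-x0)/dta)^2 + ((D(x)-d0)/dd_frac)^2
    is quadratic in x on the segment -> candidates are the two endpoints
    and the unconstrained stationary point.
    """
    if xb <= xa:
        u = (da - d0) / dd_frac
        t = (xa - x0_mm) / dta
        return t * t + u * u
    m = (db - da) / (xb - xa)
    best = 1.0e30
    for xc, dc in ((xa, da), (xb, db)):
        t = (xc - x0_mm) / dta
        u = (dc - d0) / dd_frac
        g2 = t * t + u * u
        if g2 < best:
            best = g2
    # stationary point of the quadratic
    a2 = 1.0 / (dta * dta) + (m / dd_frac) ** 2
    b1 = -x0_mm / (dta * dta) + m * (da - m * xa - d0) / (dd_frac * dd_frac)
    xs = -b1 / a2
    if xa < xs < xb:
        ds = da + m * (xs - xa)
        t = (xs - x0_mm) / dta
        u = (ds - d0) / dd_frac
        g2 = t * t + u * u
        if g2 < best:
            best = g2
    return best


def gamma_1d(
    ref_positions_cm,
    ref_doses,
    eval_positions_cm,
    eval_doses,
    criteria: GammaCriteria = GammaCriteria(),
) -> GammaResult:
    """1D gamma of an evaluated profile against a reference profile.

    The minimum is taken exactly over the piecewise-linear evaluated
    profile restricted to ``+/- window_mm`` around each reference point,
    then clipped to the cap.  Evaluated samples must be ordered in
    position.
    """
    xr = np.asarray(ref_positions_cm, dtype=float)
    dr = np.asarray(ref_doses, dtype=float)
    xe = np.asarray(eval_positions_cm, dtype=float)
    de = np.asarray(eval_doses, dtype=float)
    if xr.shape != dr.shape or xe.shape != de.shape:
        raise ValueError("positions and doses must align")
    if np.any(np.diff(xe) <= 0):
        raise ValueError("evaluated positions must be strictly increasing")
    excluded = np.abs(xr) <= criteria.exclusion_cm + 1e-12
    if np.all(excluded):
        raise ValueError("no non-excluded points to evaluate")

    xr_mm = xr * 10.0
    xe_mm = xe * 10.0
    w = criteria.window_mm
    dta = criteria.dist_crit
    if criteria.normalization == "global":
        norm_all = np.full_like(dr, dr.max())
    else:
        norm_all = dr

    gamma = np.empty(xr.shape)
    global_norm = dr.max()
    for i in range(xr.size):
        x0 = xr_mm[i]
        dn = norm_all[i]
        if dn <= 0:
            if global_norm <= 0:
                # two identically zero profiles agree trivially
                gamma[i] = 0.0
                continue
            # local normalization is undefined at a zero reference dose;
            # fall back to the global denominator for this point
            dn = global_norm
        dd_frac = criteria.dose_crit / 100.0 * dn
        lo = x0 - w
        hi = x0 + w
        j_lo = int(np.searchsorted(xe_mm, lo) - 1)
        j_hi = int(np.searchsorted(xe_mm, hi))
        best = 1.0e30
        any_seg = False
        for j in range(max(j_lo, 0), min(j_hi, xe_mm.size - 1)):
            xa = max(xe_mm[j], lo)
            xb = min(xe_mm[j + 1], hi)
            if xb < xa:
                continue
            seg = (xe_mm[j], xe_mm[j + 1], de[j], de[j + 1])
            da = np.interp(xa, [seg[0], seg[1]], [seg[2], seg[3]])
            db = np.interp(xb, [seg[0], seg[1]], [seg[2], seg[3]])
            g2 = _min_gamma_sq_segment(x0, dr[i], dn, xa, xb, da, db, dta, dd_frac)
            any_seg = True
            if g2 < best:
                best = g2
        if not any_seg:
            # window misses the evaluated support entirely; an isolated
            # evaluated sample inside the window still counts
            for j in range(xe_mm.size):
                if lo <= xe_mm[j] <= hi:
                    t = (xe_mm[j] - x0) / dta
                    u = (de[j] - dr[i]) / dd_frac
                    best = min(best, t * t + u * u)
                    any_seg = True
            if not any_seg:
                gamma[i] = criteria.cap
                continue
        gamma[i] = min(np.sqrt(best), criteria.cap)
    return GammaResult(positions_cm=xr, gamma=gamma, excluded=excluded, criteria=criteria)
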