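"""Bilinear elastic moduli from loading stress-strain curves.

Skin loaded in uniaxial extension shows two quasi-linear regimes: a compliant
initial phase (fibre uncrimping, slope E1) and a stiffer final phase (fibre
recruitment, slope E2), with E1 < E2.  The detector grows ordinary
least-squares windows from both ends of the curve and keeps the longest ones
whose coefficient of determination stays above a threshold; the moduli are
the OLS slopes of those windows (Hooke's law σ = E ε applied per phase).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, NoLinearPhaseError

__all__ = ["LoadingCurve", "BilinearFit", "detect_linear_phases", "fit_moduli"]


@dataclass(frozen=True)
class LoadingCurve:
    """Monotone loading data: engineering strain (dimensionless, non-decreasing)
    and stress (Pa).  Samples are canonicalized by a lexicographic
    (strain, stress) sort, so permutations of duplicate-strain samples map to
    the same curve."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        eps = np.asarray(self.strain, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        if eps.ndim != 1 or eps.shape != sig.shape:
            raise InvalidInputError("strain and stress must be 1-D of equal length")
        if eps.size < 8:
            raise InvalidInputError("need at least 8 samples")
        order = np.lexsort((sig, eps))
        eps, sig = eps[order], sig[order]
        if np.any(np.diff(eps) < 0):  # defensive; sort guarantees this
            raise InvalidInputError("strain must be non-decreasing")
        object.__setattr__(self, "strain", eps)
        object.__setattr__(self, "stress", sig)

    def __len__(self) -> int:
        return self.strain.size


@dataclass(frozen=True)
class BilinearFit:
    """Two-slope decomposition of a loading curve.

    ``E1``/``E2`` are the OLS slopes (Pa) of the low- and high-strain windows
    ``idx_low``/``idx_high`` (half-open index ranges); ``break_strain`` is the
    intersection of the two fitted lines, clipped strictly inside the strain
    range; ``r2_low``/``r2_high`` are the windows' coefficients of
    determination."""

    E1: float
    E2: float
    intercept1: float
    intercept2: float
    break_strain: float
    r2_low: float
    r2_high: float
    idx_low: tuple[int, int]
    idx_high: tuple[int, int]

    def __post_init__(self) -> None:
        if self.idx_low[1] > self.idx_high[0]:
            raise InvalidInputError("fitted segments must be disjoint")


def _prefix_r2(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """R² and slope of the OLS line on every prefix window [0, j), j = 1..n.

    Windows whose strain variance vanishes get R² = 1 when the stress is
    also flat (a flat line fits exactly) and -inf otherwise (vertical data
    admit no regression line)."""
    n = x.size
    j = np.arange(1, n + 1, dtype=float)
    sx, sy = np.cumsum(x), np.cumsum(y)
    sxx, syy, sxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)
    cxx = sxx - sx * sx / j
    cyy = syy - sy * sy / j
    cxy = sxy - sx * sy / j
    scale_x = np.maximum(sxx / j, 1e-300)
    scale_y = np.maximum(syy / j, 1e-300)
    degen_x = cxx <= 1e-13 * j * scale_x
    degen_y = cyy <= 1e-13 * j * scale_y
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(degen_x, 0.0, cxy / np.where(degen_x, 1.0, cxx))
        ssr = np.maximum(cyy - slope * cxy, 0.0)
        r2 = 1.0 - ssr / np.where(degen_y, 1.0, cyy)
    r2 = np.where(degen_y, 1.0, r2)
    r2 = np.where(degen_x & ~degen_y, -np.inf, r2)
    return r2, slope


def _break_from_lines(c: LoadingCurve, lo_end: int, hi_start: int) -> float:
    """Strain at which the two window lines intersect (midpoint of the strain
    range when the slopes coincide)."""
    E1, b1, _ = _ols(c.strain[:lo_end], c.stress[:lo_end])
    E2, b2, _ = _ols(c.strain[hi_start:], c.stress[hi_start:])
    smin, smax = float(c.strain[0]), float(c.strain[-1])
    if abs(E2 - E1) <= 1e-9 * max(abs(E1), abs(E2), 1e-300):
        return 0.5 * (smin + smax)
    return float(np.clip((b1 - b2) / (E2 - E1), smin, smax))


def detect_linear_phases(
    c: LoadingCurve,
    min_frac: float = 0.15,
    r2_min: float = 0.995,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Locate the two linear phases of a loading curve.

    Grows one window from the low-strain end and one from the high-strain
    end, each kept as the longest prefix/suffix achieving OLS R² >= ``r2_min``
    and covering at least ``min_frac`` of the samples (overlaps truncated at
    the overlap midpoint).  A refinement pass then intersects the two window
    lines and re-anchors the windows strictly below/above the intersection
    strain, so on an exactly bilinear curve the windows abut the break and
    the slopes are recovered exactly; a perfectly straight curve is split
    into two halves with equal slopes.

    Returns ``((lo0, lo1), (hi0, hi1))`` half-open index ranges.
    Raises :class:`NoLinearPhaseError` if either end admits no such window.
    """
    if not 0.0 < min_frac <= 0.5:
        raise InvalidInputError("min_frac must lie in (0, 0.5]")
    n = len(c)
    mlen = max(3, int(np.ceil(min_frac * n)))

    r2_lo, _ = _prefix_r2(c.strain, c.stress)
    ok = np.nonzero(r2_lo[mlen - 1:] >= r2_min)[0]
    if ok.size == 0:
        raise NoLinearPhaseError("no low-strain window reaches the R² threshold")
    lo_end = int(ok[-1]) + mlen  # longest prefix [0, lo_end)

    r2_hi, _ = _prefix_r2(c.strain[::-1], c.stress[::-1])
    ok = np.nonzero(r2_hi[mlen - 1:] >= r2_min)[0]
    if ok.size == 0:
        raise NoLinearPhaseError("no high-strain window reaches the R² threshold")
    hi_start = n - (int(ok[-1]) + mlen)  # longest suffix [hi_start, n)

    if lo_end > hi_start:  # overlap: split at the midpoint
        mid = (lo_end + hi_start) // 2
        lo_end, hi_start = mid, mid

    # refinement: re-anchor the windows at the intersection of the two
    # lines, iterated to a fixed point (at most a handful of passes)
    for _ in range(4):
        brk = _break_from_lines(c, lo_end, hi_start)
        new_lo = int(np.searchsorted(c.strain, brk, side="left"))
        new_hi = int(np.searchsorted(c.strain, brk, side="right"))
        if new_lo < 3 or n - new_hi < 3 or (new_lo, new_hi) == (lo_end, hi_start):
            break
        lo_end, hi_start = new_lo, new_hi
    return (0, lo_end), (hi_start, n)


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum(resid ** 2))
    r2 = 1.0 if sst <= 1e-13 * y.size * max(np.mean(y * y), 1e-300) \
        else 1.0 - ssr / sst
    return float(slope), float(intercept), float(min(max(r2, -np.inf), 1.0))


def fit_moduli(
    c: LoadingCurve,
    min_frac: float = 0.15,
    r2_min: float = 0.995,
) -> BilinearFit:
    """Extract E1 (initial slope) and E2 (final slope) from a loading curve.

    Intercepts are free parameters; ``break_strain`` is the strain at which
    the two fitted lines intersect (midpoint of the strain range when the
    slopes coincide, e.g. on a single straight line).
    """
    (lo0, lo1), (hi0, hi1) = detect_linear_phases(c, min_frac, r2_min)
    E1, b1, r2_low = _ols(c.strain[lo0:lo1], c.stress[lo0:lo1])
    E2, b2, r2_high = _ols(c.strain[hi0:hi1], c.stress[hi0:hi1])
    smin, smax = float(c.strain[0]), float(c.strain[-1])
    scale = max(abs(E1), abs(E2), 1e-300)
    if abs(E2 - E1) <= 1e-9 * scale:
        brk = 0.5 * (smin + smax)
    else:
        brk = (b1 - b2) / (E2 - E1)
    margin = 1e-9 * max(smax - smin, 1.0)
    brk = float(np.clip(brk, smin + margin, smax - margin))
    return BilinearFit(E1=E1, E2=E2, intercept1=b1, intercept2=b2,
                       break_strain=brk, r2_low=r2_low, r2_high=r2_high,
                       idx_low=(lo0, lo1), idx_high=(hi0, hi1))
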