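"""Generalized-Maxwell (Prony series) viscoelasticity for ramp-and-hold skin
extension tests.

The skin is modelled as a generalized Maxwell network of order one or two: an
equilibrium spring ``E0`` in parallel with branches, each a spring ``Ei`` in
series with a dashpot ``ηi``.  The relaxation modulus is a Prony series.  Two
algebraic forms are supported:

``standard``
    ``Y(t) = E0_inst * (1 - Σ p_i (1 - exp(-t/τ_i)))`` — the conventional
    relaxation function: ``Y(0)`` equals the instantaneous modulus
    ``E0_inst = E0 + Σ Ei`` and decays monotonically to the equilibrium
    modulus ``E0_inst (1 - Σ p_i) = E0``.

``as_printed``
    ``Y(t) = E0_inst * (1 - Σ p_i exp(-t/τ_i))`` — an alternative sometimes
    seen in the skin literature; it *increases* from ``E0_inst (1 - Σ p_i)``
    towards ``E0_inst``, which is not a physical relaxation modulus.  It is
    exposed for comparison but is not the default.

Stress under an arbitrary strain history follows the Boltzmann hereditary
integral ``σ(t) = Y(t) ε(0) + ∫ Y(t-ζ) dε/dζ dζ``, evaluated with a
second-order midpoint rule that is exact for step strains (see
:func:`stress_response`).

Units are SI internally (Pa, s, m); millimetre/kPa quantities are converted
at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .errors import (
    InsufficientDataError,
    InsufficientSignalError,
    InvalidGeometryError,
    InvalidInputError,
    InvalidParameterError,
)

__all__ = [
    "TestProtocol",
    "MaxwellBranches",
    "PronyRelaxation",
    "RelaxationRecord",
    "FitResult",
    "cross_section_mm2",
    "force_to_stress",
    "branches_to_prony",
    "prony_to_branches",
    "relaxation_modulus",
    "stress_response",
    "fit_relaxation",
    "fit_relaxation_per_cycle",
    "mean_prony",
]

_RAMP = "ramp"
_HOLD = "hold"


@dataclass(frozen=True)
class TestProtocol:
    """Ramp-and-hold extension protocol.

    Defaults are the in vivo forearm protocol: 1 mm/s pad speed, 20 mm
    resting gap, 20% engineering strain, 30 s hold, 3 cycles, 42 mm pad
    width and 1.2 mm effective skin thickness (surface to hypodermis).
    """

    __test__ = False  # not a test case despite the name

    pad_gap_rest_mm: float = 20.0
    pad_width_mm: float = 42.0
    skin_thickness_mm: float = 1.2
    pad_speed_mm_s: float = 1.0
    target_strain: float = 0.20
    hold_time_s: float = 30.0
    n_cycles: int = 3

    def __post_init__(self) -> None:
        for name in ("pad_gap_rest_mm", "pad_width_mm", "skin_thickness_mm",
                     "pad_speed_mm_s", "hold_time_s"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if not 0.0 < self.target_strain < 1.0:
            raise InvalidParameterError("target_strain must lie in (0, 1)")
        if self.n_cycles < 1:
            raise InvalidParameterError("n_cycles must be >= 1")

    @property
    def strain_rate(self) -> float:
        """Engineering strain rate of the ramp, 1/s."""
        return self.pad_speed_mm_s / self.pad_gap_rest_mm

    @property
    def ramp_time_s(self) -> float:
        """Duration of the loading ramp for one cycle, s."""
        return self.target_strain / self.strain_rate


@dataclass(frozen=True)
class MaxwellBranches:
    """Maxwell-network parameters: equilibrium spring ``E0`` (Pa) plus one or
    two branches ``(Ei, ηi)`` (Pa, Pa·s).  ``τi = ηi / Ei``."""

    E0: float
    branches: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise InvalidParameterError("E0 must be > 0")
        if not 0 <= len(self.branches) <= 2:
            raise InvalidParameterError("model supports at most 2 branches")
        for Ei, etai in self.branches:
            if Ei <= 0 or etai <= 0:
                raise InvalidParameterError("branch moduli and viscosities must be > 0")
        # canonical order: relaxation time ascending
        object.__setattr__(
            self, "branches",
            tuple(sorted(self.branches, key=lambda b: b[1] / b[0])),
        )

    @property
    def instantaneous_modulus(self) -> float:
        return self.E0 + sum(E for E, _ in self.branches)


@dataclass(frozen=True)
class PronyRelaxation:
    """Prony-series relaxation parameters.

    ``E0`` is the *instantaneous* modulus of the network (equilibrium spring
    plus all branch springs); ``terms`` holds ``(p_i, τ_i)`` pairs with
    ``p_i = Ei / E0`` and ``τ_i = ηi / Ei``.  ``form`` selects the algebraic
    form used by :func:`relaxation_modulus` (see module docstring).
    """

    E0: float
    terms: tuple[tuple[float, float], ...]
    form: str = "standard"

    def __post_init__(self) -> None:
        if self.E0 <= 0:
            raise InvalidParameterError("E0 must be > 0")
        if self.form not in ("standard", "as_printed"):
            raise InvalidParameterError("form must be 'standard' or 'as_printed'")
        if len(self.terms) > 2:
            raise InvalidParameterError("model supports at most 2 Prony terms")
        total = 0.0
        for p, tau in self.terms:
            if p <= 0 or tau <= 0:
                raise InvalidParameterError("Prony p_i and τ_i must be > 0")
            total += p
        if total >= 1.0:
            raise InvalidParameterError("sum of Prony weights must be < 1")
        object.__setattr__(self, "terms",
                           tuple(sorted(self.terms, key=lambda t: t[1])))

    @property
    def equilibrium_modulus(self) -> float:
        """Long-time modulus ``E0 (1 - Σ p_i)`` (standard form)."""
        return self.E0 * (1.0 - sum(p for p, _ in self.terms))


@dataclass(frozen=True)
class RelaxationRecord:
    """A sampled ramp-and-hold test record.

    ``y`` is force (N) or stress (Pa) according to ``units``; ``phase`` labels
    each sample 'ramp' or 'hold'; ``cycle`` is a 1-based cycle index;
    ``strain_history`` is the imposed engineering strain at each sample.
    """

    t: np.ndarray
    y: np.ndarray
    phase: np.ndarray
    cycle: np.ndarray
    strain_history: np.ndarray
    units: str = "Pa"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        phase = np.asarray(self.phase)
        cyc = np.asarray(self.cycle, dtype=int)
        eps = np.asarray(self.strain_history, dtype=float)
        n = t.size
        if not (y.size == phase.size == cyc.size == eps.size == n):
            raise InvalidInputError("all record columns must share one length")
        if n < 2 or np.any(np.diff(t) <= 0):
            raise InvalidInputError("time grid must be strictly increasing")
        if self.units not in ("Pa", "N"):
            raise InvalidInputError("units must be 'Pa' or 'N'")
        for c in np.unique(cyc):
            m = cyc == c
            ph = phase[m]
            # ramp must precede hold within a cycle
            if _HOLD in ph and _RAMP in ph:
                if np.argmax(ph == _HOLD) < np.argmax(ph == _RAMP):
                    raise InvalidInputError(f"cycle {c}: hold precedes ramp")
            e = eps[m]
            ramp = ph == _RAMP
            if ramp.any() and np.any(np.diff(e[ramp]) < -1e-12):
                raise InvalidInputError(f"cycle {c}: strain decreases within ramp")
            hold = ph == _HOLD
            if hold.any() and np.ptp(e[hold]) > 1e-9:
                raise InvalidInputError(f"cycle {c}: strain not constant within hold")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "phase", phase)
        object.__setattr__(self, "cycle", cyc)
        object.__setattr__(self, "strain_history", eps)

    @property
    def n_cycles(self) -> int:
        return int(self.cycle.max())

    def mask(self, cycle: int | None = None, phase: str | None = None) -> np.ndarray:
        m = np.ones(self.t.size, dtype=bool)
        if cycle is not None:
            m &= self.cycle == cycle
        if phase is not None:
            m &= self.phase == phase
        return m

    def to_stress(self, thickness_mm: float, width_mm: float) -> "RelaxationRecord":
        """Convert a force record (N) to engineering stress (Pa)."""
        if self.units == "Pa":
            return self
        return replace(self, y=force_to_stress(self.y, thickness_mm, width_mm),
                       units="Pa")


@dataclass(frozen=True)
class FitResult:
    """Outcome of a relaxation fit: parameters, RMS residual on the fitted
    window (same units as the input series), optimizer status."""

    params: PronyRelaxation
    residual_rms: float
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        if self.residual_rms < 0:
            raise InvalidParameterError("residual_rms must be >= 0")


# ---------------------------------------------------------------------------
# stress conversion


def cross_section_mm2(e_mm: float, l_mm: float) -> float:
    """Effective skin cross-section S = e·l in mm² (e: thickness, l: pad width)."""
    if e_mm <= 0 or l_mm <= 0:
        raise InvalidGeometryError("thickness and width must be > 0")
    return e_mm * l_mm


def force_to_stress(F_newton, e_mm: float, l_mm: float):
    """Engineering stress σ = F / S (Pa) from measured force (N).

    The cross-section S = e·l uses the skin thickness ``e`` recruited by the
    extension (1.2 mm down to the hypodermis by default) and the pad width
    ``l`` (42 mm), giving S = 50.4 mm² for the reference geometry.
    """
    s_m2 = cross_section_mm2(e_mm, l_mm) * 1e-6
    return np.asarray(F_newton, dtype=float) / s_m2 if np.ndim(F_newton) \
        else float(F_newton) / s_m2


# ---------------------------------------------------------------------------
# parameter conversions


def branches_to_prony(b: MaxwellBranches, form: str = "standard") -> PronyRelaxation:
    """Maxwell branch parameters → Prony parameters.

    ``p_i = Ei / (E0 + Σ Ej)`` and ``τ_i = ηi / Ei``; the Prony ``E0`` is the
    instantaneous modulus of the network.
    """
    E_inst = b.instantaneous_modulus
    terms = tuple((Ei / E_inst, etai / Ei) for Ei, etai in b.branches)
    return PronyRelaxation(E0=E_inst, terms=terms, form=form)


def prony_to_branches(p: PronyRelaxation) -> MaxwellBranches:
    """Prony parameters → Maxwell branch parameters (inverse conversion).

    ``Ei = p_i E0``, ``ηi = τ_i Ei``, equilibrium spring ``E0 (1 - Σ p_i)``.
    Round-trips with :func:`branches_to_prony` to machine precision.
    """
    total = sum(pi for pi, _ in p.terms)
    if total >= 1.0:
        raise InvalidParameterError("sum of Prony weights must be < 1")
    branches = tuple((pi * p.E0, tau * pi * p.E0) for pi, tau in p.terms)
    return MaxwellBranches(E0=p.E0 * (1.0 - total), branches=branches)


# ---------------------------------------------------------------------------
# forward model


def _coefficients(p: PronyRelaxation) -> tuple[float, np.ndarray, np.ndarray]:
    """Decompose Y(t) = c0 + Σ c_i exp(-t/τ_i) for either form."""
    ps = np.array([pi for pi, _ in p.terms], dtype=float)
    taus = np.array([tau for _, tau in p.terms], dtype=float)
    if p.form == "standard":
        return p.E0 * (1.0 - ps.sum()), p.E0 * ps, taus
    return p.E0, -p.E0 * ps, taus


def relaxation_modulus(p: PronyRelaxation, t) -> np.ndarray | float:
    """Relaxation modulus Y(t) (Pa) at times ``t`` (s, >= 0).

    Standard form: ``Y(0) = E0`` decaying to ``E0 (1 - Σ p_i)``.
    As-printed form: ``E0 (1 - Σ p_i exp(-t/τ_i))``, rising towards ``E0``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise InvalidInputError("t must be >= 0")
    c0, ci, taus = _coefficients(p)
    y = c0 + np.exp(-t_arr[..., None] / taus) @ ci if taus.size else \
        np.full_like(t_arr, c0, dtype=float) + 0.0
    return y if np.ndim(t) else float(y)


def stress_response(p: PronyRelaxation, t, strain) -> np.ndarray:
    """Hereditary-integral stress for a sampled strain history.

    Evaluates ``σ(t) = Y(t) ε(0) + Σ_j Y(t - ζ_j) Δε_j`` with strain
    increments attributed to interval midpoints (second-order accurate on
    smooth ramps, exact for a pure step).  The exponential structure of the
    Prony kernel gives an O(n) recursion per branch; on uniform grids it is
    evaluated with an IIR filter.
    """
    t = np.asarray(t, dtype=float)
    eps = np.asarray(strain, dtype=float)
    if t.ndim != 1 or t.size != eps.size:
        raise InvalidInputError("t and strain must be 1-D of equal length")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise InvalidInputError("time grid must be strictly increasing")
    c0, ci, taus = _coefficients(p)
    sigma = c0 * eps
    if taus.size == 0:
        return sigma
    # step term Y(t)·ε(0)
    sigma = sigma + (np.exp(-t[:, None] / taus) @ ci) * eps[0]
    deps = np.diff(eps)
    uniform = dt.size > 0 and np.allclose(dt, dt[0], rtol=1e-9, atol=0.0)
    for c, tau in zip(ci, taus):
        if uniform:
            a = np.exp(-dt[0] / tau)
            b = c * np.exp(-dt[0] / (2.0 * tau))
            contrib = lfilter([b], [1.0, -a], deps)
        else:
            decay = np.exp(-dt / tau)
            half = np.exp(-dt / (2.0 * tau))
            contrib = np.empty_like(deps)
            s = 0.0
            for k in range(deps.size):
                s = s * decay[k] + c * half[k] * deps[k]
                contrib[k] = s
        sigma[1:] += contrib
    return sigma


# ---------------------------------------------------------------------------
# fitting


def _pack(E0: float, ps: Sequence[float], taus: Sequence[float]) -> np.ndarray:
    s = float(np.sum(ps))
    if len(ps) == 1:
        return np.array([np.log10(E0), s, np.log10(taus[0])])
    f = ps[0] / s
    return np.array([np.log10(E0), s, f, np.log10(taus[0]), np.log10(taus[1])])


def _unpack(x: np.ndarray, n_terms: int, form: str) -> PronyRelaxation:
    E0 = 10.0 ** x[0]
    if n_terms == 1:
        terms = ((x[1], 10.0 ** x[2]),)
    else:
        s, f = x[1], x[2]
        terms = ((s * f, 10.0 ** x[3]), (s * (1.0 - f), 10.0 ** x[4]))
    return PronyRelaxation(E0=E0, terms=terms, form=form)


def _default_init(rec: RelaxationRecord, cycle: int, n_terms: int,
                  form: str) -> PronyRelaxation:
    """Deterministic, data-driven starting point.

    E0 from the within-cycle stress peak over the imposed strain, Σp from the
    peak-to-plateau drop, relaxation times log-spaced at 0.5 s and 10 s.
    """
    mc = rec.mask(cycle=cycle)
    eps0 = float(rec.strain_history[mc].max())
    if eps0 <= 0:
        raise InsufficientSignalError("no imposed strain in fitted cycle")
    y = rec.y[mc]
    peak = float(np.max(np.abs(y)))
    hold = rec.y[rec.mask(cycle=cycle, phase=_HOLD)]
    tail = hold[-max(1, hold.size // 10):]
    plateau = float(np.mean(tail)) if tail.size else 0.0
    E0 = max(peak / eps0, 1e-6)
    s = float(np.clip((peak - plateau) / peak, 0.05, 0.90)) if peak > 0 else 0.5
    if n_terms == 1:
        return PronyRelaxation(E0, ((s, np.sqrt(0.5 * 10.0)),), form)
    return PronyRelaxation(E0, ((s / 2, 0.5), (s / 2, 10.0)), form)


def fit_relaxation(
    rec: RelaxationRecord,
    init: PronyRelaxation | None = None,
    fit_window: str = "hold_only",
    cycle: int = 1,
    n_terms: int = 2,
    form: str = "standard",
    tau_bounds: tuple[float, float] = (1e-2, 1e3),
) -> FitResult:
    """Fit Prony relaxation parameters to one cycle of a record.

    Bounded nonlinear least squares over (E0, p_i, τ_i) with ``p_i > 0``,
    ``Σ p_i < 1`` enforced by construction (total-fraction/split
    parametrization) and relaxation times box-bounded; fitted terms are
    returned sorted by τ.  The model stress is the hereditary integral over
    the *full* strain history from t = 0, so earlier cycles' memory is
    accounted for; residuals are restricted to the requested window
    (``hold_only`` — the 30 s relaxation segment — or ``full_cycle``).

    Raises ``InsufficientSignalError`` for an all-zero record and
    ``InsufficientDataError`` when the window has fewer samples than free
    parameters; an optimizer that stops without meeting its own convergence
    criterion is reported via ``converged=False``, not an exception.
    """
    if fit_window not in ("hold_only", "full_cycle"):
        raise InvalidInputError("fit_window must be 'hold_only' or 'full_cycle'")
    if rec.units != "Pa":
        raise InvalidInputError("fit expects a stress record; convert with to_stress")
    if not (rec.phase == _HOLD).any():
        raise InvalidInputError("record contains no hold phase")
    if cycle < 1 or cycle > rec.n_cycles:
        raise InvalidInputError(f"cycle {cycle} not present in record")
    if init is not None:
        n_terms = len(init.terms)
        form = init.form
    if n_terms not in (1, 2):
        raise InvalidParameterError("n_terms must be 1 or 2")

    win = rec.mask(cycle=cycle, phase=_HOLD) if fit_window == "hold_only" \
        else rec.mask(cycle=cycle)
    n_free = 3 if n_terms == 1 else 5
    if win.sum() < n_free:
        raise InsufficientDataError(
            f"{int(win.sum())} samples in window < {n_free} free parameters")
    if np.allclose(rec.y[win], 0.0):
        raise InsufficientSignalError("fitted window is identically zero")

    if init is None:
        init = _default_init(rec, cycle, n_terms, form)
    # evaluate the model only up to the end of the fitted window
    kmax = int(np.nonzero(win)[0][-1]) + 1
    t = rec.t[:kmax]
    eps = rec.strain_history[:kmax]
    w = win[:kmax]
    y_obs = rec.y[:kmax][w]

    def residual(x: np.ndarray) -> np.ndarray:
        params = _unpack(x, n_terms, form)
        return stress_response(params, t, eps)[w] - y_obs

    ps0 = [pi for pi, _ in init.terms]
    taus0 = [np.clip(tau, *tau_bounds) for _, tau in init.terms]
    x0 = _pack(init.E0, ps0, taus0)
    lo_tau, hi_tau = np.log10(tau_bounds[0]), np.log10(tau_bounds[1])
    if n_terms == 1:
        lb = [-3.0, 1e-4, lo_tau]
        ub = [12.0, 0.9999, hi_tau]
    else:
        lb = [-3.0, 1e-4, 1e-4, lo_tau, lo_tau]
        ub = [12.0, 0.9999, 0.9999, hi_tau, hi_tau]
    x0 = np.clip(x0, lb, ub)
    res = least_squares(residual, x0, bounds=(lb, ub), method="trf")
    params = _unpack(res.x, n_terms, form)
    rms = float(np.sqrt(np.mean(res.fun ** 2)))
    return FitResult(params=params, residual_rms=rms,
                     converged=bool(res.success), n_iter=int(res.nfev))


def fit_relaxation_per_cycle(rec: RelaxationRecord, **kwargs) -> list[FitResult]:
    """Fit each cycle independently; see :func:`fit_relaxation`."""
    return [fit_relaxation(rec, cycle=c, **kwargs)
            for c in range(1, rec.n_cycles + 1)]


def mean_prony(results: Sequence[FitResult]) -> PronyRelaxation:
    """Average Prony parameters over per-cycle fits (terms aligned by τ rank)."""
    fits = [r.params for r in results]
    if not fits:
        raise InsufficientDataError("no fits to average")
    n_terms = len(fits[0].terms)
    if any(len(p.terms) != n_terms for p in fits):
        raise InvalidInputError("fits must share the number of Prony terms")
    E0 = float(np.mean([p.E0 for p in fits]))
    terms = tuple(
        (float(np.mean([p.terms[i][0] for p in fits])),
         float(np.mean([p.terms[i][1] for p in fits])))
        for i in range(n_terms))
    return PronyRelaxation(E0=E0, terms=terms, form=fits[0].form)
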