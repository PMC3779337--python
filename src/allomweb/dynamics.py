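"""Integration of the biomass dynamics to a stationary state.

Simulations start from the observed biomass densities B = N * M, run in
normalized time (the fastest producer has growth rate 1), and terminate
when every population has reached an equilibrium or stable oscillations.
Oscillatory states are summarized by time averages over the last detection
window.  Populations whose biomass falls below an extinction threshold are
set exactly to zero; zero is absorbing for the rest of the run.

The integrator is LSODA (stiff/non-stiff switching), run in consecutive
windows; after any window in which an extinction occurs the integration is
restarted with the reduced effective system so that the discontinuity never
crosses a solver step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import odeint

try:  # optional JIT for the vector field; pure-numpy fallback below
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

from .community import Community
from .model import (
    FixedAllometry,
    FreeParameters,
    RateSet,
    _structure,
    compute_rates,
    link_assimilation,
    normalize_time,
)

EQUILIBRIUM = "equilibrium"
OSCILLATION = "oscillation"
NOT_REACHED = "not_reached"


class SimulationError(RuntimeError):
    """The ODE solver failed; diagnostics attached."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class SimulationSettings:
    """Termination and tolerance settings for stationary-state simulation.

    extinction_threshold is far below any plausible density of a single
    individual of the smallest species per lake volume.  t_max and the
    detection window are expressed in normalized time units (generations of
    the fastest producer).  abs_tol, when None, defaults to 1e-12 times the
    smallest positive initial biomass.  oscillation_tol governs how closely
    consecutive window means must agree for a trajectory to count as stable
    oscillation; it is looser than the equilibrium tolerance because window
    means of a finite sample of a cycle carry O(period/window) error.
    """

    extinction_threshold: float = 1e-30
    t_max: float = 1e5
    window: float = 1e3
    window_points: int = 100
    rel_tol: float = 1e-8
    abs_tol: float | None = None
    stationarity_tol: float = 1e-6
    oscillation_tol: float = 1e-3

    def __post_init__(self) -> None:
        for name in ("extinction_threshold", "t_max", "window", "window_points",
                     "rel_tol", "stationarity_tol", "oscillation_tol"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        if self.abs_tol is not None and not (self.abs_tol > 0):
            raise ValueError("abs_tol must be positive")
        if self.window_points < 4:
            raise ValueError("window_points must be at least 4")

    @classmethod
    def fitting_profile(cls) -> "SimulationSettings":
        """Settings for optimization campaigns, where thousands of
        simulations run inside the objective: shorter horizon, coarser
        solver tolerance, and an extinction threshold still many decades
        below any plausible equilibrium biomass but reached quickly by
        doomed populations."""
        return cls(t_max=2e4, window=2000, window_points=30,
                   stationarity_tol=1e-5, rel_tol=1e-6,
                   extinction_threshold=1e-14)


@dataclass(frozen=True)
class SimulationResult:
    """Stationary biomasses and bookkeeping for one simulation."""

    B_sim: np.ndarray            # kg m^-3; time averages if oscillatory
    N_sim: np.ndarray            # individuals m^-3, B_sim / M exactly
    persisting: np.ndarray       # boolean, B_sim > 0
    stationary_kind: str         # equilibrium | oscillation | not_reached
    elapsed_model_time: float    # normalized time units
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class StationaryCheck:
    kind: str                    # equilibrium | oscillation | none
    mean: np.ndarray             # time-average over the inspected window


def apply_extinction(B: np.ndarray, threshold: float) -> np.ndarray:
    """Zero every entry below the threshold.  Idempotent."""
    if not (threshold > 0):
        raise ValueError("threshold must be positive")
    B = np.asarray(B, dtype=float)
    return np.where(B < threshold, 0.0, B)


def detect_stationary(
    times: np.ndarray,
    trajectory: np.ndarray,
    settings: SimulationSettings,
    previous_mean: np.ndarray | None = None,
) -> StationaryCheck:
    """Classify a window of trajectory samples.

    ``trajectory`` has one row per time sample.  Equilibrium: every species'
    relative change across the window is below stationarity_tol.
    Oscillation: the window mean agrees with the previous window's mean
    within oscillation_tol while within-window variation exceeds the
    equilibrium tolerance.  Otherwise none (still transient).
    """
    times = np.asarray(times, dtype=float)
    trajectory = np.asarray(trajectory, dtype=float)
    if times.size < 4 or trajectory.shape[0] != times.size:
        raise ValueError("window too short: need >= 4 aligned time samples")
    span = times[-1] - times[0]
    if span < settings.window * (1 - 1e-9):
        raise ValueError(
            f"window covers {span} time units; settings.window is {settings.window}"
        )
    hi = trajectory.max(axis=0)
    lo = trajectory.min(axis=0)
    scale = np.maximum(hi, 1e-300)
    rel_change = (hi - lo) / scale
    mean = np.trapezoid(trajectory, times, axis=0) / span
    if np.all(rel_change < settings.stationarity_tol):
        return StationaryCheck(EQUILIBRIUM, mean)
    if previous_mean is not None:
        mscale = np.maximum(np.maximum(np.abs(mean), np.abs(previous_mean)), 1e-300)
        means_agree = np.all(np.abs(mean - previous_mean) / mscale
                             < settings.oscillation_tol)
        if means_agree:
            return StationaryCheck(OSCILLATION, mean)
    return StationaryCheck("none", mean)


def _rhs_core_numpy(B, alive, res_idx, con_idx, e, J, r, T, prod_mask,
                    K, expo, Wpow, d, f_e):
    n = B.shape[0]
    Bc = np.maximum(B, 0.0) * alive
    Bpow = Bc ** expo
    S = np.bincount(con_idx, weights=Bpow[res_idx], minlength=n)
    denom = Wpow * (1.0 + d * Bc[con_idx]) + S[con_idx]
    JF = J * (Bpow[res_idx] / denom)
    gain = Bc * np.bincount(con_idx, weights=e * JF, minlength=n)
    loss = np.bincount(res_idx, weights=Bc[con_idx] * JF, minlength=n) / f_e
    G = 1.0 - (Bc * prod_mask).sum() / K
    return (r * G * Bc - T * Bc + gain - loss) * alive


if _HAVE_NUMBA:

    @_njit(cache=True, fastmath=False)
    def _rhs_core_jit(B, alive, res_idx, con_idx, e, J, r, T, prod_mask,
                      K, expo, Wpow, d, f_e):  # pragma: no cover - numba
        n = B.shape[0]
        m = res_idx.shape[0]
        Bc = np.empty(n)
        prod_total = 0.0
        for i in range(n):
            b = B[i]
            if b < 0.0:
                b = 0.0
            b *= alive[i]
            Bc[i] = b
            if prod_mask[i] > 0.0:
                prod_total += b
        Bpow = np.empty(n)
        for i in range(n):
            Bpow[i] = Bc[i] ** expo
        S = np.zeros(n)
        for k in range(m):
            S[con_idx[k]] += Bpow[res_idx[k]]
        gain = np.zeros(n)
        loss = np.zeros(n)
        for k in range(m):
            j = con_idx[k]
            denom = Wpow * (1.0 + d * Bc[j]) + S[j]
            JF = J[k] * (Bpow[res_idx[k]] / denom)
            gain[j] += e[k] * JF
            loss[res_idx[k]] += Bc[j] * JF
        G = 1.0 - prod_total / K
        out = np.empty(n)
        for i in range(n):
            out[i] = (r[i] * G * Bc[i] - T[i] * Bc[i] + Bc[i] * gain[i]
                      - loss[i] / f_e) * alive[i]
        return out

    _rhs_core = _rhs_core_jit
else:  # pragma: no cover
    _rhs_core = _rhs_core_numpy


def _rhs_factory(c: Community, rs: RateSet, fixed: FixedAllometry,
                 free: FreeParameters):
    """Bind community structure and rates into a flat-argument vector field."""
    s = _structure(c)
    res_idx = np.ascontiguousarray(s.res_idx)
    con_idx = np.ascontiguousarray(s.con_idx)
    prod_mask = s.producer_mask.astype(float)
    e = link_assimilation(c, fixed)
    r, T, J = rs.r, rs.T, rs.J
    K, q, W, d, f_e = free.K, free.q, free.W, free.d, fixed.f_e
    expo = 1.0 + q
    Wpow = W ** expo

    def rhs(t, B, alive):
        return _rhs_core(B, alive, res_idx, con_idx, e, J, r, T, prod_mask,
                         K, expo, Wpow, d, f_e)

    return rhs


def simulate_to_stationary(
    c: Community,
    fixed: FixedAllometry,
    free: FreeParameters,
    settings: SimulationSettings | None = None,
    B0: np.ndarray | None = None,
    rates: RateSet | None = None,
    kernels: dict[str, np.ndarray] | None = None,
) -> SimulationResult:
    """Integrate the normalized system until stationary (or t_max).

    The community must be preprocessed (no unconsumed producers) so that
    every consumer has at least one resource.  The initial state defaults to
    the observed biomasses N_data * M.  ``rates`` may supply precomputed
    (raw or normalized) rates; ``kernels`` passes through to compute_rates
    for randomization studies.
    """
    settings = settings or SimulationSettings()
    problems = c.validate()
    if problems:
        raise ValueError("community is not simulation-ready: " + "; ".join(problems))
    if rates is None:
        rates = compute_rates(c, fixed, free, kernels=kernels)
    if rates.time_unit == "raw":
        rates = normalize_time(rates, c)

    masses = c.masses
    B = (c.observed_densities * masses if B0 is None
         else np.asarray(B0, dtype=float).copy())
    if B.shape != (c.n_species,):
        raise ValueError("initial state has wrong length")

    positive = B[B > 0]
    abs_tol = (settings.abs_tol if settings.abs_tol is not None
               else 1e-12 * (positive.min() if positive.size else 1.0))
    rhs = _rhs_factory(c, rates, fixed, free)
    alive = (B >= settings.extinction_threshold).astype(float)
    B = B * alive

    t = 0.0
    prev_mean = None
    kind = NOT_REACHED
    B_stat = B.copy()
    extinction_times: dict[str, float] = {}
    n_chunks = 0
    n_steps = 0

    while t < settings.t_max * (1 - 1e-12):
        t_end = min(t + settings.window, settings.t_max)
        t_eval = np.linspace(t, t_end, settings.window_points)
        traj, info = odeint(
            rhs, B, t_eval, args=(alive,), tfirst=True,
            rtol=settings.rel_tol, atol=abs_tol,
            mxstep=500_000, full_output=True, printmessg=False,
        )
        n_chunks += 1
        n_steps += int(info["nst"][-1])
        if info["message"] != "Integration successful.":
            raise SimulationError(
                f"LSODA failed at t={t}: {info['message']}",
                {"t": t, "n_chunks": n_chunks, "message": info["message"]},
            )
        B = np.maximum(traj[-1], 0.0) * alive
        t = t_end

        newly_extinct = (alive > 0) & (B < settings.extinction_threshold)
        if newly_extinct.any():
            for i in np.flatnonzero(newly_extinct):
                extinction_times[c.ids[i]] = t
            alive = alive * (~newly_extinct)
            B = B * alive
            prev_mean = None  # restart detection on the reduced system
            B_stat = B.copy()
            continue

        check = detect_stationary(t_eval, traj * alive, settings, prev_mean)
        if check.kind == EQUILIBRIUM:
            kind = EQUILIBRIUM
            B_stat = B.copy()
            break
        if check.kind == OSCILLATION:
            kind = OSCILLATION
            B_stat = np.maximum(check.mean, 0.0) * alive
            break
        prev_mean = check.mean
        B_stat = B.copy()

    B_stat = apply_extinction(B_stat, settings.extinction_threshold)
    return SimulationResult(
        B_sim=B_stat,
        N_sim=B_stat / masses,
        persisting=B_stat > 0,
        stationary_kind=kind,
        elapsed_model_time=t,
        diagnostics={
            "n_chunks": n_chunks,
            "n_solver_samples": n_steps,
            "extinction_times": extinction_times,
            "normalization_constant": rates.normalization_constant,
        },
    )
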