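"""Three-compartment model of lipid-flux-driven periodic adipocyte recruitment.

Adipocytes occupy small, medium and large compartments with cell numbers
``N_s, N_m, N_l``.  PPAR signalling ``P`` (dimensionless, in [0, 1]) is
switched on whenever the lipid flux needing storage ``L`` exceeds the
available uptake capacity ``U = u * N_m`` of medium cells, and decays
otherwise; its maximal rate of rise equals its decay rate ``delta``:

    dP/dt   = delta * (theta(L - U) - P),      theta(0) = 1
    dN_s/dt = r * P - g * N_s
    dN_m/dt = g * N_s - k * L * N_m
    dN_l/dt = k * L * N_m

Recruitment of new small cells is driven by ``P``; small cells mature at
rate ``g``; medium cells fill with lipid and leave for the large compartment
at a rate proportional to the flux ``L``.  The delayed negative feedback
(recruitment -> maturation -> restored capacity -> PPAR off) makes the system
a relaxation oscillator: recruitment comes in periodic waves, and the period
shortens as the lipid flux grows.

This realization follows the verbal structure of the published description;
the equation bodies themselves are the package's own concrete choice (see
docs/methods.md), so its default parameters claim qualitative behaviour
only, not any particular printed period.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "OdeParams",
    "OdeTrajectory",
    "derivatives",
    "simulate",
    "estimate_period",
    "period_vs_flux",
]


@dataclass(frozen=True)
class OdeParams:
    """Rate constants; units in terms of grams of lipid, days and cell-number units."""

    L: float = 1.0          # lipid flux needing storage, g/day
    delta: float = 0.2      # PPAR decay (= maximal rise) rate, /day
    r: float = 1.0          # recruitment rate, cell-number units/day per unit P
    g: float = 0.08         # small -> medium maturation rate, /day
    u: float = 0.12         # uptake capacity per medium cell, g/day per cell-number unit
    k: float = 0.03         # medium -> large rate constant per unit flux, /(g day)
    heaviside_epsilon: float = 0.0  # smoothing width of the switch, in units of L; 0 = sharp

    def __post_init__(self) -> None:
        for name in ("L", "r", "g", "u", "k", "heaviside_epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.delta <= 0:
            raise ValueError("delta must be positive")


@dataclass
class OdeTrajectory:
    times: np.ndarray
    P: np.ndarray
    N_s: np.ndarray
    N_m: np.ndarray
    N_l: np.ndarray

    def variable(self, name: str) -> np.ndarray:
        if name not in ("P", "N_s", "N_m", "N_l"):
            raise ValueError(f"unknown variable {name!r}")
        return getattr(self, name)

    @property
    def total_cells(self) -> np.ndarray:
        return self.N_s + self.N_m + self.N_l


def _theta(x: float, eps: float) -> float:
    """Heaviside switch with theta(0) = 1; logistic smoothing when eps > 0."""
    if eps > 0:
        return 1.0 / (1.0 + np.exp(-x / eps))
    return 1.0 if x >= 0 else 0.0


def derivatives(state, params: OdeParams) -> np.ndarray:
    """Right-hand side at ``state = (P, N_s, N_m, N_l)``."""
    P, N_s, N_m, N_l = state
    if min(P, N_s, N_m, N_l) < 0:
        raise ValueError(f"negative state {state}")
    drive = _theta(params.L - params.u * N_m, params.heaviside_epsilon * params.L)
    return np.array(
        [
            params.delta * (drive - P),
            params.r * P - params.g * N_s,
            params.g * N_s - params.k * params.L * N_m,
            params.k * params.L * N_m,
        ]
    )


def _rk4_step(state: np.ndarray, dt: float, params: OdeParams) -> np.ndarray:
    k1 = derivatives(state, params)
    k2 = derivatives(np.maximum(state + 0.5 * dt * k1, 0.0), params)
    k3 = derivatives(np.maximum(state + 0.5 * dt * k2, 0.0), params)
    k4 = derivatives(np.maximum(state + dt * k3, 0.0), params)
    return state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate(
    params: OdeParams,
    initial_state=(0.0, 0.0, 0.0, 0.0),
    t_end: float = 400.0,
    dt: float = 0.01,
) -> OdeTrajectory:
    """Fixed-step fourth-order integration, deterministic by construction.

    With a sharp switch (``heaviside_epsilon = 0``) the crossing of
    ``L - U = 0`` inside a step is localized by bisection to 1e-8 relative
    tolerance and the step is split there, so the discontinuous right-hand
    side is never integrated across.
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    state = np.asarray(initial_state, dtype=float)
    if state.size != 4 or np.any(state < 0):
        raise ValueError("initial state must be four non-negative values")
    n_steps = int(round(t_end / dt))
    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    out = np.empty((n_steps + 1, 4))
    out[0] = state
    sharp = params.heaviside_epsilon == 0

    def switch_arg(s: np.ndarray) -> float:
        return params.L - params.u * s[2]

    for i in range(n_steps):
        nxt = _rk4_step(state, dt, params)
        if sharp and switch_arg(state) * switch_arg(nxt) < 0:
            # locate the switching time inside the step by bisection on the
            # step fraction, then integrate the two sub-steps separately
            lo, hi = 0.0, 1.0
            while hi - lo > 1e-8:
                mid = 0.5 * (lo + hi)
                s_mid = _rk4_step(state, mid * dt, params)
                if switch_arg(state) * switch_arg(s_mid) < 0:
                    hi = mid
                else:
                    lo = mid
            s_cross = _rk4_step(state, hi * dt, params)
            nxt = _rk4_step(s_cross, (1.0 - hi) * dt, params)
        if np.any(nxt < -1e-9):
            raise RuntimeError(
                f"state turned negative at t={times[i + 1]:.3f}: {nxt}; reduce dt"
            )
        state = np.maximum(nxt, 0.0)
        out[i + 1] = state
    return OdeTrajectory(times=times, P=out[:, 0], N_s=out[:, 1], N_m=out[:, 2],
                         N_l=out[:, 3])


class NoPeriodError(RuntimeError):
    """Raised when a trajectory has too few oscillation peaks to define a period."""


def estimate_period(trajectory: OdeTrajectory, variable: str = "N_s",
                    transient_fraction: float = 0.25) -> float:
    """Mean inter-peak interval of one variable after discarding the transient.

    Peaks are local maxima above the post-transient median, separated by at
    least one day; fewer than three peaks raises :class:`NoPeriodError`.
    """
    y = trajectory.variable(variable)
    t = trajectory.times
    start = int(len(t) * transient_fraction)
    y, t = y[start:], t[start:]
    if len(t) < 3:
        raise NoPeriodError("trajectory too short")
    dt = t[1] - t[0]
    min_dist = max(int(round(1.0 / dt)), 1)
    peaks, _ = find_peaks(y, height=float(np.median(y)), distance=min_dist)
    if len(peaks) < 3:
        raise NoPeriodError(f"only {len(peaks)} peaks found in {variable}")
    return float(np.mean(np.diff(t[peaks])))


def period_vs_flux(params: OdeParams, L_values, t_end: float = 400.0,
                   dt: float = 0.01, variable: str = "N_s") -> list[tuple[float, float]]:
    """Oscillation period per lipid-flux value; non-oscillatory fluxes are omitted."""
    L_values = list(L_values)
    out = []
    for L in L_values:
        try:
            traj = simulate(replace(params, L=float(L)), t_end=t_end, dt=dt)
            out.append((float(L), estimate_period(traj, variable=variable)))
        except NoPeriodError:
            continue
    return out
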