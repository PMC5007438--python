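"""Turbidostat inner loop, growth-rate estimation and the MetE growth plant.

The turbidostat holds optical density constant: biomass obeys
``dx/dt = mu x - (u_flow / V) x`` and an inner PI loop on the OD error
drives the influx pump, so at regulation equilibrium the dilution rate
``u_flow / V`` equals the growth rate ``mu``.  The outer loop therefore
reads the growth rate off the pump signal: a causal exponential moving
average (5-min time constant by default) of the ~1 Hz pump samples divided
by the culture volume, downsampled to the 1-min controller update.

The growth plant abstracts MetE-limited growth in methionine-dropout
medium: ``mu`` relaxes first-order (time constant ~45 min) toward a
Hill-shaped steady-state map of the green-light fraction, spanning about
0.0035 per min under full red (doubling time ~200 min) to 0.0139 per min
under full green (~50 min).  An optional drift term slowly raises the
red-light floor after prolonged growth-repressive illumination, emulating
the gradual loss of light sensitivity of the strain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TurbidostatState",
    "GrowthPlantState",
    "GrowthSignal",
    "turbidostat_step",
    "estimate_growth_rate",
    "doubling_time",
    "growth_plant_step",
    "mu_steady_state",
]

MU_FULL_GREEN = 0.0139  # min^-1, doubling ~50 min
MU_FULL_RED = 0.0035    # min^-1, doubling ~200 min


def doubling_time(mu: float) -> float:
    """T_d = ln 2 / mu for exponential growth; undefined for mu <= 0."""
    if mu <= 0:
        raise ValueError("doubling time undefined for non-positive growth rate")
    return math.log(2.0) / mu


# ---------------------------------------------------------------------------
# turbidostat inner loop
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TurbidostatState:
    """Biomass (OD units), constant culture volume and the inner PI state.

    Default gains place the closed inner loop's settling time at a couple of
    minutes, well below the hours-scale growth dynamics.
    """

    x: float = 0.1              # OD600
    V: float = 17.5             # ml
    setpoint: float = 0.1
    u_flow: float = 0.0         # ml / min
    integral: float = 0.0
    K_P: float = 1400.0         # ml/min per OD unit of error
    K_I: float = 2800.0         # ml/min per (OD*min)

    def __post_init__(self) -> None:
        if self.x <= 0 or self.V <= 0 or self.setpoint <= 0:
            raise ValueError("biomass, volume and setpoint must be positive")
        if self.u_flow < 0:
            raise ValueError("influx rate must be >= 0")


def turbidostat_step(state: TurbidostatState, mu: float, dt: float,
                     od_noise_sd: float = 0.0,
                     rng: np.random.Generator | None = None
                     ) -> TurbidostatState:
    """Advance biomass and the inner turbidity PI by ``dt`` minutes.

    ``dt`` must be small against the inner-loop time constant (~1 min);
    the 1 Hz pump update corresponds to dt = 1/60.
    """
    if dt <= 0 or dt > 0.5:
        raise ValueError("dt must be positive and small (minutes)")
    od = state.x
    if od_noise_sd > 0:
        if rng is None:
            raise ValueError("rng required for OD sensor noise")
        od = max(od + od_noise_sd * rng.standard_normal(), 0.0)
    e = od - state.setpoint          # too dense -> dilute harder
    integral = state.integral + e * dt
    u_flow = state.K_P * e + state.K_I * integral
    if u_flow < 0:
        u_flow = 0.0
        integral = state.integral    # freeze integral at the actuator floor
    x = state.x + dt * state.x * (mu - u_flow / state.V)
    return replace(state, x=max(x, 1e-9), u_flow=u_flow, integral=integral)


# ---------------------------------------------------------------------------
# growth-rate estimation from the pump signal
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthSignal:
    """Causal EMA filter state over the raw pump signal (~1 Hz samples)."""

    filtered_flow: float = 0.0
    tau_min: float = 5.0
    dt_min: float = 1.0 / 60.0
    initialized: bool = False

    @property
    def alpha(self) -> float:
        return self.dt_min / (self.tau_min + self.dt_min)


def estimate_growth_rate(signal: GrowthSignal, raw_flow: float, V: float
                         ) -> tuple[float, GrowthSignal]:
    """Filter one raw pump sample; returns (mu_hat, new filter state).

    mu_hat = EMA(u_flow) / V; on a constant signal the estimate converges to
    u_flow / V exactly.  Negative raw samples are clipped to zero.
    """
    if V <= 0:
        raise ValueError("culture volume must be positive")
    raw = max(float(raw_flow), 0.0)
    if not signal.initialized:
        f = raw
    else:
        a = signal.alpha
        f = (1.0 - a) * signal.filtered_flow + a * raw
    new = replace(signal, filtered_flow=f, initialized=True)
    return f / V, new


# ---------------------------------------------------------------------------
# MetE growth plant
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrowthPlantState:
    """Current growth rate plus the steady-state map and its slow drift.

    mu_ss(u_green) is a Hill curve normalized so mu_ss(0) = mu_min and
    mu_ss(100) = mu_max exactly; ``tau_min`` is the first-order response
    time constant.  With drift enabled, ``mu_min`` creeps upward at
    ``drift_rate`` per minute once the culture has spent
    ``drift_onset_min`` minutes under predominantly red light.
    """

    mu: float = MU_FULL_RED
    mu_min: float = MU_FULL_RED
    mu_max: float = MU_FULL_GREEN
    half_sat: float = 30.0      # % green at half-activation
    steepness: float = 2.0
    tau_min: float = 45.0
    drift_rate: float = 0.0     # min^-2, raises mu_min
    drift_onset_min: float = 720.0
    red_time_min: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.mu_min < self.mu_max):
            raise ValueError("need 0 < mu_min < mu_max")
        if self.mu < 0 or self.mu > self.mu_max * 1.2:
            raise ValueError("mu outside the plausible range")
        if self.tau_min <= 0:
            raise ValueError("response time constant must be positive")


def mu_steady_state(state: GrowthPlantState, u_green: float) -> float:
    """Steady-state growth rate for a held green fraction (in %)."""
    if not (0.0 <= u_green <= 100.0):
        raise ValueError("u_green must lie in [0, 100] %")
    n, K = state.steepness, state.half_sat
    h = u_green ** n / (K ** n + u_green ** n)
    h_max = 100.0 ** n / (K ** n + 100.0 ** n)
    return state.mu_min + (state.mu_max - state.mu_min) * h / h_max


def growth_plant_step(state: GrowthPlantState, u_green: float, dt: float
                      ) -> GrowthPlantState:
    """Relax mu toward mu_ss(u_green) over ``dt`` minutes (exact exponential
    update, so repeated small steps match the continuous solution)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    red_time = state.red_time_min + dt if u_green < 50.0 else 0.0
    mu_min = state.mu_min
    if state.drift_rate > 0 and red_time > state.drift_onset_min:
        mu_min = min(mu_min + state.drift_rate * dt, 0.9 * state.mu_max)
        state = replace(state, mu_min=mu_min)
    target = mu_steady_state(state, u_green)
    decay = math.exp(-dt / state.tau_min)
    mu = target + (state.mu - target) * decay
    return replace(state, mu=mu, red_time_min=red_time)
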