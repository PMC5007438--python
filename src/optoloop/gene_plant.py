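"""Continuous-time model of the CcaS/CcaR sfGFP expression system.

The plant is a chain of three linear ODEs for mRNA, immature protein and
fluorescent (mature) protein driven by green light.  Two coordinate systems
are supported:

* **raw** concentrations ``(r, p, g)`` with basal transcription, translation,
  maturation and dilution rates, and
* **fold-change** coordinates ``(R, P, G)`` in which each species is divided
  by its un-induced steady state, so the rest state under zero input is
  exactly ``(1, 1, 1)``.

In fold-change coordinates the dynamics are

    dR/dt = d_r (1 - R) + b_r u
    dP/dt = (d_p + k_m) (R - P)
    dG/dt = d_p (P - G)

where ``u = f(U)`` is the static dose-response image of the applied green
intensity ``U`` (percent of the maximal LED power).  A constant input ``u``
drives ``G`` to the steady state ``1 + (b_r/d_r) u``; with the nominal fitted
rates ``b_r/d_r = 1.0094`` so ``u = 1`` yields a fold change of about 2.

The module also defines the global culture disturbances used by the
disturbance-rejection scenarios (medium shift, temperature shift, input
offset, additive output offset) and day-to-day parameter variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

__all__ = [
    "RawModelParams",
    "ModelParams",
    "NOMINAL_PARAMS",
    "FoldChangeState",
    "DoseResponse",
    "DEFAULT_DOSE_RESPONSE",
    "DisturbanceEvent",
    "Plant",
    "fold_matrices",
    "simulate_fold_change",
    "simulate_raw",
    "apply_disturbance",
    "perturb_day_to_day",
]

_REST = np.ones(3)


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"{name} must be finite, got {v!r}")


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParams:
    """Fold-change model rates (min^-1) plus sampling metadata.

    ``T_s`` is the controller sampling period in minutes and
    ``input_delay_steps`` the number of whole sampling periods by which an
    applied input is delayed before it reaches the plant.
    """

    d_r: float = 0.0956
    d_p: float = 0.0214
    b_r: float = 0.0965
    k_m: float = 0.0116
    T_s: float = 10.0
    input_delay_steps: int = 1

    def __post_init__(self) -> None:
        _check_finite("rates", self.d_r, self.d_p, self.b_r, self.k_m, self.T_s)
        if min(self.d_r, self.d_p, self.b_r, self.k_m) <= 0:
            raise ValueError("all rates must be strictly positive")
        if self.T_s <= 0:
            raise ValueError("T_s must be positive")
        if self.input_delay_steps < 0:
            raise ValueError("input_delay_steps must be >= 0")

    @property
    def dc_gain(self) -> float:
        """Steady-state fold change added per unit of input u (= b_r/d_r)."""
        return self.b_r / self.d_r

    @property
    def doubling_time(self) -> float:
        """Culture doubling time implied by the dilution rate (min)."""
        return math.log(2.0) / self.d_p

    def as_vector(self) -> np.ndarray:
        return np.array([self.d_r, self.d_p, self.b_r, self.k_m])

    @classmethod
    def from_vector(cls, v: Sequence[float], T_s: float = 10.0,
                    input_delay_steps: int = 1) -> "ModelParams":
        d_r, d_p, b_r, k_m = (float(x) for x in v)
        return cls(d_r=d_r, d_p=d_p, b_r=b_r, k_m=k_m, T_s=T_s,
                   input_delay_steps=input_delay_steps)


NOMINAL_PARAMS = ModelParams()


@dataclass(frozen=True)
class RawModelParams:
    """Raw-coordinate rates of the expression system.

    ``b_r0`` is the basal (dark/red) transcription rate, ``b_r_gain`` the
    additional transcription rate per unit of fold-change input ``u = f(U)``,
    ``b_p`` the translation rate, ``d_r`` mRNA degradation, ``d_p`` dilution
    and ``k_m`` chromophore maturation (all per minute; concentrations in
    arbitrary units).
    """

    b_r0: float = 1.0
    b_r_gain: float = 1.0094
    d_r: float = 0.0956
    b_p: float = 0.5
    d_p: float = 0.0214
    k_m: float = 0.0116

    def __post_init__(self) -> None:
        vals = (self.b_r0, self.b_r_gain, self.d_r, self.b_p, self.d_p, self.k_m)
        _check_finite("raw rates", *vals)
        if min(vals) <= 0:
            raise ValueError("all raw rates must be strictly positive")
        td = math.log(2.0) / self.d_p
        if not (10.0 <= td <= 300.0):
            raise ValueError(f"d_p implies implausible doubling time {td:.1f} min")

    def uninduced_steady_state(self) -> np.ndarray:
        """Steady state (r0, p0, g0) under U = 0."""
        r0 = self.b_r0 / self.d_r
        p0 = self.b_p * r0 / (self.d_p + self.k_m)
        g0 = self.k_m * p0 / self.d_p
        return np.array([r0, p0, g0])

    def to_fold(self, T_s: float = 10.0, input_delay_steps: int = 1) -> ModelParams:
        """Equivalent fold-change parameters (b_r = b_r_gain * d_r / b_r0)."""
        return ModelParams(d_r=self.d_r, d_p=self.d_p,
                           b_r=self.b_r_gain * self.d_r / self.b_r0,
                           k_m=self.k_m, T_s=T_s,
                           input_delay_steps=input_delay_steps)


@dataclass(frozen=True)
class FoldChangeState:
    R: float = 1.0
    P: float = 1.0
    G: float = 1.0

    def __post_init__(self) -> None:
        _check_finite("state", self.R, self.P, self.G)
        if min(self.R, self.P, self.G) < 0:
            raise ValueError("fold-change state components must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.P, self.G])


# ---------------------------------------------------------------------------
# dose-response map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseResponse:
    """Static map from green intensity U (%) to fold-change input u = f(U).

    Hill form with zero basal offset, ``f(U) = u_max U^n / (K^n + U^n)``:
    f(0) = 0, monotone increasing, and with the default parameters nearly flat
    above 60% intensity (f(100) - f(60) < 2% of f(100)), mirroring the
    saturating dose-response of the light system.  ``K`` is the
    half-saturation intensity in percent and ``u_max`` the saturating
    fold-change input.
    """

    u_max: float = 1.2
    K: float = 3.0
    n: float = 1.0
    basal: float = 0.0
    kind: str = "hill"

    def __post_init__(self) -> None:
        _check_finite("dose-response", self.u_max, self.K, self.n, self.basal)
        if self.u_max <= 0 or self.K <= 0 or self.n <= 0:
            raise ValueError("u_max, K and n must be positive")
        if self.basal != 0.0:
            raise ValueError("basal offset is fixed at 0 so that f(0) = 0")

    def __call__(self, U):
        U = np.asarray(U, dtype=float)
        _check_finite("U", U)
        if np.any(U < 0) or np.any(U > 100):
            raise ValueError("green intensity U must lie in [0, 100] %")
        Un = np.power(U, self.n)
        out = self.u_max * Un / (self.K ** self.n + Un)
        return float(out) if out.ndim == 0 else out

    def invert(self, u: float) -> float:
        """Green intensity achieving fold input ``u``; clips to [0, 100].

        Inputs beyond the saturation value f(100) cannot be realized and
        return 100 (the saturation flag is simply ``u > f(100)``).
        """
        _check_finite("u", u)
        if u < 0:
            raise ValueError("fold-change input u must be >= 0")
        if u >= self(100.0):
            return 100.0
        if u == 0.0:
            return 0.0
        U = self.K * (u / (self.u_max - u)) ** (1.0 / self.n)
        return float(min(max(U, 0.0), 100.0))

    def saturates(self, u: float) -> bool:
        return u > self(100.0)

    @classmethod
    def fit(cls, U_points: Sequence[float], u_points: Sequence[float],
            n_fixed: float | None = None) -> "DoseResponse":
        """Least-squares Hill fit to steady-state (U, u) measurements."""
        U = np.asarray(U_points, dtype=float)
        u = np.asarray(u_points, dtype=float)
        if n_fixed is None:
            def model(x, u_max, K, n):
                return u_max * x ** n / (K ** n + x ** n)
            p0 = (max(u.max(), 1e-3), max(np.median(U), 1.0), 1.0)
            popt, _ = curve_fit(model, U, u, p0=p0, maxfev=20000,
                                bounds=([1e-8, 1e-8, 0.2], [np.inf, 200.0, 8.0]))
            return cls(u_max=popt[0], K=popt[1], n=popt[2])
        def model1(x, u_max, K):
            return u_max * x ** n_fixed / (K ** n_fixed + x ** n_fixed)
        popt, _ = curve_fit(model1, U, u, p0=(max(u.max(), 1e-3), 1.0),
                            maxfev=20000)
        return cls(u_max=popt[0], K=popt[1], n=n_fixed)


DEFAULT_DOSE_RESPONSE = DoseResponse()


# ---------------------------------------------------------------------------
# disturbances
# ---------------------------------------------------------------------------

_KINDS = ("medium_shift", "temperature_shift", "input_offset", "additive_output")


@dataclass(frozen=True)
class DisturbanceEvent:
    """A global perturbation applied to a running culture.

    kind:
        ``medium_shift``       -- dilution rate jumps to ln2/``new_doubling_time``
                                  at onset (e.g. M9 -> LB: 38 min -> 25 min).
        ``temperature_shift``  -- transcription/translation/maturation rates are
                                  scaled by ``kinetic_scale`` and the dilution
                                  rate by ``dilution_scale``, both ramped
                                  linearly over ``ramp_min`` minutes (cool-down
                                  out of the heat bath).
        ``input_offset``       -- every later commanded intensity is reduced by
                                  ``fraction`` of the intensity applied at
                                  onset, floored at 0 (LED damage mimic).
        ``additive_output``    -- constant offset ``level`` added to the
                                  measured output from onset.
    """

    kind: str
    onset: float
    new_doubling_time: float | None = None
    kinetic_scale: float = 0.46
    dilution_scale: float = 0.5
    ramp_min: float = 30.0
    fraction: float = 0.5
    level: float = 0.0
    # resolved at run time for input_offset (fraction of the applied input)
    offset_value: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown disturbance kind {self.kind!r}; "
                             f"expected one of {_KINDS}")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if self.kind == "medium_shift" and (
                self.new_doubling_time is None or self.new_doubling_time <= 0):
            raise ValueError("medium_shift requires a positive new_doubling_time")
        if self.kind == "temperature_shift":
            if not (0 < self.kinetic_scale <= 1 and 0 < self.dilution_scale <= 1):
                raise ValueError("temperature scales must lie in (0, 1]")
            if self.ramp_min < 0:
                raise ValueError("ramp_min must be >= 0")

    def is_noop(self) -> bool:
        if self.kind == "medium_shift":
            return False
        if self.kind == "temperature_shift":
            return self.kinetic_scale == 1.0 and self.dilution_scale == 1.0
        if self.kind == "input_offset":
            return self.fraction == 0.0 and not self.offset_value
        return self.level == 0.0


def apply_disturbance(plant: "Plant", event: DisturbanceEvent) -> "Plant":
    """Return a copy of ``plant`` with ``event`` added (kept in time order)."""
    events = sorted([*plant.events, event], key=lambda e: e.onset)
    return replace(plant, events=tuple(events))


# ---------------------------------------------------------------------------
# linear system in deviation coordinates
# ---------------------------------------------------------------------------

def fold_matrices(params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """(A, B) of the fold-change system in deviations from rest.

    With x = (R-1, P-1, G-1), dx/dt = A x + B u; the affine rest terms cancel
    exactly, so deviations obey a pure LTI system.
    """
    c = params.d_p + params.k_m
    A = np.array([
        [-params.d_r, 0.0, 0.0],
        [c, -c, 0.0],
        [0.0, params.d_p, -params.d_p],
    ])
    B = np.array([params.b_r, 0.0, 0.0])
    return A, B


def _as_profile(u) -> Callable[[float], float]:
    """Normalize an input specification to a callable u(t).

    Accepts a scalar, a callable, or a piecewise-constant pair
    ``(breakpoints, values)`` with ``values[i]`` held on
    ``[breakpoints[i], breakpoints[i+1])``.
    """
    if callable(u):
        return u
    if np.isscalar(u):
        val = float(u)
        _check_finite("u", val)
        return lambda t: val
    times, values = u
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    _check_finite("input profile", times, values)

    def profile(t: float) -> float:
        i = int(np.searchsorted(times, t, side="right")) - 1
        return float(values[max(i, 0)])

    return profile


def _breakpoints(u, horizon: float) -> np.ndarray:
    if callable(u) or np.isscalar(u):
        return np.array([])
    times = np.asarray(u[0], dtype=float)
    return times[(times > 0) & (times < horizon)]


def simulate_fold_change(params: ModelParams, input_profile, horizon: float,
                         initial=(1.0, 1.0, 1.0), t_eval=None,
                         rtol: float = 1e-8, atol: float = 1e-10):
    """Integrate the fold-change ODE under a fold-input profile u(t) >= 0.

    Returns ``(t, X)`` with ``X[k] = (R, P, G)`` at ``t[k]``.  Inputs are
    zero-order-held between breakpoints when given as a piecewise profile;
    integration restarts at each breakpoint so discontinuities are exact.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if isinstance(initial, FoldChangeState):
        x0 = initial.as_array()
    else:
        x0 = np.asarray(initial, dtype=float)
    _check_finite("initial state", x0)
    u_of_t = _as_profile(input_profile)

    def rhs(t, x):
        u = u_of_t(t)
        if not np.isfinite(u) or u < 0:
            raise ValueError(f"input u(t) must be finite and >= 0, got {u}")
        R, P, G = x
        c = params.d_p + params.k_m
        return [params.d_r * (1.0 - R) + params.b_r * u,
                c * (R - P),
                params.d_p * (P - G)]

    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 301)
    t_eval = np.asarray(t_eval, dtype=float)
    breaks = _breakpoints(input_profile, horizon)
    segments = np.concatenate(([0.0], breaks, [horizon]))

    ts: list[np.ndarray] = []
    xs: list[np.ndarray] = []
    x = x0
    for a, b in zip(segments[:-1], segments[1:]):
        # evaluate u just inside the segment so ZOH values are unambiguous
        mask = (t_eval >= a) & (t_eval <= b) if b == horizon else \
               (t_eval >= a) & (t_eval < b)
        pts = np.unique(np.concatenate((t_eval[mask], [a, b])))
        sol = solve_ivp(rhs, (a, b), x, t_eval=pts, rtol=rtol, atol=atol,
                        method="LSODA")
        if not sol.success:  # pragma: no cover - LSODA is robust here
            raise RuntimeError(f"integration failed: {sol.message}")
        keep = np.isin(sol.t, t_eval[mask])
        ts.append(sol.t[keep])
        xs.append(sol.y[:, keep].T)
        x = sol.y[:, -1]
    t = np.concatenate(ts)
    X = np.vstack(xs)
    order = np.argsort(t, kind="stable")
    t, X = t[order], X[order]
    uniq = np.concatenate(([True], np.diff(t) > 0))
    return t[uniq], np.clip(X[uniq], 0.0, None)


def simulate_raw(params: RawModelParams, light_profile, horizon: float,
                 dose_response: DoseResponse = DEFAULT_DOSE_RESPONSE,
                 initial=None, t_eval=None, rtol: float = 1e-8,
                 atol: float = 1e-10):
    """Integrate the raw model under a green-intensity profile U(t) in %.

    ``initial`` defaults to the un-induced steady state.  Dividing each
    species by its un-induced steady state recovers the fold-change
    trajectory of :func:`simulate_fold_change` driven by u = f(U).
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    U_of_t = _as_profile(light_profile)
    if initial is None:
        x0 = params.uninduced_steady_state()
    else:
        x0 = np.asarray(initial, dtype=float)
    _check_finite("initial state", x0)

    def rhs(t, x):
        U = U_of_t(t)
        u = dose_response(U)
        r, p, g = x
        return [params.b_r0 + params.b_r_gain * u - params.d_r * r,
                params.b_p * r - (params.d_p + params.k_m) * p,
                params.k_m * p - params.d_p * g]

    if t_eval is None:
        t_eval = np.linspace(0.0, horizon, 301)
    t_eval = np.asarray(t_eval, dtype=float)
    breaks = _breakpoints(light_profile, horizon)
    segments = np.concatenate(([0.0], breaks, [horizon]))
    ts, xs = [], []
    x = x0
    for a, b in zip(segments[:-1], segments[1:]):
        mask = (t_eval >= a) & (t_eval <= b) if b == horizon else \
               (t_eval >= a) & (t_eval < b)
        pts = np.unique(np.concatenate((t_eval[mask], [a, b])))
        sol = solve_ivp(rhs, (a, b), x, t_eval=pts, rtol=rtol, atol=atol,
                        method="LSODA")
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"integration failed: {sol.message}")
        keep = np.isin(sol.t, t_eval[mask])
        ts.append(sol.t[keep])
        xs.append(sol.y[:, keep].T)
        x = sol.y[:, -1]
    t = np.concatenate(ts)
    X = np.vstack(xs)
    order = np.argsort(t, kind="stable")
    t, X = t[order], X[order]
    uniq = np.concatenate(([True], np.diff(t) > 0))
    return t[uniq], np.clip(X[uniq], 0.0, None)


# ---------------------------------------------------------------------------
# disturbed plant used by the closed-loop scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plant:
    """A culture: fold-change dynamics + dose-response + scheduled disturbances.

    The simulation state is kept externally (the experiments module advances
    it interval by interval); this object only defines the time-varying
    rates.  Disturbance scalings act on the raw-model rates and are expressed
    here in fold-change coordinates normalized to the *pre-disturbance*
    baseline, which is how the measured fold change is defined throughout an
    experiment.
    """

    params: ModelParams = NOMINAL_PARAMS
    dose_response: DoseResponse = DEFAULT_DOSE_RESPONSE
    events: tuple[DisturbanceEvent, ...] = ()

    def _scales(self, t: float) -> tuple[float, float]:
        """(kinetic_scale, current d_p) at time t."""
        s_k = 1.0
        d_p = self.params.d_p
        for ev in self.events:
            if t < ev.onset:
                continue
            if ev.kind == "medium_shift":
                d_p = math.log(2.0) / ev.new_doubling_time
            elif ev.kind == "temperature_shift":
                if ev.ramp_min > 0:
                    frac = min((t - ev.onset) / ev.ramp_min, 1.0)
                else:
                    frac = 1.0
                s_k *= 1.0 + frac * (ev.kinetic_scale - 1.0)
                d_p *= 1.0 + frac * (ev.dilution_scale - 1.0)
        return s_k, d_p

    def transform_input(self, U: float, t: float) -> float:
        """Apply active input_offset events to a commanded intensity."""
        for ev in self.events:
            if ev.kind == "input_offset" and t >= ev.onset:
                if ev.offset_value is None:
                    raise RuntimeError(
                        "input_offset event not resolved; the runner must set "
                        "offset_value = fraction * (input applied at onset)")
                U = max(0.0, U - ev.offset_value)
        return float(min(U, 100.0))

    def output_offset(self, t: float) -> float:
        return sum(ev.level for ev in self.events
                   if ev.kind == "additive_output" and t >= ev.onset)

    def rhs(self, t: float, x: np.ndarray, u: float) -> list[float]:
        """Fold-change dynamics (baseline-normalized) with disturbances.

        Derived from the raw model with transcription/translation/maturation
        scaled by s_k and the dilution rate replaced by d_p(t); production
        coefficients keep the baseline normalization constants.
        """
        s_k, d_p = self._scales(t)
        p0 = self.params
        R, P, G = x
        return [s_k * (p0.d_r * (1.0 - R) + p0.b_r * u),
                s_k * (p0.d_p + p0.k_m) * R - (d_p + s_k * p0.k_m) * P,
                s_k * p0.d_p * P - d_p * G]

    def advance(self, x: np.ndarray, U_commanded: float, t0: float,
                dt: float, rtol: float = 1e-8, atol: float = 1e-10
                ) -> np.ndarray:
        """Advance the culture state over [t0, t0+dt] under a held input."""
        U_eff = self.transform_input(U_commanded, t0)
        u = self.dose_response(U_eff)
        sol = solve_ivp(lambda t, x: self.rhs(t, x, u), (t0, t0 + dt), x,
                        rtol=rtol, atol=atol, method="LSODA")
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"integration failed: {sol.message}")
        return np.clip(sol.y[:, -1], 0.0, None)

    def resolve_input_offsets(self, t: float, U_applied: float) -> "Plant":
        """Freeze the magnitude of input_offset events whose onset is ``t``."""
        events = []
        for ev in self.events:
            if (ev.kind == "input_offset" and ev.offset_value is None
                    and abs(ev.onset - t) < 1e-9):
                ev = replace(ev, offset_value=ev.fraction * U_applied)
            events.append(ev)
        return replace(self, events=tuple(events))


def trajectory_frame(t: np.ndarray, X: np.ndarray, u=None, U_green_pct=None):
    """Tidy CSV-ready frame (time_min, R, P, G, u, U_green_pct)."""
    import pandas as pd
    df = pd.DataFrame({"time_min": t, "R": X[:, 0], "P": X[:, 1],
                       "G": X[:, 2]})
    df["u"] = np.broadcast_to(u, len(df)) if u is not None else np.nan
    df["U_green_pct"] = (np.broadcast_to(U_green_pct, len(df))
                         if U_green_pct is not None else np.nan)
    return df


def perturb_day_to_day(plant: Plant, sigma: float,
                       rng: np.random.Generator) -> Plant:
    """Day-to-day variability: independent log-normal factors on each rate
    and on the dose-response gain (median-preserving, spread ``sigma``)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    f = rng.lognormal(mean=0.0, sigma=sigma, size=5)
    p = plant.params
    params = ModelParams(d_r=p.d_r * f[0], d_p=p.d_p * f[1],
                         b_r=p.b_r * f[2], k_m=p.k_m * f[3],
                         T_s=p.T_s, input_delay_steps=p.input_delay_steps)
    dr = plant.dose_response
    dose = DoseResponse(u_max=dr.u_max * f[4], K=dr.K, n=dr.n)
    return replace(plant, params=params, dose_response=dose)
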