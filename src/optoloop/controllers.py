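"""Discrete-time feedback laws: positional PI with gain scheduling, the
growth-rate PI variant, and receding-horizon MPC on the discretized model.

The PI law is the positional form with the integral updated before the
output and clamped to a finite interval:

    e_k   = y_ref - y
    u_I'  = clip(u_I + K_I e_k, clamp)
    u_k   = clip(K_P e_k + u_I', [u_min, u_max])

For gene-expression control the error is in fold-change units and the
output is the commanded green intensity in percent of maximal LED power
(saturated to [0, 100]).  The growth variant runs every minute on the
filtered growth-rate estimate, clamps its integral to [0, 60] and splits
the actuation between the two LED channels (u_red = 100 - u_green so the
sum of normalized intensities stays constant).

The MPC optimizes the next N fold-change inputs against a reference
preview using the (possibly adapted) ZOH model with its one-step input
delay and additive disturbance estimate; the problem is a box-constrained
linear least squares solved exactly, and only the first input is applied,
mapped to an intensity through the inverse dose-response and capped at
60% where the dose-response is already nearly flat.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import lsq_linear

from .estimation import DiscreteModel
from .gene_plant import DEFAULT_DOSE_RESPONSE, DoseResponse

logger = logging.getLogger(__name__)

__all__ = [
    "PIConfig",
    "PIState",
    "pi_step",
    "apply_gain_schedule",
    "growth_pi_step",
    "MPCConfig",
    "mpc_step",
    "mpc_predict_cost",
    "ReferenceProfile",
]


# ---------------------------------------------------------------------------
# PI control
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleStage:
    """A gain pair activated by a time trigger or a sustained-in-band one."""

    K_P: float
    K_I: float
    at_time: float | None = None       # activate when t >= at_time
    in_band_samples: int | None = None # or after this many in-band samples


@dataclass(frozen=True)
class PIConfig:
    K_P: float = 80.0
    K_I: float = 8.0
    u_min: float = 0.0
    u_max: float = 100.0
    # the dose-response is nearly flat above ~30% intensity, so a larger
    # integral would only encode saturation time (windup); the growth loop
    # overrides this with the wider [0, 60] interval it was tuned with
    clamp: tuple[float, float] = (0.0, 30.0)
    schedule: tuple[ScheduleStage, ...] = ()

    def __post_init__(self) -> None:
        if self.u_min >= self.u_max:
            raise ValueError("u_min must be < u_max")
        lo, hi = self.clamp
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("clamp must be a finite interval")

    def gains_at_stage(self, stage: int) -> tuple[float, float]:
        if stage <= 0 or not self.schedule:
            return self.K_P, self.K_I
        s = self.schedule[min(stage, len(self.schedule)) - 1]
        return s.K_P, s.K_I


@dataclass(frozen=True)
class PIState:
    u_I: float = 0.0
    last_error: float = 0.0
    last_input: float = 0.0
    last_measurement: float | None = None
    stage: int = 0
    in_band_count: int = 0


def pi_step(cfg: PIConfig, state: PIState, y_ref: float,
            y: float | None) -> tuple[float, PIState]:
    """One PI update; ``y=None`` signals a failed measurement and reuses the
    previous one (the first step of a run must have a real measurement)."""
    if y is None:
        if state.last_measurement is None:
            raise ValueError("no previous measurement to reuse")
        y = state.last_measurement
    if not np.isfinite(y) or not np.isfinite(y_ref):
        raise ValueError("reference and measurement must be finite")
    K_P, K_I = cfg.gains_at_stage(state.stage)
    e = y_ref - y
    u_I = float(np.clip(state.u_I + K_I * e, *cfg.clamp))
    u = float(np.clip(K_P * e + u_I, cfg.u_min, cfg.u_max))
    return u, replace(state, u_I=u_I, last_error=e, last_input=u,
                      last_measurement=y)


def apply_gain_schedule(cfg: PIConfig, state: PIState,
                        trigger: bool) -> PIState:
    """Advance to the next scheduled gain pair on a trigger.

    The integral term is carried over unchanged (bumpless at zero error);
    with no further stages the trigger is ignored.
    """
    if not trigger or state.stage >= len(cfg.schedule):
        return state
    return replace(state, stage=state.stage + 1, in_band_count=0)


def evaluate_schedule_trigger(cfg: PIConfig, state: PIState, t: float,
                              y: float, y_ref: float, band: float) -> tuple[bool, PIState]:
    """Trigger logic for the next stage: explicit time, or output inside the
    tolerance band for ``in_band_samples`` consecutive samples (default 3)."""
    if state.stage >= len(cfg.schedule):
        return False, state
    nxt = cfg.schedule[state.stage]
    if nxt.at_time is not None:
        return t >= nxt.at_time, state
    need = nxt.in_band_samples or 3
    count = state.in_band_count + 1 if abs(y - y_ref) <= band else 0
    return count >= need, replace(state, in_band_count=count)


def growth_pi_step(cfg: PIConfig, state: PIState, mu_ref: float,
                   mu_filtered: float) -> tuple[float, float, PIState]:
    """Growth-rate PI: returns (u_green %, u_red %) with u_red = 100-u_green.

    The integral term is saturated in [0, 60] to keep large persistent
    errors from accumulating; the green command is clipped to [0, 100].
    """
    if mu_filtered < 0:
        raise ValueError("filtered growth rate must be >= 0")
    K_P, K_I = cfg.gains_at_stage(state.stage)
    e = mu_ref - mu_filtered
    u_I = float(np.clip(state.u_I + K_I * e, *cfg.clamp))
    u_green = float(np.clip(K_P * e + u_I, 0.0, 100.0))
    new = replace(state, u_I=u_I, last_error=e, last_input=u_green,
                  last_measurement=mu_filtered)
    return u_green, 100.0 - u_green, new


GROWTH_PI_CONFIG = PIConfig(K_P=6000.0, K_I=45.0, clamp=(0.0, 60.0))


# ---------------------------------------------------------------------------
# reference profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceProfile:
    """Reference trajectory: constant, sinusoid or piecewise-linear.

    ``band`` is the tolerance half-width as a fraction of the scenario's
    scale; ``band_convention`` selects that scale: the target level
    ('target'), the instantaneous reference ('reference') or the maximum
    reference level ('max').
    """

    kind: str = "constant"
    level: float = 2.0
    amplitude: float = 0.0
    period: float = 120.0
    mean: float = 2.0
    breakpoints: tuple[tuple[float, float], ...] = ()
    band: float = 0.05
    band_convention: str = "target"

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "sinusoid", "piecewise_linear"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        if self.kind == "constant" and self.level <= 0:
            raise ValueError("reference level must be positive")
        if self.kind == "sinusoid":
            if self.period <= 0:
                raise ValueError("period must be positive")
            if self.mean - self.amplitude <= 0:
                raise ValueError("sinusoid must stay strictly positive")
        if self.kind == "piecewise_linear" and len(self.breakpoints) < 2:
            raise ValueError("piecewise_linear needs >= 2 (time, level) points")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            out = np.full(t.shape, self.level)
        elif self.kind == "sinusoid":
            out = self.mean + self.amplitude * np.sin(2 * np.pi * t / self.period)
        else:
            times = np.array([b[0] for b in self.breakpoints])
            levels = np.array([b[1] for b in self.breakpoints])
            out = np.interp(t, times, levels)
        return float(out) if out.ndim == 0 else out

    def band_halfwidth(self, t) -> np.ndarray:
        """Absolute tolerance half-width at each time."""
        t = np.asarray(t, dtype=float)
        if self.band_convention == "reference":
            scale = self(t)
        elif self.band_convention == "max":
            scale = self.max_level()
        else:
            scale = self.level if self.kind == "constant" else self.max_level()
        return self.band * np.broadcast_to(scale, t.shape)

    def max_level(self) -> float:
        if self.kind == "constant":
            return self.level
        if self.kind == "sinusoid":
            return self.mean + self.amplitude
        return max(b[1] for b in self.breakpoints)


# ---------------------------------------------------------------------------
# MPC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MPCConfig:
    horizon: int = 6
    U_cap: float = 60.0
    du_weight: float = 1e-3
    dose_response: DoseResponse = DEFAULT_DOSE_RESPONSE

    def __post_init__(self) -> None:
        if self.horizon < 2:
            raise ValueError("horizon must be >= 2")
        if not (0 < self.U_cap <= 100):
            raise ValueError("U_cap must lie in (0, 100]")
        if self.du_weight < 0:
            raise ValueError("du_weight must be >= 0")

    @property
    def u_cap_fold(self) -> float:
        return self.dose_response(self.U_cap)


def _prediction_matrices(model: DiscreteModel, N: int
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                    np.ndarray]:
    """Output maps over j = 1..N: free-state, pending-input/disturbance and
    decision-input contributions (one-step input delay baked in)."""
    C = model.C
    powers = [np.eye(3)]
    for _ in range(N):
        powers.append(model.Ad @ powers[-1])
    F = np.stack([C @ powers[j] for j in range(1, N + 1)])       # (N, 3)
    # response of output j to an input acting from interval i (i < j)
    h = np.array([C @ powers[j] @ model.Bd for j in range(N)])    # j = 0.. N-1
    # pending input acts on interval 0 only; decision u_i acts on interval i+1
    pend = np.array([h[j - 1] if j >= 1 else 0.0 for j in range(1, N + 1)])
    Phi = np.zeros((N, N))
    for j in range(1, N + 1):        # output index
        for i in range(N):           # decision index, acts on interval i+1
            if i + 1 < j:
                Phi[j - 1, i] = h[j - 2 - i]
    # disturbance acts on every interval
    dist = np.array([sum(h[:j]) for j in range(1, N + 1)])
    # affine drift of the adaptive model accumulates every interval
    S = np.zeros(3)
    drift = np.empty(N)
    for j in range(N):
        S = S + C @ powers[j]
        drift[j] = S @ model.fd
    return F, pend, Phi, dist, drift


def mpc_predict_cost(model: DiscreteModel, cfg: MPCConfig, x_est: np.ndarray,
                     pending_u: float, d_est: float, ref_window: np.ndarray,
                     u_seq: np.ndarray) -> float:
    """Cost of an explicit input sequence (used by the brute-force oracle
    and by the optimizer through the same prediction matrices)."""
    N = cfg.horizon
    F, pend, Phi, dist, drift = _prediction_matrices(model, N)
    # dist already covers every interval, including the pending one
    free = (F @ np.asarray(x_est, float) + pend * pending_u + dist * d_est
            + drift)
    y = free + Phi @ np.asarray(u_seq, float)
    r = np.asarray(ref_window, float)[:N] - 1.0
    cost = float(np.sum((y - r) ** 2))
    if cfg.du_weight > 0:
        du = np.diff(np.concatenate(([pending_u], u_seq)))
        cost += cfg.du_weight * float(np.sum(du ** 2))
    return cost


def mpc_step(cfg: MPCConfig, model: DiscreteModel, x_est: np.ndarray,
             pending_u: float, d_est: float, ref_window: Sequence[float],
             warm_start: np.ndarray | None = None
             ) -> tuple[float, float, np.ndarray, dict]:
    """One receding-horizon solve.

    ``x_est`` is the fold-change deviation estimate, ``pending_u`` the
    fold-change input already committed for the current interval (input
    delay), ``d_est`` the additive disturbance estimate and ``ref_window``
    the next N reference values in fold-change units.  Returns the applied
    intensity U (%), the fold input, the shifted solution for warm starting
    and an info dict with the achieved cost.
    """
    N = cfg.horizon
    ref = np.asarray(ref_window, dtype=float)
    if ref.size < N:
        raise ValueError(f"reference window must provide >= {N} samples")
    if not np.all(np.isfinite(x_est)):
        raise ValueError("state estimate must be finite")
    F, pend, Phi, dist, drift = _prediction_matrices(model, N)
    free = (F @ np.asarray(x_est, float) + pend * pending_u + dist * d_est
            + drift)
    target = (ref[:N] - 1.0) - free
    u_hi = cfg.u_cap_fold
    A = Phi
    b = target
    if cfg.du_weight > 0:
        # increment-penalty rows: sqrt(w) * (u_i - u_{i-1}), u_{-1} = pending
        D = np.eye(N) - np.eye(N, k=-1)
        w = math.sqrt(cfg.du_weight)
        A = np.vstack([Phi, w * D])
        rhs0 = np.zeros(N)
        rhs0[0] = w * pending_u
        b = np.concatenate([target, rhs0])
    try:
        sol = lsq_linear(A, b, bounds=(0.0, u_hi), method="bvls",
                         tol=1e-12)
        u_seq = sol.x
        ok = sol.success or sol.status > 0
    except Exception:  # pragma: no cover - bvls is robust on these sizes
        ok = False
    if not ok:  # pragma: no cover
        logger.warning("MPC optimizer failed; reusing previous input")
        u_seq = np.full(N, pending_u)
    u0 = float(np.clip(u_seq[0], 0.0, u_hi))
    U = cfg.dose_response.invert(u0)
    U = float(min(U, cfg.U_cap))
    warm = np.concatenate([u_seq[1:], u_seq[-1:]])
    y_pred = free + Phi @ u_seq
    cost = float(np.sum((y_pred - (ref[:N] - 1.0)) ** 2))
    if cfg.du_weight > 0:
        du = np.diff(np.concatenate(([pending_u], u_seq)))
        cost += cfg.du_weight * float(np.sum(du ** 2))
    return U, u0, warm, {"cost": cost, "u_seq": u_seq, "predicted": y_pred + 1.0}
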