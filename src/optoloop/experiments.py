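"""Closed-loop scenario harness: replays the platform's tracking and
disturbance experiments in silico and scores them.

A :class:`Scenario` bundles a plant (fold-change dynamics + dose-response +
scheduled disturbances), a controller specification (PI with optional gain
schedule, adaptive MPC with particle-filter estimation, an open-loop input
replay, or the nested growth loops), a reference profile, a measurement
model and seeds.  :func:`run_scenario` advances the culture interval by
interval with zero-order-held inputs and a one-sampling-period actuation
delay, and returns a tidy :class:`ExperimentTrace`.

Tracking metrics follow the tolerance-band conventions of the platform's
figures: the band half-width is 5% of the target level (constant
references), of the instantaneous reference (sinusoids) or of the maximum
reference level (piecewise profiles); "post-transient" starts at the first
band entry sustained for three consecutive samples.  Sinusoid phase is the
lag maximizing the continuous cross-correlation with the reference
sinusoid (computed by quadrature regression), reported in degrees.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .controllers import (GROWTH_PI_CONFIG, MPCConfig, PIConfig, PIState,
                          ReferenceProfile, ScheduleStage, apply_gain_schedule,
                          evaluate_schedule_trigger, growth_pi_step, mpc_step,
                          pi_step)
from .cytometry import (CytometryCalibration, gate_events, normalized_mean,
                        synthesize_sample)
from .estimation import (PFConfig, discretize_adaptive, measurement_to_fold,
                         pf_init, pf_update)
from .gene_plant import (DEFAULT_DOSE_RESPONSE, DisturbanceEvent, ModelParams,
                         Plant, perturb_day_to_day)
from .growth_control import (GrowthPlantState, GrowthSignal, TurbidostatState,
                             estimate_growth_rate, growth_plant_step,
                             turbidostat_step)

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementModel",
    "Scenario",
    "ExperimentTrace",
    "TrackingMetrics",
    "run_scenario",
    "tracking_metrics",
    "replay_scenario",
    "make_preset",
    "PRESETS",
    "scenario_from_yaml",
    "scenario_to_yaml",
]


# ---------------------------------------------------------------------------
# scenario definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementModel:
    """How the true output turns into the controller's measurement.

    mode 'none': exact; 'multiplicative': y = G (1 + sigma * N(0,1));
    'cytometry': a full synthetic event cloud is generated, gated and
    reduced to the normalized mean, then divided by the un-induced baseline.
    """

    mode: str = "multiplicative"
    sigma: float = 0.03
    calibration: CytometryCalibration = CytometryCalibration()
    n_events: int = 5000

    def __post_init__(self) -> None:
        if self.mode not in ("none", "multiplicative", "cytometry"):
            raise ValueError(f"unknown measurement mode {self.mode!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class Scenario:
    name: str = "scenario"
    plant: Plant = Plant()
    controller: str = "pi"            # pi | mpc | open_loop | growth_pi
    pi_config: PIConfig = PIConfig()
    mpc_config: MPCConfig = MPCConfig()
    pf_config: PFConfig = PFConfig()
    reference: ReferenceProfile = ReferenceProfile()
    measurement: MeasurementModel = MeasurementModel()
    duration: float = 600.0           # min
    seed: int = 0
    day_variability_sigma: float = 0.0
    freeze_at: float | None = None    # freeze the controller output from here
    replay_inputs: tuple = ()         # commanded U sequence for open_loop
    # growth-loop extras
    growth_plant: GrowthPlantState = GrowthPlantState()
    turbidostat: TurbidostatState = TurbidostatState()
    growth_update_min: float = 1.0
    pump_noise_sd: float = 0.005      # ml/min on the 1 Hz pump samples

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")
        if self.controller not in ("pi", "mpc", "open_loop", "growth_pi"):
            raise ValueError(f"unknown controller {self.controller!r}")
        if self.controller == "open_loop" and self.duration > 0 \
                and not self.replay_inputs:
            raise ValueError("open-loop replay requires a stored input sequence")
        T = (self.growth_update_min if self.controller == "growth_pi"
             else self.plant.params.T_s)
        if self.duration > 0 and abs(
                self.duration / T - round(self.duration / T)) > 1e-9:
            raise ValueError("measurement cadence must divide the duration")


@dataclass
class ExperimentTrace:
    """Tidy per-sample record of a run plus a provenance manifest."""

    data: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "ExperimentTrace":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# the GFP expression loops
# ---------------------------------------------------------------------------

def _measure(mode: MeasurementModel, true_output: float,
             rng: np.random.Generator) -> float:
    if mode.mode == "none":
        return float(true_output)
    if mode.mode == "multiplicative":
        return float(true_output * (1.0 + mode.sigma * rng.standard_normal()))
    calib = mode.calibration
    events = synthesize_sample(true_output, calib, n_events=mode.n_events,
                               rng=rng)
    nm = normalized_mean(gate_events(events))
    baseline = calib.background + calib.gain  # un-induced culture, G = 1
    return measurement_to_fold(nm, baseline)


def run_scenario(scenario: Scenario) -> ExperimentTrace:
    """Simulate one closed- or open-loop experiment.

    Inputs are held between measurements; the commanded intensity reaches
    the culture one sampling period later (actuation delay); disturbances
    fire at their onsets; everything is reproducible from the scenario seed.
    """
    if scenario.controller == "growth_pi":
        return _run_growth(scenario)
    s = scenario
    T_s = s.plant.params.T_s
    n_steps = int(round(s.duration / T_s))
    manifest = _manifest(s)
    if n_steps == 0:
        return ExperimentTrace(pd.DataFrame(columns=_GFP_COLUMNS),
                               manifest=manifest)
    ss = np.random.SeedSequence(s.seed)
    rng_day, rng_meas, rng_pf = (np.random.default_rng(c) for c in ss.spawn(3))
    plant = s.plant
    if s.day_variability_sigma > 0:
        plant = perturb_day_to_day(plant, s.day_variability_sigma, rng_day)

    delay = s.plant.params.input_delay_steps
    cmds: list[float] = []            # commanded U per step

    def cmd(idx: int) -> float:
        return cmds[idx] if 0 <= idx < len(cmds) else 0.0

    x = np.ones(3)
    pi_state = PIState()
    ensemble = None
    warm = None
    if s.controller == "mpc":
        ensemble = pf_init(s.plant.params, s.pf_config, rng_pf)
    ctrl_dose = s.mpc_config.dose_response  # the controller's nominal map
    rows: list[dict] = []
    error: str | None = None

    for k in range(n_steps):
        t = k * T_s
        true_G = float(x[2])
        y = _measure(s.measurement, true_G + plant.output_offset(t), rng_meas)
        ref_now = float(s.reference(t))
        d_est = 0.0
        d_p_est = math.nan
        cost = math.nan
        try:
            frozen = s.freeze_at is not None and t >= s.freeze_at
            if frozen:
                U = cmd(k - 1)
            elif s.controller == "open_loop":
                U = float(s.replay_inputs[min(k, len(s.replay_inputs) - 1)])
            elif s.controller == "pi":
                band = float(s.reference.band_halfwidth(t))
                trig, pi_state = evaluate_schedule_trigger(
                    s.pi_config, pi_state, t, y, ref_now, band)
                pi_state = apply_gain_schedule(s.pi_config, pi_state, trig)
                U, pi_state = pi_step(s.pi_config, pi_state, ref_now, y)
            else:  # mpc
                u_last = ctrl_dose(cmd(k - 1 - delay))
                ensemble = pf_update(ensemble, u_last, y, s.pf_config)
                d_p_est = ensemble.param_estimate().d_p
                model = discretize_adaptive(
                    ensemble.param_estimate(),
                    ModelParams.from_vector(ensemble.baseline))
                x_est = ensemble.state_estimate() - 1.0
                d_est = ensemble.d_estimate()
                N = s.mpc_config.horizon
                ref_window = s.reference(t + T_s * np.arange(1, N + 1))
                pending = ctrl_dose(cmd(k - 1))
                U, _, warm, info = mpc_step(s.mpc_config, model, x_est,
                                            pending, d_est, ref_window, warm)
                cost = info["cost"]
        except Exception as exc:  # controller failure truncates the trace
            error = f"controller error at t={t:g} min: {exc}"
            logger.error(error)
            break
        cmds.append(float(U))
        # the culture sees the command issued `delay` steps ago
        U_in_effect = cmd(k - delay)
        plant = plant.resolve_input_offsets(t, U_in_effect)
        U_effective = plant.transform_input(U_in_effect, t)
        rows.append({
            "time_min": t, "reference": ref_now, "measurement": y,
            "true_G": true_G, "U_commanded": float(U),
            "U_effective": U_effective, "u_I": pi_state.u_I,
            "gain_stage": pi_state.stage, "d_est": d_est,
            "d_p_est": d_p_est, "mpc_cost": cost,
            "disturbance_active": int(any(t >= ev.onset
                                          for ev in plant.events)),
        })
        x = plant.advance(x, U_in_effect, t, T_s)
    df = pd.DataFrame(rows, columns=_GFP_COLUMNS)
    if error:
        manifest["error"] = error
    return ExperimentTrace(df, manifest=manifest)


_GFP_COLUMNS = ["time_min", "reference", "measurement", "true_G",
                "U_commanded", "U_effective", "u_I", "gain_stage", "d_est",
                "d_p_est", "mpc_cost", "disturbance_active"]


def replay_scenario(source: ExperimentTrace, scenario: Scenario,
                    seed: int | None = None) -> ExperimentTrace:
    """Open-loop replay of a recorded input sequence on a (possibly
    different-day) plant described by ``scenario``."""
    inputs = tuple(source.data["U_commanded"].to_numpy(float))
    rep = replace(scenario, controller="open_loop", replay_inputs=inputs,
                  seed=scenario.seed if seed is None else seed,
                  name=scenario.name + "_replay")
    return run_scenario(rep)


# ---------------------------------------------------------------------------
# the nested growth loops
# ---------------------------------------------------------------------------

_GROWTH_COLUMNS = ["time_min", "mu_ref", "mu_hat", "mu_true", "u_green_pct",
                   "u_red_pct", "od", "u_flow_ml_min", "u_I"]


def _run_growth(s: Scenario) -> ExperimentTrace:
    """Inner turbidity loop at ~1 Hz nested in the 1-min growth-rate PI."""
    manifest = _manifest(s)
    n_updates = int(round(s.duration / s.growth_update_min))
    if n_updates == 0:
        return ExperimentTrace(pd.DataFrame(columns=_GROWTH_COLUMNS),
                               manifest=manifest)
    rng = np.random.default_rng(np.random.SeedSequence(s.seed))
    dt = 1.0 / 60.0                       # 1 Hz pump sampling, in minutes
    inner_per_update = int(round(s.growth_update_min / dt))
    turb = s.turbidostat
    growth = s.growth_plant
    signal = GrowthSignal(dt_min=dt)
    pi_state = PIState()
    cfg = s.pi_config
    u_green = 100.0 * (growth.mu - growth.mu_min) / \
        (growth.mu_max - growth.mu_min) if growth.mu > growth.mu_min else 0.0
    mu_hat = growth.mu
    rows = []
    for m in range(n_updates):
        t = m * s.growth_update_min
        mu_ref = float(s.reference(t))
        u_green, u_red, pi_state = growth_pi_step(cfg, pi_state, mu_ref,
                                                  mu_hat)
        for _ in range(inner_per_update):
            turb = turbidostat_step(turb, growth.mu, dt)
            raw = turb.u_flow
            if s.pump_noise_sd > 0:
                raw += s.pump_noise_sd * rng.standard_normal()
            mu_hat, signal = estimate_growth_rate(signal, raw, turb.V)
            growth = growth_plant_step(growth, u_green, dt)
        rows.append({"time_min": t, "mu_ref": mu_ref, "mu_hat": mu_hat,
                     "mu_true": growth.mu, "u_green_pct": u_green,
                     "u_red_pct": u_red, "od": turb.x,
                     "u_flow_ml_min": turb.u_flow, "u_I": pi_state.u_I})
    return ExperimentTrace(pd.DataFrame(rows, columns=_GROWTH_COLUMNS),
                           manifest=manifest)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackingMetrics:
    fraction_in_band: float
    settling_time: float | None
    steady_state_error: float
    rms_error: float
    amplitude_ratio: float | None = None
    phase_deg: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_in_band <= 1.0):
            raise ValueError("fraction_in_band must lie in [0, 1]")
        if self.phase_deg is not None and not (-360 < self.phase_deg <= 360):
            raise ValueError("phase must lie in (-360, 360]")


def _post_transient_start(in_band: np.ndarray, sustain: int = 3) -> int | None:
    run = 0
    for i, ok in enumerate(in_band):
        run = run + 1 if ok else 0
        if run >= sustain:
            return i - sustain + 1
    return None


def tracking_metrics(trace: ExperimentTrace, reference: ReferenceProfile,
                     column: str = "measurement") -> TrackingMetrics:
    """Score a trace against its reference profile.

    Band membership uses the profile's band convention; the post-transient
    region begins at the first band entry sustained for three samples.
    Sinusoid references additionally get an amplitude ratio and a phase
    from the lag maximizing the cross-correlation with the reference.
    """
    df = trace.data
    if len(df) < 2:
        raise ValueError("need at least 2 samples")
    t = df["time_min"].to_numpy(float)
    y = df[column].to_numpy(float)
    r = np.asarray(reference(t), dtype=float)
    band = reference.band_halfwidth(t)
    err = y - r
    in_band = np.abs(err) <= band
    start = _post_transient_start(in_band)
    if start is None:
        frac, rms = 0.0, float(np.sqrt(np.mean(err ** 2)))
        settling = None
    else:
        frac = float(np.mean(in_band[start:]))
        rms = float(np.sqrt(np.mean(err[start:] ** 2)))
        settling = float(t[start])
    tail = max(2, len(y) // 10)
    sse = float(np.mean(np.abs(err[-tail:])))
    amp = phase = None
    if reference.kind == "sinusoid":
        sel = slice(start, None) if start is not None else slice(None)
        amp, phase = _sinusoid_fit(t[sel], y[sel], reference)
    return TrackingMetrics(fraction_in_band=frac, settling_time=settling,
                           steady_state_error=sse, rms_error=rms,
                           amplitude_ratio=amp, phase_deg=phase)


def _sinusoid_fit(t: np.ndarray, y: np.ndarray, ref: ReferenceProfile
                  ) -> tuple[float, float]:
    """Amplitude ratio and phase lag (deg) of y against the reference
    sinusoid; the quadrature regression is the continuous-lag maximizer of
    the cross-correlation with the reference."""
    w = 2.0 * np.pi / ref.period
    X = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b = beta[0], beta[1]
    amp_out = math.hypot(a, b)
    psi = math.atan2(b, a)        # y ~ amp * sin(w t + psi)
    phase = (-math.degrees(psi)) % 360.0
    ratio = amp_out / ref.amplitude if ref.amplitude > 0 else math.inf
    return float(ratio), float(phase)


# ---------------------------------------------------------------------------
# the preset scenario library
# ---------------------------------------------------------------------------

def _pi_sched() -> PIConfig:
    return PIConfig(K_P=80.0, K_I=8.0,
                    schedule=(ScheduleStage(K_P=160.0, K_I=20.0,
                                            at_time=240.0),))


def make_preset(name: str, seed: int = 0) -> Scenario:
    """Named scenarios mirroring the platform's experiments."""
    nominal = Plant()
    if name == "setpoints_pi":
        return Scenario(name=name, controller="pi",
                        pi_config=PIConfig(K_P=80.0, K_I=8.0),
                        reference=ReferenceProfile(kind="constant", level=2.0),
                        duration=600.0, seed=seed)
    if name == "setpoints_mpc":
        return Scenario(name=name, controller="mpc",
                        reference=ReferenceProfile(kind="constant", level=1.5),
                        duration=600.0, seed=seed)
    if name == "sinusoid_2h":
        return Scenario(name=name, controller="pi",
                        pi_config=PIConfig(K_P=80.0, K_I=8.0),
                        reference=ReferenceProfile(
                            kind="sinusoid", mean=2.0, amplitude=0.15,
                            period=120.0, band_convention="reference"),
                        measurement=MeasurementModel(mode="none"),
                        duration=1440.0, seed=seed)
    if name == "sinusoid_2h_mpc":
        return Scenario(name=name, controller="mpc",
                        reference=ReferenceProfile(
                            kind="sinusoid", mean=2.0, amplitude=0.15,
                            period=120.0, band_convention="reference"),
                        duration=720.0, seed=seed)
    if name == "piecewise":
        ref = ReferenceProfile(kind="piecewise_linear",
                               breakpoints=((0.0, 1.4), (180.0, 1.4),
                                            (480.0, 2.0), (720.0, 2.0)),
                               band_convention="max")
        return Scenario(name=name, controller="mpc", reference=ref,
                        duration=720.0, seed=seed)
    if name in ("medium_shift", "medium_shift_frozen"):
        plant = Plant(params=ModelParams(d_p=math.log(2.0) / 38.0),
                      events=(DisturbanceEvent(kind="medium_shift",
                                               onset=300.0,
                                               new_doubling_time=25.0),))
        base = Scenario(name=name, plant=plant, controller="mpc",
                        reference=ReferenceProfile(kind="constant",
                                                   level=1.35),
                        duration=720.0, seed=seed)
        if name.endswith("frozen"):
            base = replace(base, freeze_at=300.0)
        return base
    if name in ("temp_shift", "temp_shift_frozen"):
        plant = Plant(events=(DisturbanceEvent(kind="temperature_shift",
                                               onset=300.0),))
        base = Scenario(name=name, plant=plant, controller="mpc",
                        reference=ReferenceProfile(kind="constant", level=1.8),
                        duration=900.0, seed=seed)
        if name.endswith("frozen"):
            base = replace(base, freeze_at=300.0)
        return base
    if name in ("input_minus50", "input_minus50_frozen"):
        plant = Plant(events=(DisturbanceEvent(kind="input_offset",
                                               onset=300.0, fraction=0.5),))
        base = Scenario(name=name, plant=plant, controller="pi",
                        pi_config=_pi_sched(),
                        reference=ReferenceProfile(kind="constant", level=2.0),
                        measurement=MeasurementModel(mode="none"),
                        duration=600.0, seed=seed)
        if name.endswith("frozen"):
            base = replace(base, freeze_at=300.0)
        return base
    if name == "growth_setpoints":
        return Scenario(name=name, controller="growth_pi",
                        pi_config=GROWTH_PI_CONFIG,
                        reference=ReferenceProfile(kind="constant",
                                                   level=0.009),
                        growth_plant=GrowthPlantState(mu=0.0139),
                        duration=720.0, seed=seed)
    if name == "growth_drift":
        return Scenario(name=name, controller="growth_pi",
                        pi_config=GROWTH_PI_CONFIG,
                        reference=ReferenceProfile(kind="constant",
                                                   level=0.009),
                        growth_plant=GrowthPlantState(mu=0.0139,
                                                      drift_rate=2e-6,
                                                      drift_onset_min=360.0),
                        duration=1440.0, seed=seed)
    raise KeyError(f"unknown preset {name!r}")


PRESETS = ("setpoints_pi", "setpoints_mpc", "sinusoid_2h", "sinusoid_2h_mpc",
           "piecewise", "medium_shift", "medium_shift_frozen", "temp_shift",
           "temp_shift_frozen", "input_minus50", "input_minus50_frozen",
           "growth_setpoints", "growth_drift")


# ---------------------------------------------------------------------------
# config I/O and provenance
# ---------------------------------------------------------------------------

def _manifest(s: Scenario) -> dict:
    return {"name": s.name, "seed": s.seed, "controller": s.controller,
            "duration_min": s.duration,
            "T_s": s.plant.params.T_s, "version": 1}


def scenario_to_yaml(s: Scenario, path) -> None:
    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj
    doc = {
        "name": s.name, "controller": s.controller, "duration": s.duration,
        "seed": s.seed, "day_variability_sigma": s.day_variability_sigma,
        "freeze_at": s.freeze_at,
        "plant": {"params": clean(s.plant.params),
                  "dose_response": clean(s.plant.dose_response),
                  "disturbances": [clean(e) for e in s.plant.events]},
        "pi": clean(s.pi_config), "mpc": {
            "horizon": s.mpc_config.horizon, "U_cap": s.mpc_config.U_cap,
            "du_weight": s.mpc_config.du_weight},
        "pf": clean(s.pf_config),
        "reference": clean(s.reference),
        "measurement": clean(s.measurement),
        "replay_inputs": [float(u) for u in s.replay_inputs],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path) -> Scenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if "preset" in doc:
        return make_preset(doc["preset"], seed=int(doc.get("seed", 0)))
    plant_doc = doc.get("plant", {})
    params = ModelParams(**plant_doc.get("params", {}))
    from .gene_plant import DoseResponse
    dr_doc = plant_doc.get("dose_response")
    dose = DoseResponse(**dr_doc) if dr_doc else DEFAULT_DOSE_RESPONSE
    events = tuple(DisturbanceEvent(**e)
                   for e in plant_doc.get("disturbances", []))
    plant = Plant(params=params, dose_response=dose, events=events)
    pi_doc = dict(doc.get("pi", {}))
    sched = tuple(ScheduleStage(**st) for st in pi_doc.pop("schedule", []))
    if "clamp" in pi_doc:
        pi_doc["clamp"] = tuple(pi_doc["clamp"])
    pi = PIConfig(schedule=sched, **pi_doc)
    mpc = MPCConfig(**doc.get("mpc", {}))
    pf_doc = dict(doc.get("pf", {}))
    if "d_bounds" in pf_doc:
        pf_doc["d_bounds"] = tuple(pf_doc["d_bounds"])
    pf = PFConfig(**pf_doc)
    ref_doc = dict(doc.get("reference", {}))
    if "breakpoints" in ref_doc:
        ref_doc["breakpoints"] = tuple(tuple(b) for b in ref_doc["breakpoints"])
    ref = ReferenceProfile(**ref_doc)
    meas_doc = dict(doc.get("measurement", {}))
    if "calibration" in meas_doc:
        meas_doc["calibration"] = CytometryCalibration(
            **meas_doc["calibration"])
    meas = MeasurementModel(**meas_doc)
    return Scenario(name=doc.get("name", "scenario"), plant=plant,
                    controller=doc.get("controller", "pi"), pi_config=pi,
                    mpc_config=mpc, pf_config=pf, reference=ref,
                    measurement=meas, duration=float(doc.get("duration", 600)),
                    seed=int(doc.get("seed", 0)),
                    day_variability_sigma=float(
                        doc.get("day_variability_sigma", 0.0)),
                    freeze_at=doc.get("freeze_at"),
                    replay_inputs=tuple(doc.get("replay_inputs", [])))
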