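"""Synthetic flow-cytometry event clouds and their reduction to the scalar
"average of normalized sfGFP" fed back to the controllers.

An event table carries per-event FSC-H, FSC-A, SSC-A and FL1-A (arbitrary
units).  Processing follows the acquisition pipeline of the platform:
events below an FSC-H instrument-noise threshold (11,000 a.u.) or an FL1
threshold (800 a.f.u.) or outside a wide elliptical gate in FSC-A x SSC-A
space are discarded, fluorescence is normalized by FSC-H (a cell-volume
proxy) and the sample mean of the normalized values summarizes the culture.

The generator draws correlated log-normal scatter channels with
``FL1 = FSC-H * (background + gain * G) * noise`` so the expected
normalized mean is ``background + gain * G`` for a true population fold
change ``G``, reproducing the positive size-fluorescence coupling of real
data.  Tables interchange as CSV with the channel names as columns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "GateConfig",
    "DEFAULT_GATE",
    "CytometrySample",
    "CytometryCalibration",
    "gate_events",
    "normalized_mean",
    "synthesize_sample",
]

CHANNELS = ("FSC-H", "FSC-A", "SSC-A", "FL1-A")
ACQUISITION_CAP = 20_000


@dataclass(frozen=True)
class EventTable:
    """Per-event channel table; wraps a DataFrame with the four channels."""

    data: pd.DataFrame
    warning: str | None = None

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing channels: {missing}")
        vals = self.data[list(CHANNELS)].to_numpy(float)
        if vals.size and (not np.all(np.isfinite(vals)) or np.any(vals < 0)):
            raise ValueError("all channels must be finite and >= 0")
        if len(self.data) > ACQUISITION_CAP:
            raise ValueError(f"event count exceeds acquisition cap "
                             f"{ACQUISITION_CAP}")

    def __len__(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_arrays(cls, fsc_h, fsc_a, ssc_a, fl1) -> "EventTable":
        return cls(pd.DataFrame({"FSC-H": fsc_h, "FSC-A": fsc_a,
                                 "SSC-A": ssc_a, "FL1-A": fl1}))


@dataclass(frozen=True)
class GateConfig:
    """Thresholds plus an elliptical gate in FSC-A x SSC-A space.

    The ellipse is ``((x-cx) cos r + (y-cy) sin r)^2 / a^2 +
    (-(x-cx) sin r + (y-cy) cos r)^2 / b^2 <= 1``.  The exact instrument
    ellipse is not published; the default is a permissive gate around the
    synthetic cell cluster retaining roughly three quarters of generated
    events (about 15,000 of 20,000).
    """

    fsc_h_threshold: float = 11_000.0
    fl1_threshold: float = 800.0
    center_x: float = 52_000.0
    center_y: float = 20_000.0
    semi_axis_x: float = 40_000.0
    semi_axis_y: float = 18_000.0
    rotation: float = 0.35

    def __post_init__(self) -> None:
        if self.fsc_h_threshold < 0 or self.fl1_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise ValueError("semi-axes must be positive")

    def ellipse_mask(self, fsc_a: np.ndarray, ssc_a: np.ndarray) -> np.ndarray:
        dx = np.asarray(fsc_a, float) - self.center_x
        dy = np.asarray(ssc_a, float) - self.center_y
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        xr = dx * c + dy * s
        yr = -dx * s + dy * c
        return (xr / self.semi_axis_x) ** 2 + (yr / self.semi_axis_y) ** 2 <= 1.0


DEFAULT_GATE = GateConfig()


@dataclass(frozen=True)
class CytometryCalibration:
    """Per-day measurement calibration: normalized_mean = background + gain*G."""

    background: float = 0.0
    gain: float = 0.15
    cv: float = 0.25  # per-event coefficient of variation of FL1 noise

    def __post_init__(self) -> None:
        if self.background < 0 or self.gain <= 0:
            raise ValueError("background must be >= 0 and gain > 0")
        if self.cv < 0:
            raise ValueError("CV must be >= 0")


def gate_events(events: EventTable, cfg: GateConfig = DEFAULT_GATE
                ) -> EventTable:
    """Drop events failing a threshold or the ellipse; order preserved."""
    df = events.data
    if len(df) == 0:
        warnings.warn("gating an empty event table")
        return EventTable(df.copy(), warning="empty input")
    keep = ((df["FSC-H"].to_numpy(float) >= cfg.fsc_h_threshold)
            & (df["FL1-A"].to_numpy(float) >= cfg.fl1_threshold)
            & cfg.ellipse_mask(df["FSC-A"].to_numpy(float),
                               df["SSC-A"].to_numpy(float)))
    out = df.loc[keep].reset_index(drop=True)
    warning = "no events survived the gate" if len(out) == 0 else None
    if warning:
        warnings.warn(warning)
    return EventTable(out, warning=warning)


def normalized_mean(events: EventTable) -> float:
    """Arithmetic mean of per-event FL1-A / FSC-H.

    Zero events is a measurement failure: raises so the caller can fall
    back on the previous measurement (the controllers accept ``None``).
    """
    if len(events) == 0:
        raise ValueError("measurement failure: no events")
    fl1 = events.data["FL1-A"].to_numpy(float)
    fsc = events.data["FSC-H"].to_numpy(float)
    if np.any(fsc <= 0):
        raise ValueError("FSC-H must be positive for normalization")
    return float(np.mean(fl1 / fsc))


@dataclass(frozen=True)
class CytometrySample:
    """A gated event table with its stored scalar summary and timestamp."""

    events: EventTable
    normalized_mean: float
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if self.normalized_mean < 0:
            raise ValueError("normalized mean must be >= 0")
        recomputed = normalized_mean(self.events)
        if recomputed != self.normalized_mean:
            raise ValueError("stored summary does not match the gated table")

    @classmethod
    def from_events(cls, events: EventTable, timestamp: float = 0.0,
                    gate: GateConfig = DEFAULT_GATE) -> "CytometrySample":
        gated = gate_events(events, gate)
        return cls(events=gated, normalized_mean=normalized_mean(gated),
                   timestamp=timestamp)


def synthesize_sample(true_G: float, calib: CytometryCalibration,
                      n_events: int = ACQUISITION_CAP,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> EventTable:
    """Draw a synthetic event cloud for a population at fold change true_G.

    FSC-H is log-normal (median 40,000 a.u., log-sd 0.35); FSC-A and SSC-A
    are correlated log-normal companions; FL1 couples fluorescence to cell
    size with mean-one multiplicative noise of coefficient of variation
    ``calib.cv``, so the expected FL1/FSC-H equals
    ``background + gain * true_G``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if true_G < 0:
        raise ValueError("true_G must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_events, 3))
    fsc_h = 40_000.0 * np.exp(0.35 * z[:, 0])
    # FSC-A tracks FSC-H closely; SSC-A is correlated with cell size
    fsc_a = fsc_h * np.exp(0.10 + 0.12 * z[:, 1])
    ssc_a = 15_000.0 * np.exp(0.45 * (0.6 * z[:, 0] + 0.8 * z[:, 2]))
    level = calib.background + calib.gain * true_G
    if calib.cv > 0:
        sigma = math.sqrt(math.log(1.0 + calib.cv ** 2))
        noise = rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma,
                              size=n_events)
    else:
        noise = np.ones(n_events)
    fl1 = fsc_h * level * noise
    return EventTable.from_arrays(fsc_h, fsc_a, ssc_a, fl1)
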