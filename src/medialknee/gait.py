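"""Scalar gait-feature computations on force-plate and CoP signals.

Implements the signal-level conventions of the study design this package
serves: stance detected as the longest contiguous interval with vertical
ground reaction force above 20 N, zero-lag Butterworth filtering (50 Hz for
kinetics, 6 Hz for kinematics), the foot progression angle as the heading
of the chord between the centre of pressure at initial contact and at
toe-off (positive toe-out), daily loading cycles from a modelled daily
walking distance and the stride length, and the cumulative load as
stance-mean force per unit stride.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "Trajectory",
    "NoStanceError",
    "detect_stance",
    "lowpass_filter",
    "foot_progression_angle",
    "daily_loading_cycles",
    "cumulative_load",
    "cop_offset_at_peak",
]


class NoStanceError(ValueError):
    """Raised when no sample exceeds the stance force threshold."""


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled signal: times (s) and one or more channels.

    ``values`` has shape (n,) for a single channel or (n, k); mm for CoP
    channels, N for forces.
    """

    times: np.ndarray
    values: np.ndarray
    channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or times.size < 2:
            raise ValueError("times must be a 1-D array of at least 2 samples")
        if values.shape[0] != times.size:
            raise ValueError("values and times lengths differ")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if np.ptp(dt) > 1e-6 * np.mean(dt) + 1e-12:
            raise ValueError("sampling must be uniform")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def rate(self) -> float:
        return 1.0 / self.dt

    def channel(self, name_or_index) -> np.ndarray:
        vals = self.values if self.values.ndim > 1 else self.values[:, None]
        if isinstance(name_or_index, str):
            idx = self.channels.index(name_or_index)
        else:
            idx = int(name_or_index)
        return vals[:, idx]

    def to_frame(self) -> pd.DataFrame:
        vals = self.values if self.values.ndim > 1 else self.values[:, None]
        names = self.channels or tuple(f"ch{i}" for i in range(vals.shape[1]))
        df = pd.DataFrame(vals, columns=list(names))
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        times = df["time_s"].to_numpy()
        chans = tuple(c for c in df.columns if c != "time_s")
        values = df[list(chans)].to_numpy()
        if values.shape[1] == 1:
            values = values[:, 0]
        return cls(times=times, values=values, channels=chans)


def detect_stance(
    vertical_grf: Trajectory, threshold: float = 20.0
) -> tuple[int, int]:
    """First and last sample indices of the longest contiguous interval
    with vertical GRF above ``threshold`` N (closed interval, 0-based)."""
    force = np.asarray(vertical_grf.values, dtype=float)
    if force.ndim != 1:
        force = vertical_grf.channel(0)
    above = force > threshold
    if not np.any(above):
        raise NoStanceError(
            f"no sample exceeds the {threshold} N stance threshold"
        )
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    starts, stops = edges[::2], edges[1::2]
    longest = int(np.argmax(stops - starts))
    return int(starts[longest]), int(stops[longest] - 1)


def lowpass_filter(
    x: Trajectory, cutoff: float, order: int = 4, zero_lag: bool = True
) -> Trajectory:
    """Butterworth low-pass of the given design order.

    With ``zero_lag`` the filter is applied forward and backward
    (``filtfilt``), doubling the effective order and cancelling the phase
    shift; this is the standard treatment for gait kinetics/kinematics.
    """
    nyquist = 0.5 * x.rate
    if cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {nyquist} Hz"
        )
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sos = _signal.butter(order, cutoff, btype="low", fs=x.rate, output="sos")
    vals = np.asarray(x.values, dtype=float)
    if zero_lag:
        filtered = _signal.sosfiltfilt(sos, vals, axis=0)
    else:
        filtered = _signal.sosfilt(sos, vals, axis=0)
    return Trajectory(times=x.times, values=filtered, channels=x.channels)


def foot_progression_angle(
    cop: Trajectory, contact_index: int, toeoff_index: int
) -> float:
    """Signed angle (degrees) between the initial-contact -> toe-off CoP
    chord and the anterior axis; positive = toe-out (lateral heading).

    Expects a two-channel trajectory ordered (mediolateral, anterior), with
    mediolateral positive toward lateral.
    """
    n = cop.times.size
    for idx in (contact_index, toeoff_index):
        if not (0 <= idx < n):
            raise IndexError(f"index {idx} outside trajectory of length {n}")
    ml = cop.channel("ml") if "ml" in cop.channels else cop.channel(0)
    ap = cop.channel("ap") if "ap" in cop.channels else cop.channel(1)
    d_ml = ml[toeoff_index] - ml[contact_index]
    d_ap = ap[toeoff_index] - ap[contact_index]
    if d_ml == 0.0 and d_ap == 0.0:
        raise ValueError("zero-length CoP chord: cannot define a heading")
    return math.degrees(math.atan2(d_ml, d_ap))


def daily_loading_cycles(
    stride_length: float, daily_distance: float = 6000.0, count: str = "steps"
) -> float:
    """Daily loading cycles from a modelled walking distance.

    ``count="steps"`` (default) counts two loading cycles per stride,
    2 x distance / stride; ``count="strides"`` counts distance / stride.
    """
    if stride_length <= 0:
        raise ValueError("stride_length must be positive")
    if daily_distance < 0:
        raise ValueError("daily_distance must be non-negative")
    if count not in ("steps", "strides"):
        raise ValueError("count must be 'steps' or 'strides'")
    factor = 2.0 if count == "steps" else 1.0
    return factor * daily_distance / stride_length


def cumulative_load(mean_stance_force: float, stride_length: float) -> float:
    """Cumulative load per unit distance: stance-mean force / stride (BW/m)."""
    if stride_length <= 0:
        raise ValueError("stride_length must be positive")
    if mean_stance_force < 0:
        raise ValueError("mean_stance_force must be non-negative")
    return mean_stance_force / stride_length


def cop_offset_at_peak(
    cop_ml: Trajectory, foot_com_ml: Trajectory, peak_index: int
) -> float:
    """Mediolateral CoP position relative to the foot centre of mass (mm)
    at the sample of peak contact force; positive = CoP lateral of the CoM."""
    if cop_ml.times.size != foot_com_ml.times.size or not np.allclose(
        cop_ml.times, foot_com_ml.times
    ):
        raise ValueError("trajectories must share the same time base")
    n = cop_ml.times.size
    if not (0 <= peak_index < n):
        raise IndexError(f"peak_index {peak_index} outside length {n}")
    cop = cop_ml.values if cop_ml.values.ndim == 1 else cop_ml.channel(0)
    com = (
        foot_com_ml.values
        if foot_com_ml.values.ndim == 1
        else foot_com_ml.channel(0)
    )
    return float(cop[peak_index] - com[peak_index])
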