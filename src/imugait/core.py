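"""Shared domain containers for multi-placement IMU walking trials.

A trial is one walk recorded by seven inertial sensors (lower back L5, both
feet, both shanks, both thighs), each delivering a synchronized triaxial
accelerometer (units: g) and triaxial gyroscope (units: deg/s) at a common
sampling rate.  Axis convention: x = mediolateral, y = vertical,
z = anteroposterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The seven sensor placements, in canonical order.
PLACEMENTS: tuple[str, ...] = (
    "L5",
    "foot_L",
    "foot_R",
    "shank_L",
    "shank_R",
    "thigh_L",
    "thigh_R",
)

SENSORS: tuple[str, str] = ("acc", "gyr")
AXES: tuple[str, str, str] = ("x", "y", "z")
SIDES: tuple[str, str] = ("L", "R")
GROUPS: tuple[str, ...] = ("healthy", "stroke", "other_neuro")

#: Default sampling rate of the emulated hardware, Hz.
DEFAULT_FS: float = 148.0


def channel_columns() -> list[str]:
    """Canonical CSV column names for the 42 data channels."""
    return [f"{p}_{s}_{a}" for p in PLACEMENTS for s in SENSORS for a in AXES]


def other_side(side: str) -> str:
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}; expected one of {SIDES}")
    return "L" if side == "R" else "R"


@dataclass
class SensorStream:
    """One placement's synchronized accelerometer + gyroscope record.

    ``accel`` and ``gyro`` are arrays of shape (3, n_samples) holding the
    x/y/z axes in g and deg/s respectively.
    """

    placement: str
    accel: np.ndarray
    gyro: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise ValueError(
                f"unknown placement {self.placement!r}; expected one of {PLACEMENTS}"
            )
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        for name, arr in (("accel", self.accel), ("gyro", self.gyro)):
            if arr.ndim != 2 or arr.shape[0] != 3:
                raise ValueError(f"{name} must have shape (3, n_samples), got {arr.shape}")
        if self.accel.shape[1] != self.gyro.shape[1]:
            raise ValueError("accelerometer and gyroscope must have equal length")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.accel.shape[1]

    def channel(self, sensor: str, axis: str) -> np.ndarray:
        """Return one axis of one sensor as a 1-D view."""
        arr = {"acc": self.accel, "gyr": self.gyro}[sensor]
        return arr[AXES.index(axis)]


@dataclass
class Trial:
    """One walking trial: the seven placements' streams plus identity."""

    subject_id: str
    trial_id: str
    group_label: str
    streams: dict[str, SensorStream] = field(repr=False)

    def __post_init__(self) -> None:
        missing = [p for p in PLACEMENTS if p not in self.streams]
        if missing:
            raise ValueError(f"trial is missing placements: {missing}")
        extra = [p for p in self.streams if p not in PLACEMENTS]
        if extra:
            raise ValueError(f"trial has unknown placements: {extra}")
        lengths = {s.n_samples for s in self.streams.values()}
        rates = {s.fs for s in self.streams.values()}
        if len(lengths) != 1:
            raise ValueError(f"placements disagree on length: {sorted(lengths)}")
        if len(rates) != 1:
            raise ValueError(f"placements disagree on sampling rate: {sorted(rates)}")

    @property
    def fs(self) -> float:
        return next(iter(self.streams.values())).fs

    @property
    def n_samples(self) -> int:
        return next(iter(self.streams.values())).n_samples

    def channel(self, placement: str, sensor: str, axis: str) -> np.ndarray:
        return self.streams[placement].channel(sensor, axis)
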