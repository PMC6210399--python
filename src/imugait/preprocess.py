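"""Trial CSV reading and zero-phase Butterworth band-pass filtering.

Every channel is filtered with a fourth-order Butterworth band-pass applied
forward and backward (zero phase, effective eighth-order magnitude response):
1–20 Hz for accelerometer channels and 0.25–30 Hz for gyroscope channels.
Edges are handled by odd-symmetric signal extension so that the first and
last strides — the only ones used downstream — are not distorted by filter
transients.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .core import PLACEMENTS, SensorStream, Trial, channel_columns

__all__ = [
    "ACC_BAND",
    "GYR_BAND",
    "read_trial_csv",
    "bandpass",
    "filter_trial",
    "TrialFilter",
]

#: Default pass bands, Hz.
ACC_BAND: tuple[float, float] = (1.0, 20.0)
GYR_BAND: tuple[float, float] = (0.25, 30.0)
DEFAULT_ORDER: int = 4


def read_trial_csv(
    path: str | Path,
    subject_id: str | None = None,
    trial_id: str | None = None,
    group_label: str = "unknown",
) -> Trial:
    """Read a trial CSV written by :func:`imugait.simulate.write_trial_csv`.

    The file must contain ``time_s`` plus all 42 ``<placement>_<acc|gyr>_<x|y|z>``
    columns; the sampling rate is recovered from the time column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty trial file") from exc
    expected = channel_columns()
    missing = [c for c in ["time_s"] + expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    if len(df) < 2:
        raise ValueError(f"{path}: too few samples to define a sampling rate")
    non_numeric = [
        c for c in ["time_s"] + expected
        if not np.issubdtype(df[c].dtype, np.number)
    ]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric values in columns: {non_numeric}")
    if df[expected].isna().any().any():
        raise ValueError(f"{path}: missing values in channel columns")
    dt = np.median(np.diff(df["time_s"].to_numpy()))
    if not dt > 0:
        raise ValueError(f"{path}: time_s column is not increasing")
    fs = 1.0 / dt
    streams = {}
    for placement in PLACEMENTS:
        accel = df[[f"{placement}_acc_{a}" for a in "xyz"]].to_numpy().T
        gyro = df[[f"{placement}_gyr_{a}" for a in "xyz"]].to_numpy().T
        streams[placement] = SensorStream(placement, accel, gyro, fs)
    return Trial(
        subject_id=subject_id or path.stem,
        trial_id=trial_id or path.stem,
        group_label=group_label,
        streams=streams,
    )


def bandpass(
    x: np.ndarray,
    fs: float,
    low: float,
    high: float,
    order: int = DEFAULT_ORDER,
    padtype: str = "odd",
    padlen: int | None = None,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter (forward–backward).

    ``order`` is the design order of the underlying Butterworth filter; the
    bidirectional application squares its magnitude response.  Output length
    equals input length.
    """
    x = np.asarray(x, dtype=float)
    if not 0 < low < high < fs / 2:
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2, got ({low}, {high}) at fs={fs}"
        )
    if order < 1:
        raise ValueError("filter order must be >= 1")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    if padlen is None:
        ntaps = 2 * order + 1  # equivalent (b, a) length of the cascade
        padlen = 3 * ntaps
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"signal too short for stable bidirectional filtering: "
            f"need > {padlen} samples, got {x.shape[-1]}"
        )
    return sps.sosfiltfilt(sos, x, padtype=padtype, padlen=padlen)


def filter_trial(
    trial: Trial,
    acc_band: tuple[float, float] = ACC_BAND,
    gyr_band: tuple[float, float] = GYR_BAND,
    order: int = DEFAULT_ORDER,
) -> Trial:
    """Return a new trial with every channel band-pass filtered.

    Accelerometer channels use ``acc_band``, gyroscope channels ``gyr_band``.
    """
    fs = trial.fs
    streams = {}
    for placement, stream in trial.streams.items():
        accel = bandpass(stream.accel, fs, *acc_band, order=order)
        gyro = bandpass(stream.gyro, fs, *gyr_band, order=order)
        streams[placement] = SensorStream(placement, accel, gyro, fs)
    return Trial(trial.subject_id, trial.trial_id, trial.group_label, streams)


class TrialFilter(TransformerMixin, BaseEstimator):
    """Stateless sklearn-style transformer applying :func:`filter_trial`.

    ``X`` is a list of :class:`~imugait.core.Trial`; ``transform`` returns a
    new list of filtered trials.
    """

    def __init__(
        self,
        acc_band: tuple[float, float] = ACC_BAND,
        gyr_band: tuple[float, float] = GYR_BAND,
        order: int = DEFAULT_ORDER,
    ):
        self.acc_band = acc_band
        self.gyr_band = gyr_band
        self.order = order

    def fit(self, X, y=None):
        self.n_features_in_ = 1  # object input; no tabular features
        return self

    def transform(self, X):
        return [
            filter_trial(t, acc_band=self.acc_band, gyr_band=self.gyr_band, order=self.order)
            for t in X
        ]
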