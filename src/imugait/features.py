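"""Stride segmentation, 101-point time normalization and feature matrices.

Each channel is segmented into the stride of its own side (IC to the next
ipsilateral IC; the lower-back L5 sensor contributes to both strides), every
segment is linearly resampled onto a fixed 101-point percentage-of-cycle
grid, and four time-domain statistics (mean, variance, kurtosis, standard
deviation) are computed per normalized cycle.

Feature-set modes and their column counts:

* ``time_domain`` — 192 = 2 strides x (ipsilateral foot + shank + thigh,
  plus L5) x 6 channels x 4 statistics;
* ``temporal`` — the 17 temporal gait parameters;
* ``combined`` — 209 = 192 + 17;
* ``placement:L5|foot|shank|thigh`` — 65 = 48 time-domain (two
  sensors-or-cycles x 6 channels x 4 statistics) + 17 temporal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from sklearn.base import BaseEstimator, TransformerMixin

from .core import AXES, SENSORS, Trial
from .events import GaitSequence
from .temporal import TEMPORAL_FEATURE_NAMES, compute_temporal_params, temporal_feature_vector

__all__ = [
    "MODES",
    "STATS",
    "N_CYCLE_POINTS",
    "FeatureMatrix",
    "segment_cycle",
    "time_normalize",
    "time_domain_stats",
    "feature_manifest",
    "extract_trial_features",
    "build_feature_matrix",
    "CycleFeatureExtractor",
]

logger = logging.getLogger(__name__)

N_CYCLE_POINTS: int = 101
STATS: tuple[str, ...] = ("mean", "variance", "kurtosis", "std")
MODES: tuple[str, ...] = (
    "time_domain",
    "temporal",
    "combined",
    "placement:L5",
    "placement:foot",
    "placement:shank",
    "placement:thigh",
)

#: Stride order within a feature row (right stride first, then left).
_STRIDE_SIDES: tuple[str, str] = ("R", "L")


def segment_cycle(channel: np.ndarray, ic_start: int, ic_next: int) -> np.ndarray:
    """Samples of one stride cycle, half-open ``[ic_start, ic_next)``.

    Half-open so consecutive cycles tile the signal without overlap.
    """
    channel = np.asarray(channel)
    if not 0 <= ic_start < ic_next <= len(channel):
        raise ValueError(
            f"invalid cycle bounds [{ic_start}, {ic_next}) for signal of "
            f"length {len(channel)}"
        )
    return channel[ic_start:ic_next]


def time_normalize(segment: np.ndarray, n: int = N_CYCLE_POINTS) -> np.ndarray:
    """Linearly resample a segment onto a uniform ``n``-point cycle grid.

    The first and last output points equal the segment's boundary samples.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or len(segment) < 2:
        raise ValueError("segment must be 1-D with at least 2 samples")
    grid = np.linspace(0.0, len(segment) - 1.0, n)
    return np.interp(grid, np.arange(len(segment)), segment)


def time_domain_stats(values: np.ndarray, population: bool = True) -> dict[str, float]:
    """Mean, variance, kurtosis and standard deviation of one cycle.

    Kurtosis uses the Fisher convention (normal -> 0).  Population moments
    by default (``population=False`` switches variance/std to the n-1
    denominator).  A constant cycle has undefined kurtosis, reported as 0.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 values")
    ddof = 0 if population else 1
    var = float(np.var(values, ddof=ddof))
    if np.ptp(values) == 0.0:
        logger.debug("constant cycle: kurtosis undefined, reported as 0")
        kurt = 0.0
    else:
        kurt = float(spstats.kurtosis(values, fisher=True, bias=population))
    return {
        "mean": float(np.mean(values)),
        "variance": var,
        "kurtosis": kurt,
        "std": float(np.sqrt(var)),
    }


def _mode_placements(mode: str) -> dict[str, list[str]]:
    """Per stride side, the placements contributing to that stride's features."""
    if mode in ("time_domain", "combined"):
        return {s: [f"foot_{s}", f"shank_{s}", f"thigh_{s}", "L5"] for s in _STRIDE_SIDES}
    if mode.startswith("placement:"):
        loc = mode.split(":", 1)[1]
        if loc == "L5":
            return {s: ["L5"] for s in _STRIDE_SIDES}
        if loc in ("foot", "shank", "thigh"):
            return {s: [f"{loc}_{s}"] for s in _STRIDE_SIDES}
        raise ValueError(f"unknown placement group {loc!r}")
    if mode == "temporal":
        return {s: [] for s in _STRIDE_SIDES}
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def feature_manifest(mode: str) -> list[str]:
    """Deterministic ordered feature-name list for one mode."""
    names: list[str] = []
    placements = _mode_placements(mode)
    for stride_side in _STRIDE_SIDES:
        for placement in placements[stride_side]:
            for sensor in SENSORS:
                for axis in AXES:
                    for stat in STATS:
                        names.append(
                            f"stride{stride_side}_{placement}_{sensor}_{axis}_{stat}"
                        )
    if mode != "time_domain":
        names.extend(TEMPORAL_FEATURE_NAMES)
    return names


def extract_trial_features(
    trial: Trial,
    seq: GaitSequence,
    mode: str = "time_domain",
    population: bool = True,
) -> pd.Series:
    """One trial's feature row (named, in manifest order)."""
    manifest = feature_manifest(mode)
    values: dict[str, float] = {}
    placements = _mode_placements(mode)
    for stride_side in _STRIDE_SIDES:
        lo, hi = seq.stride_bounds(stride_side)
        for placement in placements[stride_side]:
            for sensor in SENSORS:
                for axis in AXES:
                    cycle = time_normalize(
                        segment_cycle(trial.channel(placement, sensor, axis), lo, hi)
                    )
                    stats = time_domain_stats(cycle, population=population)
                    for stat in STATS:
                        values[
                            f"stride{stride_side}_{placement}_{sensor}_{axis}_{stat}"
                        ] = stats[stat]
    if mode != "time_domain":
        values.update(temporal_feature_vector(compute_temporal_params(seq)).to_dict())
    row = pd.Series(values).reindex(manifest)
    assert not row.isna().any()
    return row


@dataclass
class FeatureMatrix:
    """Labeled samples x named features for one experiment configuration."""

    frame: pd.DataFrame  # index: (subject_id, trial_id); columns: features
    labels: pd.Series  # aligned with frame.index
    mode: str
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frame.index.equals(self.labels.index):
            raise ValueError("labels must be aligned with the feature rows")
        if self.frame.isna().any().any():
            raise ValueError("feature matrix must not contain missing values")

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def X(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.labels.to_numpy()

    def subset(self, classes: list[str]) -> "FeatureMatrix":
        mask = self.labels.isin(classes).to_numpy()
        return FeatureMatrix(
            self.frame.iloc[mask], self.labels.iloc[mask], self.mode, list(self.excluded)
        )


def build_feature_matrix(
    pairs: list[tuple[Trial, GaitSequence]],
    mode: str = "time_domain",
    population: bool = True,
    excluded: list[tuple[str, str]] | None = None,
) -> FeatureMatrix:
    """Assemble the cohort feature matrix (one row per trial) for one mode."""
    manifest = feature_manifest(mode)
    rows, index, labels = [], [], []
    for trial, seq in pairs:
        rows.append(extract_trial_features(trial, seq, mode, population=population))
        index.append((trial.subject_id, trial.trial_id))
        labels.append(trial.group_label)
    idx = pd.MultiIndex.from_tuples(index, names=["subject_id", "trial_id"])
    frame = pd.DataFrame(rows, index=idx, columns=manifest)
    return FeatureMatrix(
        frame=frame,
        labels=pd.Series(labels, index=idx, name="label"),
        mode=mode,
        excluded=list(excluded or []),
    )


class CycleFeatureExtractor(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: (trial, sequence) pairs -> feature DataFrame.

    ``transform`` returns the feature ``DataFrame``; the full
    :class:`FeatureMatrix` (with labels) is kept in ``feature_matrix_``.
    """

    def __init__(self, mode: str = "time_domain", population: bool = True):
        self.mode = mode
        self.population = population

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        fm = build_feature_matrix(X, mode=self.mode, population=self.population)
        self.feature_matrix_ = fm
        self.feature_names_out_ = fm.feature_names
        return fm.frame
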