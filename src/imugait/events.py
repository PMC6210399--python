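"""Gait-event detection from filtered shank mediolateral angular velocity.

Per side, the detector finds the large positive mid-swing peaks of the shank
gyroscope mediolateral channel, then takes the nearest qualifying local
minimum before each mid-swing as the final contact (FC, toe-off) and the
nearest qualifying local minimum after it as the initial contact (IC, heel
strike).  Candidate peaks are pruned by a minimum height and a minimum
mutual distance; minima qualify when the trough dips at least
``minima_min_height`` deg/s below zero.

The bilateral events are then assembled into the canonical seven-event gait
cycle

    IC_R -> FC_L -> IC_L -> FC_R -> IC_R -> FC_L -> IC_L

which comprises exactly one right and one left stride (IC to the next
ipsilateral IC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .core import SIDES, Trial, other_side

__all__ = [
    "PeakCriteria",
    "GaitEvent",
    "SideEvents",
    "GaitSequence",
    "SequenceError",
    "detect_midswing",
    "detect_ic_fc",
    "side_events",
    "detect_trial_events",
    "assemble_sequence",
    "detect_gait_sequence",
    "GaitEventDetector",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakCriteria:
    """Minimum peak height / mutual distance criteria for event detection.

    Defaults are the values selected to prevent wrong IC/FC detections:
    30 samples and 100 deg/s for the mid-swing maxima, 50 samples and
    30 deg/s for the flanking minima.
    """

    ms_min_height: float = 100.0  # deg/s
    ms_min_distance: int = 30  # samples
    minima_min_height: float = 30.0  # deg/s below zero
    minima_min_distance: int = 50  # samples

    def __post_init__(self) -> None:
        if min(
            self.ms_min_height,
            self.ms_min_distance,
            self.minima_min_height,
            self.minima_min_distance,
        ) <= 0:
            raise ValueError("all peak criteria must be positive")


@dataclass(frozen=True, order=True)
class GaitEvent:
    time: float  # s; first field so events sort chronologically
    index: int  # sample
    side: str  # L | R
    kind: str  # IC | FC | MS


@dataclass
class SideEvents:
    """Detected events of one side, as sample indices."""

    side: str
    fs: float
    ms: np.ndarray
    ic: np.ndarray
    fc: np.ndarray
    invalid_ms: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def as_events(self) -> list[GaitEvent]:
        out = [GaitEvent(i / self.fs, int(i), self.side, "IC") for i in self.ic]
        out += [GaitEvent(i / self.fs, int(i), self.side, "FC") for i in self.fc]
        return sorted(out)


class SequenceError(ValueError):
    """Bilateral events do not form the expected seven-event pattern."""


def _prune_by_distance(
    indices: np.ndarray, values: np.ndarray, min_distance: int
) -> np.ndarray:
    """Greedy distance pruning: keep the higher peak, ties to the earlier."""
    if len(indices) == 0:
        return indices
    order = np.lexsort((indices, -values))  # by height desc, then index asc
    keep: list[int] = []
    for i in order:
        if all(abs(indices[i] - indices[j]) >= min_distance for j in keep):
            keep.append(i)
    return np.sort(indices[np.array(keep, dtype=int)])


def detect_midswing(omega_ml: np.ndarray, criteria: PeakCriteria | None = None) -> np.ndarray:
    """Indices of mid-swing peaks: local maxima above the height criterion,
    pairwise at least ``ms_min_distance`` samples apart, ascending.

    Returns an empty array when nothing qualifies.
    """
    criteria = criteria or PeakCriteria()
    omega_ml = np.asarray(omega_ml, dtype=float)
    peaks, _ = sps.find_peaks(omega_ml, height=criteria.ms_min_height)
    return _prune_by_distance(peaks, omega_ml[peaks], criteria.ms_min_distance)


def detect_ic_fc(
    omega_ml: np.ndarray,
    ms_indices: np.ndarray,
    criteria: PeakCriteria | None = None,
) -> list[tuple[int, int] | None]:
    """For each mid-swing, the flanking (FC, IC) local-minima pair.

    FC is the nearest qualifying minimum before the mid-swing, IC the nearest
    after it; qualifying minima dip at least ``minima_min_height`` below zero
    and are pairwise at least ``minima_min_distance`` apart.  A mid-swing
    without both flanking minima yields ``None`` (flagged, never guessed).
    """
    criteria = criteria or PeakCriteria()
    omega_ml = np.asarray(omega_ml, dtype=float)
    troughs, _ = sps.find_peaks(-omega_ml, height=criteria.minima_min_height)
    troughs = _prune_by_distance(troughs, -omega_ml[troughs], criteria.minima_min_distance)
    out: list[tuple[int, int] | None] = []
    for m in ms_indices:
        before = troughs[troughs < m]
        after = troughs[troughs > m]
        if len(before) == 0 or len(after) == 0:
            out.append(None)
        else:
            out.append((int(before[-1]), int(after[0])))
    return out


def orient_ml(omega_ml: np.ndarray) -> np.ndarray:
    """Flip the sign when the channel's dominant peak is negative.

    Left- and right-side sensors can have mirrored mediolateral axes; the
    detector assumes positive mid-swing peaks.
    """
    omega_ml = np.asarray(omega_ml, dtype=float)
    if abs(omega_ml.min()) > abs(omega_ml.max()):
        return -omega_ml
    return omega_ml


def side_events(
    omega_ml: np.ndarray,
    side: str,
    fs: float,
    criteria: PeakCriteria | None = None,
    auto_orient: bool = True,
) -> SideEvents:
    """Detect all gait events of one side from its shank ML gyroscope channel."""
    if auto_orient:
        omega_ml = orient_ml(omega_ml)
    ms = detect_midswing(omega_ml, criteria)
    pairs = detect_ic_fc(omega_ml, ms, criteria)
    invalid = np.array([m for m, p in zip(ms, pairs) if p is None], dtype=int)
    if len(invalid):
        logger.warning("side %s: %d mid-swing(s) without flanking minima", side, len(invalid))
    fcs = sorted({p[0] for p in pairs if p is not None})
    ics = sorted({p[1] for p in pairs if p is not None})
    return SideEvents(
        side=side,
        fs=fs,
        ms=np.asarray(ms, dtype=int),
        ic=np.array(ics, dtype=int),
        fc=np.array(fcs, dtype=int),
        invalid_ms=invalid,
    )


def detect_trial_events(
    trial: Trial,
    criteria: PeakCriteria | None = None,
    auto_orient: bool = True,
) -> dict[str, SideEvents]:
    """Run per-side detection on the trial's shank gyroscope ML (x) channels."""
    return {
        side: side_events(
            trial.channel(f"shank_{side}", "gyr", "x"),
            side,
            trial.fs,
            criteria,
            auto_orient=auto_orient,
        )
        for side in SIDES
    }


@dataclass
class GaitSequence:
    """The validated seven-event cycle: two complete stride cycles.

    Events follow ``IC_s -> FC_o -> IC_o -> FC_s -> IC_s -> FC_o -> IC_o``
    where ``s`` is the starting side and ``o`` the other.
    """

    events: list[GaitEvent]
    fs: float

    def __post_init__(self) -> None:
        if len(self.events) != 7:
            raise SequenceError(f"expected 7 events, got {len(self.events)}")
        times = [e.time for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise SequenceError(f"event times must strictly increase: {self.events}")
        s = self.events[0].side
        o = other_side(s)
        expected = [
            (s, "IC"), (o, "FC"), (o, "IC"), (s, "FC"),
            (s, "IC"), (o, "FC"), (o, "IC"),
        ]
        got = [(e.side, e.kind) for e in self.events]
        if got != expected:
            raise SequenceError(f"events do not match the gait-cycle pattern: {got}")

    @property
    def start_side(self) -> str:
        return self.events[0].side

    def _of(self, side: str, kind: str) -> list[GaitEvent]:
        return [e for e in self.events if e.side == side and e.kind == kind]

    def ic(self, side: str, k: int) -> GaitEvent:
        return self._of(side, "IC")[k]

    def fc(self, side: str, k: int = 0) -> GaitEvent:
        return self._of(side, "FC")[k]

    def stride_bounds(self, side: str) -> tuple[int, int]:
        """Sample-index bounds [IC(k), IC(k+1)) of this side's stride."""
        ics = self._of(side, "IC")
        return ics[0].index, ics[1].index


def assemble_sequence(
    events_L: SideEvents,
    events_R: SideEvents,
    start_side: str = "R",
    fs: float | None = None,
) -> GaitSequence:
    """Assemble the earliest valid seven-event cycle from bilateral events.

    Starting at the first IC of ``start_side``, every subsequent IC/FC event
    (of either side) must match the expected pattern slot; any out-of-pattern
    event raises :class:`SequenceError` naming the offenders.  Only the first
    right and first left stride cycle are returned, mirroring a protocol that
    analyses the first two forward strides.
    """
    by_side = {"L": events_L, "R": events_R}
    for side, ev in by_side.items():
        if ev.side != side:
            raise ValueError(f"events labelled {ev.side!r} passed as side {side!r}")
        if len(ev.ic) < 2 or len(ev.fc) < 2:
            raise SequenceError(
                f"side {side}: need >= 2 ICs and >= 2 FCs, got "
                f"{len(ev.ic)} ICs / {len(ev.fc)} FCs"
            )
    fs = fs if fs is not None else events_R.fs
    s, o = start_side, other_side(start_side)
    merged = sorted(by_side["L"].as_events() + by_side["R"].as_events())
    anchors = [e for e in merged if e.side == s and e.kind == "IC"]
    if not anchors:
        raise SequenceError(f"no IC event on starting side {s}")
    anchor = anchors[0]
    expected = [
        (s, "IC"), (o, "FC"), (o, "IC"), (s, "FC"),
        (s, "IC"), (o, "FC"), (o, "IC"),
    ]
    chosen: list[GaitEvent] = []
    for e in merged:
        if e.time < anchor.time:
            continue
        want = expected[len(chosen)]
        if (e.side, e.kind) != want:
            raise SequenceError(
                f"event {e} violates the gait-cycle pattern (expected {want}); "
                f"assembled so far: {chosen}"
            )
        chosen.append(e)
        if len(chosen) == 7:
            break
    if len(chosen) < 7:
        raise SequenceError(
            f"ran out of events after {len(chosen)} of 7 pattern slots: {chosen}"
        )
    return GaitSequence(chosen, fs)


def detect_gait_sequence(
    trial: Trial,
    criteria: PeakCriteria | None = None,
    start_side: str = "R",
    auto_orient: bool = True,
) -> GaitSequence:
    """Detect per-side events on a filtered trial and assemble the cycle."""
    ev = detect_trial_events(trial, criteria, auto_orient=auto_orient)
    return assemble_sequence(ev["L"], ev["R"], start_side=start_side, fs=trial.fs)


class GaitEventDetector(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer: filtered trials -> (trial, GaitSequence) pairs.

    Trials whose events cannot be assembled into a valid cycle are dropped
    (and recorded in ``excluded_``), never silently imputed.
    """

    def __init__(
        self,
        criteria: PeakCriteria | None = None,
        start_side: str = "R",
        auto_orient: bool = True,
    ):
        self.criteria = criteria
        self.start_side = start_side
        self.auto_orient = auto_orient

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        pairs: list[tuple[Trial, GaitSequence]] = []
        self.excluded_: list[tuple[str, str]] = []
        for trial in X:
            try:
                seq = detect_gait_sequence(
                    trial,
                    criteria=self.criteria,
                    start_side=self.start_side,
                    auto_orient=self.auto_orient,
                )
            except SequenceError as exc:
                logger.warning("trial %s excluded: %s", trial.trial_id, exc)
                self.excluded_.append((trial.trial_id, str(exc)))
                continue
            pairs.append((trial, seq))
        return pairs
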