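"""Synthetic multi-sensor walking-trial generator with ground-truth gait events.

The generator emulates short self-paced level-walking trials recorded by seven
IMU placements for three groups: healthy adults, stroke patients and patients
with other neurological disorders.  It produces exactly the signal morphology
the downstream event detector assumes on the shank mediolateral gyroscope
channel — per stride, a large positive mid-swing pulse flanked by a negative
trough at final contact (before) and initial contact (after) — and smooth
gait-locked periodic waveforms on every other channel, plus additive Gaussian
noise.

Pathology model (all knobs config-exposed):

* stroke — one affected side with scaled-down pulse amplitudes, extra noise, a
  longer stance fraction, and a right/left stride-time asymmetry;
* other neurological disorders — bilateral, milder versions of the same
  effects;
* healthy — symmetric, baseline noise.

Event times are laid down first (an initial-contact ladder per side, final
contacts at the stance fraction of each stride, mid-swing midway through each
swing phase) and the waveform pulses are centred exactly on the rounded event
samples, so the returned :class:`GroundTruth` indices coincide with the
waveform extrema by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AXES,
    DEFAULT_FS,
    GROUPS,
    PLACEMENTS,
    SENSORS,
    SIDES,
    SensorStream,
    Trial,
    channel_columns,
)

__all__ = [
    "GroupParams",
    "SimulationSpec",
    "GroundTruth",
    "simulate_trial",
    "simulate_cohort",
    "write_trial_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "GaitSimulator",
]


@dataclass
class GroupParams:
    """Per-group gait timing and pathology parameters.

    ``asymmetry_ratio`` is the target right/left stride-time ratio; stride
    times are split as ``mean * sqrt(r)`` (right) and ``mean / sqrt(r)``
    (left) so their geometric mean stays at ``stride_time_mean``.
    """

    n_subjects: int
    stride_time_mean: float  # s
    stride_time_sd: float  # s, stride-to-stride
    stance_fraction_mean: float  # fraction of stride
    stance_fraction_sd: float
    asymmetry_ratio: float = 1.0  # right/left stride-time ratio
    amplitude_scale: float = 1.0  # affected-side pulse scaling, in (0, 1]
    noise_scale: float = 1.0  # affected-side noise multiplier
    stance_shift: float = 0.0  # affected-side stance-fraction increment
    bilateral: bool = False  # apply pathology to both sides


def default_groups() -> dict[str, GroupParams]:
    """Default three-group cohort: 10 healthy, 11 stroke, 9 other-neurological."""
    return {
        "healthy": GroupParams(
            n_subjects=10,
            stride_time_mean=1.10,
            stride_time_sd=0.03,
            stance_fraction_mean=0.60,
            stance_fraction_sd=0.010,
        ),
        "stroke": GroupParams(
            n_subjects=11,
            stride_time_mean=1.30,
            stride_time_sd=0.05,
            stance_fraction_mean=0.62,
            stance_fraction_sd=0.015,
            asymmetry_ratio=1.10,
            amplitude_scale=0.6,
            noise_scale=3.0,
            stance_shift=0.05,
        ),
        "other_neuro": GroupParams(
            n_subjects=9,
            stride_time_mean=1.20,
            stride_time_sd=0.04,
            stance_fraction_mean=0.61,
            stance_fraction_sd=0.012,
            asymmetry_ratio=1.05,
            amplitude_scale=0.8,
            noise_scale=2.0,
            stance_shift=0.025,
            bilateral=True,
        ),
    }


@dataclass
class SimulationSpec:
    """Full description of a synthetic cohort.

    Amplitudes are in deg/s on the shank mediolateral gyroscope; widths are
    fractions of the stride duration.  ``dls_fraction`` sets where in the
    leading stride the contralateral initial contact falls and hence the
    double-limb-support durations.
    """

    groups: dict[str, GroupParams] = field(default_factory=default_groups)
    trials_per_subject: int = 6
    fs: float = DEFAULT_FS
    n_strides: int = 10
    #: None derives stance_fraction - 0.5 per group, which makes the two
    #: double-limb-support intervals equal (one shared interval per step)
    dls_fraction: float | None = None
    midswing_amplitude: float = 300.0
    trough_amplitude_fc: float = -80.0
    trough_amplitude_ic: float = -120.0
    midswing_width_frac: float = 0.05
    trough_width_frac: float = 0.02
    gyro_noise_sd: float = 2.0  # deg/s
    accel_noise_sd: float = 0.02  # g
    mirror_left_ml: bool = True  # left shank ML axis physically mirrored
    lead_in_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.n_strides < 3:
            raise ValueError("need at least 3 strides per trial")
        if self.trials_per_subject < 1:
            raise ValueError("trials_per_subject must be >= 1")
        if not self.midswing_amplitude > 0:
            raise ValueError("midswing_amplitude must be positive")
        if self.trough_amplitude_fc >= 0 or self.trough_amplitude_ic >= 0:
            raise ValueError("trough amplitudes must be negative")
        for name, g in self.groups.items():
            if name not in GROUPS:
                raise ValueError(f"unknown group label {name!r}; expected one of {GROUPS}")
            c = g.stance_fraction_mean + g.stance_shift
            if not 0.0 < g.stance_fraction_mean < 1.0 or not 0.0 < c < 1.0:
                raise ValueError(f"group {name}: stance fraction outside (0, 1)")
            d = self.group_dls_fraction(name)
            if d <= 0:
                raise ValueError(
                    f"group {name}: dls_fraction must be positive "
                    "(stance fraction must exceed 0.5 when it is derived)"
                )
            if 2 * d >= g.stance_fraction_mean:
                raise ValueError(f"group {name}: 2*dls_fraction must be < stance fraction")
            # contralateral FC must land after the next ipsilateral IC
            if 2 * g.stance_fraction_mean - d - 1.0 <= 0:
                raise ValueError(
                    f"group {name}: stance fraction too short for dls_fraction "
                    "(first double support would be negative)"
                )
            if not 0.0 < g.amplitude_scale <= 1.0:
                raise ValueError(f"group {name}: amplitude_scale must be in (0, 1]")
            if g.stride_time_mean <= 0 or g.asymmetry_ratio <= 0:
                raise ValueError(f"group {name}: timing parameters must be positive")

    def group_dls_fraction(self, group_label: str) -> float:
        """Double-support fraction of stride for one group."""
        if self.dls_fraction is not None:
            return self.dls_fraction
        return self.groups[group_label].stance_fraction_mean - 0.5

    # -- (de)serialisation used by the CLI config file -------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationSpec":
        d = dict(d)
        groups = d.pop("groups", None)
        spec = cls(**d) if groups is None else cls(
            groups={k: GroupParams(**v) for k, v in groups.items()}, **d
        )
        return spec


@dataclass
class GroundTruth:
    """Ground-truth gait events of one simulated trial (sample indices)."""

    subject_id: str
    trial_id: str
    group_label: str
    affected_side: str | None
    fs: float
    ic: dict[str, np.ndarray]  # per side, strictly increasing
    fc: dict[str, np.ndarray]
    ms: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for side in SIDES:
            for d in (self.ic, self.fc, self.ms):
                d[side] = np.asarray(d[side], dtype=int)
                if np.any(np.diff(d[side]) <= 0):
                    raise ValueError(f"{side}: event indices must be strictly increasing")
            # per side, events alternate IC(k) < FC(k) < IC(k+1)
            ic, fc = self.ic[side], self.fc[side]
            if len(ic) != len(fc) + 1:
                raise ValueError(f"{side}: expected one more IC than FC")
            if np.any(fc <= ic[:-1]) or np.any(fc >= ic[1:]):
                raise ValueError(f"{side}: FC events must alternate with ICs")

    def stride_times(self, side: str) -> np.ndarray:
        return np.diff(self.ic[side]) / self.fs

    def stance_fractions(self, side: str) -> np.ndarray:
        ic = self.ic[side]
        return (self.fc[side] - ic[:-1]) / np.diff(ic)


def _gauss_pulse(n: int, center: int, sigma: float, amplitude: float) -> np.ndarray:
    """Gaussian pulse evaluated on sample grid 0..n-1, truncated at 5 sigma."""
    half = int(np.ceil(5 * sigma))
    lo, hi = max(0, center - half), min(n, center + half + 1)
    out = np.zeros(n)
    x = np.arange(lo, hi) - center
    out[lo:hi] = amplitude * np.exp(-0.5 * (x / sigma) ** 2)
    return out


def _side_event_times(
    spec: SimulationSpec, g: GroupParams, dls: float, rng: np.random.Generator
) -> dict[str, dict[str, np.ndarray]]:
    """Lay down IC/FC/mid-swing times (seconds) for both sides.

    The right/left stride-time asymmetry alternates long–short per stride
    (right long exactly when left is short) so that the two sides' ladders
    stay synchronized over a stride pair instead of drifting apart, while
    the analysed stride pair — the one starting at the second right IC —
    shows the requested right/left ratio.
    """
    r = np.sqrt(g.asymmetry_ratio)
    k = np.arange(spec.n_strides)
    mod = {"R": np.where(k % 2 == 1, r, 1.0 / r), "L": np.where(k % 2 == 1, 1.0 / r, r)}
    strides = {}
    stance = {}
    for side in ("R", "L"):
        d = g.stride_time_mean * mod[side] + rng.normal(
            0.0, g.stride_time_sd, size=spec.n_strides
        )
        strides[side] = np.clip(d, 0.4 * g.stride_time_mean, None)
        stance[side] = np.clip(
            g.stance_fraction_mean
            + rng.normal(0.0, g.stance_fraction_sd, size=spec.n_strides),
            0.3,
            0.9,
        )
    times: dict[str, dict[str, np.ndarray]] = {}
    ic_r0 = spec.lead_in_s
    for side in ("R", "L"):
        if side == "R":
            ic0 = ic_r0
        else:
            # contralateral IC lands dls_fraction of a stride before right FC
            ic0 = ic_r0 + (stance["R"][0] - dls) * strides["R"][0]
        ic = ic0 + np.concatenate([[0.0], np.cumsum(strides[side])])
        fc = ic[:-1] + stance[side] * strides[side]
        ms = 0.5 * (fc + ic[1:])
        times[side] = {"ic": ic, "fc": fc, "ms": ms}
    return times


def _side_is_affected(side: str, g: GroupParams, affected_side: str | None) -> bool:
    return g.bilateral or side == affected_side


# deterministic per-channel base waveform parameters, shared across the cohort
_CHANNEL_SEED = 1_913_077


def _harmonic_params(placement: str, sensor: str, axis: str):
    idx = PLACEMENTS.index(placement) * 6 + SENSORS.index(sensor) * 3 + AXES.index(axis)
    rng = np.random.default_rng([_CHANNEL_SEED, idx])
    n_harm = 3
    if sensor == "acc":
        amps = rng.uniform(0.05, 0.35, n_harm) / np.arange(1, n_harm + 1)
    else:
        amps = rng.uniform(15.0, 60.0, n_harm) / np.arange(1, n_harm + 1)
    phases = rng.uniform(0, 2 * np.pi, n_harm)
    return amps, phases


def simulate_trial(
    spec: SimulationSpec,
    subject_id: int,
    group_label: str,
    trial_index: int = 0,
    affected_side: str | None = None,
) -> tuple[Trial, GroundTruth]:
    """Generate one trial and its ground-truth events.

    Reproducible from ``(spec.seed, group, subject_id, trial_index)``.  For
    the stroke group, ``affected_side`` defaults to a per-subject draw that is
    stable across that subject's trials.
    """
    if group_label not in spec.groups:
        raise ValueError(
            f"unknown group label {group_label!r}; expected one of {sorted(spec.groups)}"
        )
    g = spec.groups[group_label]
    gi = GROUPS.index(group_label)
    if affected_side is None and not g.bilateral and (
        g.amplitude_scale < 1.0 or g.noise_scale > 1.0 or g.stance_shift != 0.0
        or g.asymmetry_ratio != 1.0
    ):
        subj_rng = np.random.default_rng([spec.seed, gi, subject_id])
        affected_side = "L" if subj_rng.random() < 0.5 else "R"
    rng = np.random.default_rng([spec.seed, gi, subject_id, trial_index])

    # event ladder; the affected side's stance fraction is shifted afterwards
    times = _side_event_times(spec, g, spec.group_dls_fraction(group_label), rng)
    if g.stance_shift != 0.0:
        for side in SIDES:
            if _side_is_affected(side, g, affected_side):
                ic = times[side]["ic"]
                strides = np.diff(ic)
                times[side]["fc"] = times[side]["fc"] + g.stance_shift * strides
                times[side]["ms"] = 0.5 * (times[side]["fc"] + ic[1:])

    t_end = max(times[s]["ic"][-1] for s in SIDES) + spec.lead_in_s
    n = int(np.ceil(t_end * spec.fs))
    t = np.arange(n) / spec.fs

    idx = {
        side: {k: np.round(v * spec.fs).astype(int) for k, v in times[side].items()}
        for side in SIDES
    }

    # shank mediolateral angular velocity, deg/s
    def shank_ml(side: str) -> np.ndarray:
        affected = _side_is_affected(side, g, affected_side)
        scale = g.amplitude_scale if affected else 1.0
        stride_samp = float(np.mean(np.diff(idx[side]["ic"])))
        sig = np.zeros(n)
        for center in idx[side]["ms"]:
            sig += _gauss_pulse(
                n, center, spec.midswing_width_frac * stride_samp,
                spec.midswing_amplitude * scale,
            )
        for center in idx[side]["fc"]:
            sig += _gauss_pulse(
                n, center, spec.trough_width_frac * stride_samp,
                spec.trough_amplitude_fc * scale,
            )
        for center in idx[side]["ic"]:
            sig += _gauss_pulse(
                n, center, spec.trough_width_frac * stride_samp,
                spec.trough_amplitude_ic * scale,
            )
        return sig

    streams: dict[str, SensorStream] = {}
    for placement in PLACEMENTS:
        side = placement[-1] if placement[-1] in SIDES else "R"  # L5 follows right phase
        affected = _side_is_affected(side, g, affected_side) and placement != "L5"
        scale = g.amplitude_scale if affected else 1.0
        noise_mult = g.noise_scale if affected else 1.0
        stride_mean = float(np.mean(np.diff(times[side]["ic"])))
        phase = 2 * np.pi * (t - times[side]["ic"][0]) / stride_mean
        accel = np.empty((3, n))
        gyro = np.empty((3, n))
        for sensor, target in (("acc", accel), ("gyr", gyro)):
            noise_sd = spec.accel_noise_sd if sensor == "acc" else spec.gyro_noise_sd
            for ai, axis in enumerate(AXES):
                if placement.startswith("shank") and sensor == "gyr" and axis == "x":
                    sig = shank_ml(side)
                    if spec.mirror_left_ml and side == "L":
                        sig = -sig
                else:
                    amps, phases = _harmonic_params(placement, sensor, axis)
                    sig = scale * sum(
                        a * np.sin((h + 1) * phase + p)
                        for h, (a, p) in enumerate(zip(amps, phases))
                    )
                target[ai] = sig + rng.normal(0.0, noise_sd * noise_mult, n)
        streams[placement] = SensorStream(placement, accel, gyro, spec.fs)

    sid = f"{group_label}_{subject_id:02d}"
    tid = f"{sid}_t{trial_index:02d}"
    trial = Trial(sid, tid, group_label, streams)
    truth = GroundTruth(
        subject_id=sid,
        trial_id=tid,
        group_label=group_label,
        affected_side=affected_side,
        fs=spec.fs,
        ic={s: idx[s]["ic"] for s in SIDES},
        fc={s: idx[s]["fc"] for s in SIDES},
        ms={s: idx[s]["ms"] for s in SIDES},
    )
    return trial, truth


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[list[Trial], list[GroundTruth], list[str]]:
    """Generate all trials of the cohort described by ``spec``.

    Returns one label per trial; cohort size is
    ``sum(n_subjects) * trials_per_subject``.
    """
    trials: list[Trial] = []
    truths: list[GroundTruth] = []
    labels: list[str] = []
    for group_label in GROUPS:
        if group_label not in spec.groups:
            continue
        g = spec.groups[group_label]
        for subject in range(g.n_subjects):
            for k in range(spec.trials_per_subject):
                trial, truth = simulate_trial(spec, subject, group_label, trial_index=k)
                trials.append(trial)
                truths.append(truth)
                labels.append(group_label)
    return trials, truths, labels


# ---------------------------------------------------------------------------
# trial CSV / ground-truth JSON writers (reader lives in imugait.preprocess)


def write_trial_csv(trial: Trial, path: str | Path) -> Path:
    """Write one trial as CSV: ``time_s`` plus the 42 channel columns."""
    path = Path(path)
    n = trial.n_samples
    # time needs more digits than the channels: the sampling rate is
    # recovered from it on read
    data: dict[str, object] = {
        "time_s": [f"{t:.9f}" for t in np.arange(n) / trial.fs]
    }
    for col in channel_columns():
        placement, sensor, axis = col.rsplit("_", 2)
        data[col] = trial.channel(placement, sensor, axis)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")
    return path


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "subject_id": truth.subject_id,
        "trial_id": truth.trial_id,
        "group_label": truth.group_label,
        "affected_side": truth.affected_side,
        "fs": truth.fs,
        "events": {
            side: {
                "IC": truth.ic[side].tolist(),
                "FC": truth.fc[side].tolist(),
                "MS": truth.ms[side].tolist(),
            }
            for side in SIDES
        },
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_ground_truth_json(path: str | Path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        subject_id=d["subject_id"],
        trial_id=d["trial_id"],
        group_label=d["group_label"],
        affected_side=d["affected_side"],
        fs=d["fs"],
        ic={s: np.array(d["events"][s]["IC"]) for s in SIDES},
        fc={s: np.array(d["events"][s]["FC"]) for s in SIDES},
        ms={s: np.array(d["events"][s]["MS"]) for s in SIDES},
    )


class GaitSimulator:
    """Object wrapper over :func:`simulate_cohort` with sklearn-style params."""

    def __init__(self, spec: SimulationSpec | None = None):
        self.spec = spec if spec is not None else SimulationSpec()

    def get_params(self, deep: bool = True) -> dict:
        return {"spec": self.spec}

    def set_params(self, **params) -> "GaitSimulator":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def sample_trial(self, subject_id: int, group_label: str, trial_index: int = 0):
        return simulate_trial(self.spec, subject_id, group_label, trial_index)

    def sample_cohort(self):
        return simulate_cohort(self.spec)
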