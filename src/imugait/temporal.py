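"""Temporal gait parameters from the assembled seven-event cycle.

Per side: stride time (IC to next ipsilateral IC), stance time (IC to
ipsilateral FC), swing time (FC to next ipsilateral IC), and the two
double-limb-support intervals (ipsilateral IC to contralateral FC, and
contralateral IC to ipsilateral FC).  Stance and swing are also expressed as
percentages of the ipsilateral stride, and right/left symmetry ratios are
computed for stride, stance and swing.  Together these form the 17-element
temporal feature vector: 5 durations x 2 sides, 2 percentages x 2 sides and
3 symmetry ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import SIDES, other_side
from .events import GaitSequence

__all__ = [
    "TemporalParams",
    "TEMPORAL_FEATURE_NAMES",
    "stride_time",
    "stance_time",
    "swing_time",
    "double_support",
    "percentages",
    "symmetry_ratio",
    "compute_temporal_params",
    "temporal_feature_vector",
]

#: Stable name/order manifest of the 17 temporal features.
TEMPORAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{param}_{side}"
    for param in ("stride_time", "stance_time", "swing_time", "dls1", "dls2")
    for side in ("R", "L")
) + tuple(
    f"{param}_{side}" for param in ("stance_pct", "swing_pct") for side in ("R", "L")
) + ("symmetry_stride", "symmetry_stance", "symmetry_swing")


def stride_time(ic_k: float, ic_k1: float) -> float:
    """Stride time: next ipsilateral IC minus IC, seconds."""
    if ic_k1 <= ic_k:
        raise ValueError(f"IC(k+1)={ic_k1} must be after IC(k)={ic_k}")
    return ic_k1 - ic_k


def stance_time(ic_k: float, fc_k: float) -> float:
    """Stance time: ipsilateral FC minus IC, seconds."""
    if fc_k <= ic_k:
        raise ValueError(f"FC(k)={fc_k} must be after IC(k)={ic_k}")
    return fc_k - ic_k


def swing_time(fc_k: float, ic_k1: float) -> float:
    """Swing time: next ipsilateral IC minus FC, seconds."""
    if ic_k1 <= fc_k:
        raise ValueError(f"IC(k+1)={ic_k1} must be after FC(k)={fc_k}")
    return ic_k1 - fc_k


def double_support(seq: GaitSequence, side: str) -> tuple[float, float]:
    """The two double-limb-support durations of ``side``'s stride, seconds.

    First DLS: contralateral FC minus ipsilateral IC; second DLS:
    ipsilateral FC minus contralateral IC.
    """
    contra = other_side(side)
    if side == seq.start_side:
        ic_ipsi = seq.ic(side, 0)
        fc_contra = seq.fc(contra, 0)
        ic_contra = seq.ic(contra, 0)
        fc_ipsi = seq.fc(side, 0)
    else:
        # the non-starting side's stride spans slots 2..6 of the pattern
        ic_ipsi = seq.ic(side, 0)
        fc_contra = seq.fc(contra, 0)
        ic_contra = seq.ic(contra, 1)
        fc_ipsi = seq.fc(side, 1)
    dls1 = fc_contra.time - ic_ipsi.time
    dls2 = fc_ipsi.time - ic_contra.time
    if dls1 <= 0 or dls2 <= 0:
        raise ValueError(
            f"side {side}: double-support events out of order "
            f"(dls1={dls1:.4f}s, dls2={dls2:.4f}s)"
        )
    return dls1, dls2


def percentages(stance_s: float, swing_s: float, stride_s: float) -> tuple[float, float]:
    """Stance and swing as percentages of the ipsilateral stride time."""
    if stride_s <= 0:
        raise ValueError("stride time must be positive")
    return 100.0 * stance_s / stride_s, 100.0 * swing_s / stride_s


def symmetry_ratio(right_value: float, left_value: float) -> float:
    """Right divided by left temporal parameter; 1.0 = perfect symmetry."""
    if left_value <= 0:
        raise ValueError(f"left value must be positive, got {left_value}")
    return right_value / left_value


@dataclass
class TemporalParams:
    """Per-side temporal durations (s), percentages and symmetry ratios."""

    stride_time: dict[str, float]
    stance_time: dict[str, float]
    swing_time: dict[str, float]
    dls1: dict[str, float]
    dls2: dict[str, float]
    stance_pct: dict[str, float]
    swing_pct: dict[str, float]
    symmetry_stride: float
    symmetry_stance: float
    symmetry_swing: float


def compute_temporal_params(seq: GaitSequence) -> TemporalParams:
    """Evaluate all temporal parameters on one assembled cycle."""
    stride: dict[str, float] = {}
    stance: dict[str, float] = {}
    swing: dict[str, float] = {}
    d1: dict[str, float] = {}
    d2: dict[str, float] = {}
    st_pct: dict[str, float] = {}
    sw_pct: dict[str, float] = {}
    for side in SIDES:
        ic0 = seq.ic(side, 0).time
        ic1 = seq.ic(side, 1).time
        # the starting side's FC is its only one; the other side's stride
        # (slots 2..6) closes with that side's second FC
        fc = seq.fc(side, 0 if side == seq.start_side else 1).time
        stride[side] = stride_time(ic0, ic1)
        stance[side] = stance_time(ic0, fc)
        swing[side] = swing_time(fc, ic1)
        d1[side], d2[side] = double_support(seq, side)
        st_pct[side], sw_pct[side] = percentages(stance[side], swing[side], stride[side])
    return TemporalParams(
        stride_time=stride,
        stance_time=stance,
        swing_time=swing,
        dls1=d1,
        dls2=d2,
        stance_pct=st_pct,
        swing_pct=sw_pct,
        symmetry_stride=symmetry_ratio(stride["R"], stride["L"]),
        symmetry_stance=symmetry_ratio(stance["R"], stance["L"]),
        symmetry_swing=symmetry_ratio(swing["R"], swing["L"]),
    )


def temporal_feature_vector(params: TemporalParams) -> pd.Series:
    """The 17 named temporal features in manifest order."""
    values = {}
    for name in ("stride_time", "stance_time", "swing_time", "dls1", "dls2",
                 "stance_pct", "swing_pct"):
        per_side = getattr(params, name)
        for side in ("R", "L"):
            values[f"{name}_{side}"] = float(per_side[side])
    values["symmetry_stride"] = float(params.symmetry_stride)
    values["symmetry_stance"] = float(params.symmetry_stance)
    values["symmetry_swing"] = float(params.symmetry_swing)
    out = pd.Series(values).reindex(list(TEMPORAL_FEATURE_NAMES))
    if out.isna().any():
        raise ValueError(f"missing temporal components: {out.index[out.isna()].tolist()}")
    return out
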