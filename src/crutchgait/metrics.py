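"""Feedback metrics of the 3-point gait.

Three metrics drive the corrective feedback, all derived from the marker
positions around a completed compound state:

* **crutch angle** — signed tilt of the crutch from vertical, projected on
  the walking direction, at placement.  Computed from handle and tip
  markers as ``atan2(w_handle - w_tip, y_handle - y_tip)`` in degrees, plus
  a configurable cane-mount offset.  Negative means the handle trails the
  planted tip (tip ahead along travel).
* **crutch position** — walk-axis offset (cm) between the planted tip and
  the center of the foot; the foot center is estimated as the foot marker
  minus a 15 cm anatomical offset, so 0 cm is the optimum.
* **synchronicity** — fraction of a compound state's moving time during
  which all required entities move together (intersection over union of
  their bout intervals).

Step length and step speed are additionally reported per cycle from the
moving foot's bout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .gait_data import ENTITY_ROLES, Entity, MarkerRole, Trajectory
from .pattern import GaitPattern, StateInstance
from .segmentation import MovementInterval

__all__ = [
    "MetricConfig",
    "MetricRecord",
    "crutch_angle",
    "crutch_position",
    "synchronicity",
    "step_metrics",
    "compute_metrics",
    "aggregate_metrics",
    "METRIC_FIELDS",
]

METRIC_FIELDS = ("crutch_angle", "crutch_position", "synchronicity", "step_length", "step_speed")


@dataclass(frozen=True)
class MetricConfig:
    """Calibration constants of the metric computations."""

    cane_offset_deg: float = 0.0  # additive cane-mount correction (degrees)
    foot_center_offset: float = 0.15  # foot marker to foot center (m)
    settle_window: float = 0.15  # marker-average window at measurement (s)

    def __post_init__(self) -> None:
        if self.foot_center_offset < 0:
            raise ValueError("foot_center_offset must be non-negative")


@dataclass(frozen=True)
class MetricRecord:
    """Per-cycle, per-crutch metric values; NaN marks an unmeasurable metric."""

    cycle: int
    side: str  # "left" | "right" crutch
    crutch_angle: float  # degrees, signed
    crutch_position: float  # cm, signed (positive = tip ahead of foot center)
    synchronicity: float  # [0, 1]
    step_length: float  # m
    step_speed: float  # m/s


def _role_mean(
    traj: Trajectory, role: MarkerRole, t: float, window: float
) -> tuple[float, float, float] | None:
    """Mean (x, y, w) of a role over frames in [t, t + window]; the markers
    are static there, so averaging only suppresses jitter."""
    pts = [
        f.points[role]
        for f in traj.frames
        if t <= f.t <= t + window and role in f.points
    ]
    if not pts:
        # fall back to the nearest observed frame
        cands = [(abs(f.t - t), f.points[role]) for f in traj.frames if role in f.points]
        if not cands:
            return None
        pts = [min(cands, key=lambda c: c[0])[1]]
    return (
        float(np.mean([p.x for p in pts])),
        float(np.mean([p.y for p in pts])),
        float(np.mean([p.w for p in pts])),
    )


def crutch_angle(
    traj: Trajectory,
    crutch: Entity,
    t_placed: float,
    cfg: MetricConfig = MetricConfig(),
) -> float:
    """Signed crutch tilt (degrees) from vertical at placement time.

    Returns NaN when either crutch marker is unobserved around
    ``t_placed``.
    """
    handle_role, tip_role = ENTITY_ROLES[crutch]
    h = _role_mean(traj, handle_role, t_placed, cfg.settle_window)
    p = _role_mean(traj, tip_role, t_placed, cfg.settle_window)
    if h is None or p is None:
        return math.nan
    return math.degrees(math.atan2(h[2] - p[2], h[1] - p[1])) + cfg.cane_offset_deg


def crutch_position(
    traj: Trajectory,
    crutch: Entity,
    foot: Entity,
    t_state_end: float,
    cfg: MetricConfig = MetricConfig(),
) -> float:
    """Walk-axis tip-to-foot-center offset (cm) after the state's movement."""
    tip_role = ENTITY_ROLES[crutch][-1]
    foot_role = ENTITY_ROLES[foot][0]
    tip = _role_mean(traj, tip_role, t_state_end, cfg.settle_window)
    ft = _role_mean(traj, foot_role, t_state_end, cfg.settle_window)
    if tip is None or ft is None:
        return math.nan
    return (tip[2] - (ft[2] - cfg.foot_center_offset)) * 100.0


def synchronicity(instance: StateInstance) -> float:
    """Shared moving time over total moving time of a compound state.

    Intersection duration of all required entities' bouts divided by the
    duration of their union.  Defined only for compound states (two or more
    required entities); returns NaN otherwise.
    """
    if len(instance.intervals) < 2:
        return math.nan
    ivs = list(instance.intervals.values())
    union = max(iv.t_off for iv in ivs) - min(iv.t_on for iv in ivs)
    if union <= 0:
        raise ValueError("degenerate state: zero overall moving time")
    inter = min(iv.t_off for iv in ivs) - max(iv.t_on for iv in ivs)
    return max(0.0, inter) / union


def step_metrics(instance: StateInstance) -> tuple[float, float]:
    """(step_length m, step_speed m/s) from the state's foot bout."""
    foot_iv: MovementInterval | None = None
    for ent, iv in instance.intervals.items():
        if ent in (Entity.LEFT_FOOT, Entity.RIGHT_FOOT):
            foot_iv = iv
            break
    if foot_iv is None:
        return math.nan, math.nan
    length = abs(foot_iv.displacement_w)
    if length == 0:
        return 0.0, 0.0
    return length, length / foot_iv.duration


def compute_metrics(
    traj: Trajectory,
    instances: list[StateInstance],
    pattern: GaitPattern,
    cfg: MetricConfig = MetricConfig(),
) -> list[MetricRecord]:
    """One MetricRecord per (cycle, crutch side) from the compound states.

    The crutch angle is read at the crutch's placement (end of its bout);
    the crutch position at state completion, pairing each crutch with the
    state's moving foot.
    """
    records: list[MetricRecord] = []
    for inst in instances:
        state = pattern.states[inst.state_index]
        crutches = [e for e in state.required if e in (Entity.LEFT_CRUTCH, Entity.RIGHT_CRUTCH)]
        feet = [e for e in state.required if e in (Entity.LEFT_FOOT, Entity.RIGHT_FOOT)]
        if not crutches or not feet:
            continue
        foot = feet[0]
        sync = synchronicity(inst)
        length, speed = step_metrics(inst)
        for crutch in sorted(crutches, key=lambda e: e.value):
            t_placed = inst.intervals[crutch].t_off
            records.append(
                MetricRecord(
                    cycle=inst.cycle,
                    side="left" if crutch is Entity.LEFT_CRUTCH else "right",
                    crutch_angle=crutch_angle(traj, crutch, t_placed, cfg),
                    crutch_position=crutch_position(traj, crutch, foot, inst.t_end, cfg),
                    synchronicity=sync,
                    step_length=length,
                    step_speed=speed,
                )
            )
    return records


def aggregate_metrics(records: Iterable[MetricRecord]) -> dict[str, dict[str, float]]:
    """Per-subject summary: mean and sample SD (n-1) per metric.

    Missing (NaN) values are excluded pairwise; a metric with no valid
    values is reported with NaN mean, and SD is NaN when fewer than two
    valid values remain.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to aggregate")
    out: dict[str, dict[str, float]] = {}
    for name in METRIC_FIELDS:
        vals = np.array([getattr(r, name) for r in records], dtype=float)
        vals = vals[~np.isnan(vals)]
        out[name] = {
            "n": int(len(vals)),
            "mean": float(np.mean(vals)) if len(vals) else math.nan,
            "sd": float(np.std(vals, ddof=1)) if len(vals) >= 2 else math.nan,
        }
    return out
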