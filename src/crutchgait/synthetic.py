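"""Seeded generator of synthetic 3-point-gait marker trajectories.

Stands in for patient recordings: it emits the same long-format marker
trajectories the analysis pipeline ingests, together with a ``GroundTruth``
record of every bout and every metric value the generator was configured
with, so the whole pipeline can be validated by parameter recovery.

Movement bouts follow a minimum-jerk displacement profile (the standard
model of point-to-point reaching/stepping movements), which produces
realistic bell-shaped speed curves that exercise the hysteresis thresholds
of the segmenter.  Within the compound state the crutches start
``sync_lag`` seconds after the injured foot (negative = crutches first).
Gaussian jitter of configurable sigma is added to every coordinate, and a
tracking-dropout mode deletes a crutch's markers from a given time onward,
emulating the mid-session loss of crutch tracking seen in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .gait_data import ENTITY_ROLES, Entity, Frame, MarkerRole, Point3, Trajectory

__all__ = [
    "GaitParams",
    "ErrorPlan",
    "PlannedError",
    "GroundTruth",
    "CohortSpec",
    "generate_session",
    "generate_cohort",
]

_LIFT_FOOT = 0.05  # swing-phase marker lift (m)
_LIFT_CRUTCH = 0.03
_FOOT_MARKER_HEIGHT = 0.05  # foot marker above ground (m)
_FOOT_CENTER_OFFSET = 0.15  # foot marker to foot center (m), matches MetricConfig
_CRUTCH_X = 0.30  # lateral crutch offset from midline (m)
_FOOT_X = 0.10
_LEAD_IN = 1.0  # quiet standing before the first cycle (s)


@dataclass(frozen=True)
class GaitParams:
    """Ground-truth gait parameters of one synthetic subject."""

    step_length: float = 0.40  # m per cycle
    foot_move_duration: float = 0.60  # s per bout
    stance_duration: float = 0.80  # quiet time between states (s)
    crutch_angle_deg: float = -6.3  # tilt at placement (deg, negative = handle trails)
    crutch_pos_offset: float = 3.3  # tip vs foot center (cm, positive = ahead)
    sync_lag: float = 0.20  # crutch onset minus foot onset (s)
    cycles: int = 4
    noise_sigma: float = 0.0  # marker jitter (m)
    rate: float = 30.0  # Hz
    subject_height: float = 1.75  # m (scales crutch length)
    injured_side: str = "left"

    def __post_init__(self) -> None:
        if self.foot_move_duration <= 0 or self.stance_duration <= 0:
            raise ValueError("durations must be positive")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.injured_side not in ("left", "right"):
            raise ValueError("injured_side must be 'left' or 'right'")
        if abs(self.sync_lag) >= self.foot_move_duration + self.stance_duration:
            raise ValueError("sync_lag overlaps adjacent state windows")

    @property
    def crutch_length(self) -> float:
        return 1.0 * self.subject_height / 1.75

    @property
    def sync_truth(self) -> float:
        """Intersection-over-union of the compound state's bout intervals."""
        d, lag = self.foot_move_duration, abs(self.sync_lag)
        return max(0.0, d - lag) / (d + lag)


@dataclass(frozen=True)
class PlannedError:
    cycle: int
    kind: str  # wrong_entity | wrong_order
    entity: Entity


ErrorPlan = Sequence[PlannedError]


@dataclass
class GroundTruth:
    """Everything the generator knows about the session it produced."""

    params: GaitParams
    bouts: list[dict]  # entity, t_on, t_off, displacement_w
    cycle_metrics: list[dict]  # cycle, crutch_angle, crutch_position, sync, step_length, step_speed
    planned_errors: list[PlannedError]
    dropout: tuple[Entity, float] | None = None


def _minjerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile s(tau) on [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


@dataclass
class _Bout:
    """One scripted movement: piecewise minimum-jerk segments in w plus a lift."""

    t_on: float
    t_off: float
    segments: list[tuple[float, float, float, float]]  # (t0, t1, w0, w1)
    lift: float

    def w(self, t: np.ndarray, w_before: float) -> np.ndarray:
        out = np.full_like(t, w_before, dtype=float)
        for t0, t1, w0, w1 in self.segments:
            tau = (t - t0) / (t1 - t0)
            inside = (t >= t0) & (t < t1)
            out[inside] = w0 + (w1 - w0) * _minjerk(tau[inside])
            out[t >= t1] = w1
        return out

    def y_lift(self, t: np.ndarray) -> np.ndarray:
        tau = np.clip((t - self.t_on) / (self.t_off - self.t_on), 0.0, 1.0)
        return self.lift * np.sin(np.pi * tau) ** 2


class _Script:
    """Per-entity list of bouts; positions sampled after scripting."""

    def __init__(self, start_w: dict[Entity, float]):
        self.bouts: dict[Entity, list[_Bout]] = {e: [] for e in Entity}
        self.pos_w: dict[Entity, float] = dict(start_w)

    def advance(self, entity: Entity, t_on: float, duration: float, w_to: float, lift: float) -> _Bout:
        w0 = self.pos_w[entity]
        b = _Bout(t_on, t_on + duration, [(t_on, t_on + duration, w0, w_to)], lift)
        self.bouts[entity].append(b)
        self.pos_w[entity] = w_to
        return b

    def out_and_back(self, entity: Entity, t_on: float, duration: float, amp: float, lift: float) -> _Bout:
        w0 = self.pos_w[entity]
        half = duration / 2
        b = _Bout(
            t_on,
            t_on + duration,
            [(t_on, t_on + half, w0, w0 + amp), (t_on + half, t_on + duration, w0 + amp, w0)],
            lift,
        )
        self.bouts[entity].append(b)
        return b

    def sample_w(self, entity: Entity, t: np.ndarray) -> np.ndarray:
        bouts = self.bouts[entity]
        if not bouts:
            return np.full_like(t, self.pos_w[entity])
        out = np.full_like(t, bouts[0].segments[0][2], dtype=float)
        for b in bouts:
            w_final = b.segments[-1][3]
            active = (t >= b.t_on) & (t < b.t_off)
            if active.any():
                out[active] = b.w(t[active], b.segments[0][2])
            out[t >= b.t_off] = w_final
        return out

    def sample_lift(self, entity: Entity, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(t)
        for b in self.bouts[entity]:
            active = (t >= b.t_on) & (t <= b.t_off)
            out[active] = b.y_lift(t[active])
        return out


def generate_session(
    params: GaitParams,
    errors: ErrorPlan = (),
    seed: int = 0,
    dropout: tuple[Entity, float] | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Generate one synthetic session and its ground truth.

    Identical ``(params, errors, seed, dropout)`` give bit-identical output.
    Planned errors are injected in a pre-window before the affected cycle's
    compound state: a ``wrong_entity`` error is a spurious out-and-back bout
    of the named entity; a ``wrong_order`` error duplicates the injured
    foot's bout before the state is repeated correctly.
    """
    errors = list(errors)
    for e in errors:
        if not 0 <= e.cycle < params.cycles:
            raise ValueError(f"planned error cycle {e.cycle} outside session")
    injured = Entity.LEFT_FOOT if params.injured_side == "left" else Entity.RIGHT_FOOT
    other = Entity.RIGHT_FOOT if params.injured_side == "left" else Entity.LEFT_FOOT
    crutches = (Entity.LEFT_CRUTCH, Entity.RIGHT_CRUTCH)

    tip0 = -_FOOT_CENTER_OFFSET + params.crutch_pos_offset / 100.0
    script = _Script(
        {injured: 0.0, other: 0.0, crutches[0]: tip0, crutches[1]: tip0}
    )
    gt_bouts: list[dict] = []
    cycle_metrics: list[dict] = []
    d = params.foot_move_duration
    lag = params.sync_lag
    step = params.step_length
    t = _LEAD_IN
    err_by_cycle: dict[int, list[PlannedError]] = {}
    for e in errors:
        err_by_cycle.setdefault(e.cycle, []).append(e)

    def record(entity: Entity, b: _Bout, disp: float) -> None:
        gt_bouts.append(
            {"entity": entity, "t_on": b.t_on, "t_off": b.t_off, "displacement_w": disp}
        )

    for k in range(params.cycles):
        # --- planned-error pre-window ---------------------------------
        for e in err_by_cycle.get(k, []):
            if e.kind == "wrong_entity":
                b = script.out_and_back(e.entity, t, 0.5, 0.10, _LIFT_FOOT)
                record(e.entity, b, 0.0)
                t = b.t_off + params.stance_duration
            elif e.kind == "wrong_order":
                # injured foot moves twice before the state is done properly
                b1 = script.out_and_back(injured, t, 0.5, 0.10, _LIFT_FOOT)
                record(injured, b1, 0.0)
                t = b1.t_off + params.stance_duration
                b2 = script.out_and_back(injured, t, 0.5, 0.10, _LIFT_FOOT)
                record(injured, b2, 0.0)
                t = b2.t_off + params.stance_duration
            else:
                raise ValueError(f"unknown planned error kind {e.kind!r}")
        # --- compound state: injured foot + both crutches -------------
        foot_on = t + max(0.0, -lag)
        crutch_on = t + max(0.0, lag)
        foot_target = (k + 1) * step
        b = script.advance(injured, foot_on, d, foot_target, _LIFT_FOOT)
        record(injured, b, foot_target - (b.segments[0][2]))
        tip_target = foot_target - _FOOT_CENTER_OFFSET + params.crutch_pos_offset / 100.0
        for c in crutches:
            bc = script.advance(c, crutch_on, d, tip_target, _LIFT_CRUTCH)
            record(c, bc, tip_target - bc.segments[0][2])
        state_a_end = max(foot_on, crutch_on) + d
        t = state_a_end + params.stance_duration
        # --- single state: non-injured foot ---------------------------
        b = script.advance(other, t, d, foot_target, _LIFT_FOOT)
        record(other, b, foot_target - b.segments[0][2])
        t = t + d + params.stance_duration
        cycle_metrics.append(
            {
                "cycle": k,
                "crutch_angle": params.crutch_angle_deg,
                "crutch_position": params.crutch_pos_offset,
                "synchronicity": params.sync_truth,
                "step_length": step,
                "step_speed": step / d,
            }
        )

    total = t + 0.5  # quiet tail
    n = int(round(total * params.rate)) + 1
    times = np.arange(n) / params.rate

    theta = math.radians(params.crutch_angle_deg)
    L = params.crutch_length
    rng = np.random.default_rng(seed)

    cols: dict[MarkerRole, np.ndarray] = {}
    for entity in (injured, other):
        w = script.sample_w(entity, times)
        y = _FOOT_MARKER_HEIGHT + script.sample_lift(entity, times)
        x = np.full(n, -_FOOT_X if entity is Entity.LEFT_FOOT else _FOOT_X)
        cols[ENTITY_ROLES[entity][0]] = np.column_stack([x, y, w])
    for c in crutches:
        w_tip = script.sample_w(c, times)
        y_tip = script.sample_lift(c, times)
        x = np.full(n, -_CRUTCH_X if c is Entity.LEFT_CRUTCH else _CRUTCH_X)
        handle_role, tip_role = ENTITY_ROLES[c]
        cols[tip_role] = np.column_stack([x, y_tip, w_tip])
        cols[handle_role] = np.column_stack(
            [x, y_tip + L * math.cos(theta), w_tip + L * math.sin(theta)]
        )
    if params.noise_sigma > 0:
        for role in cols:
            cols[role] = cols[role] + rng.normal(0.0, params.noise_sigma, cols[role].shape)

    frames = []
    for i, ti in enumerate(times):
        pts = {}
        for role, arr in cols.items():
            if dropout is not None:
                ent, t_lost = dropout
                if role in ENTITY_ROLES[ent] and ti >= t_lost:
                    continue
            pts[role] = Point3(*arr[i])
        if pts:
            frames.append(Frame(float(ti), pts))
    traj = Trajectory(frames, nominal_rate=params.rate)
    gt = GroundTruth(
        params=params,
        bouts=gt_bouts,
        cycle_metrics=cycle_metrics,
        planned_errors=errors,
        dropout=dropout,
    )
    return traj, gt


@dataclass(frozen=True)
class CohortSpec:
    """Population spec: per-parameter normal distributions across subjects."""

    n: int
    base: GaitParams = GaitParams()
    sd: dict = field(default_factory=dict)  # GaitParams field -> between-subject SD
    dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if any(v < 0 for v in self.sd.values()):
            raise ValueError("SDs must be non-negative")
        if not 0 <= self.dropout_prob <= 1:
            raise ValueError("dropout_prob must be in [0, 1]")


_PARAM_BOUNDS = {
    "step_length": (0.05, 1.5),
    "foot_move_duration": (0.1, 3.0),
    "stance_duration": (0.3, 5.0),
    "sync_lag": (-0.5, 0.5),
    "crutch_angle_deg": (-45.0, 45.0),
    "crutch_pos_offset": (-40.0, 40.0),
    "subject_height": (1.2, 2.2),
}


def generate_cohort(
    spec: CohortSpec, seed: int = 0
) -> list[tuple[str, Trajectory, GroundTruth]]:
    """Generate ``spec.n`` subjects with parameters drawn from the cohort
    normals (truncated to physical bounds with resampling, max 100 tries).
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * spec.n)
    out = []
    for i in range(spec.n):
        rng = np.random.default_rng(int(child_seeds[2 * i]))
        draws = {}
        for name, sd in spec.sd.items():
            if sd == 0:
                continue
            lo, hi = _PARAM_BOUNDS.get(name, (-math.inf, math.inf))
            mu = getattr(spec.base, name)
            for _ in range(100):
                v = rng.normal(mu, sd)
                if lo < v < hi:
                    break
            else:
                v = min(max(mu, lo + 1e-6), hi - 1e-6)
            draws[name] = float(v)
        params = replace(spec.base, **draws)
        dropout = None
        if rng.uniform() < spec.dropout_prob:
            ent = Entity.LEFT_CRUTCH if rng.uniform() < 0.5 else Entity.RIGHT_CRUTCH
            dropout = (ent, float(rng.uniform(2.0, 5.0)))
        traj, gt = generate_session(params, (), seed=int(child_seeds[2 * i + 1]), dropout=dropout)
        out.append((f"S{i + 1:02d}", traj, gt))
    return out
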