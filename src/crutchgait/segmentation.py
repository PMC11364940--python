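"""Movement-bout segmentation of marker trajectories.

Each tracked entity (crutch or foot) alternates between quiet stance and
short forward movements.  Bouts are detected on the speed of the entity's
reference marker (foot marker; crutch tip) with a velocity-hysteresis rule:
a bout opens when speed exceeds ``v_on`` and closes once speed has stayed
below ``v_off`` for at least ``min_quiet`` seconds.  The resulting
``MovementInterval`` list is the atomic event stream the gait-pattern
matcher consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gait_data import ENTITY_ROLES, Entity, Trajectory, reference_role

__all__ = [
    "SegmentationConfig",
    "MovementInterval",
    "SpeedSeries",
    "entity_speed",
    "detect_movement_intervals",
    "segment_trajectory",
    "detect_tracking_loss",
    "LossEpisode",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholds of the bout detector.

    Defaults separate walking-speed bouts (roughly 0.3-1 m/s at the marker)
    from residual marker jitter; none of them is dictated by the capture
    hardware, so all are configurable.
    """

    smooth_window: float = 0.2  # moving-average window (s)
    v_on: float = 0.10  # bout onset threshold (m/s)
    v_off: float = 0.05  # bout offset threshold, hysteresis (m/s)
    min_bout: float = 0.15  # discard shorter bouts (s)
    min_quiet: float = 0.20  # sub-threshold time required to close a bout (s)
    max_interp_gap: float = 0.2  # interpolate occlusions up to this long (s)

    def __post_init__(self) -> None:
        vals = (self.smooth_window, self.v_on, self.v_off, self.min_bout, self.min_quiet)
        if any(v <= 0 for v in vals):
            raise ValueError("all segmentation thresholds must be positive")
        if self.v_off > self.v_on:
            raise ValueError("v_off must not exceed v_on")


@dataclass(frozen=True)
class MovementInterval:
    """One movement bout of an entity."""

    entity: Entity
    t_on: float
    t_off: float
    displacement_w: float  # net walk-axis displacement (m)
    peak_speed: float  # m/s

    def __post_init__(self) -> None:
        if not self.t_on < self.t_off:
            raise ValueError("t_on must precede t_off")

    @property
    def duration(self) -> float:
        return self.t_off - self.t_on


@dataclass
class SpeedSeries:
    """Speed of an entity's reference marker over time.

    ``speed`` and ``w`` are NaN where the marker was occluded for longer
    than the interpolation limit; bouts never span such gaps.
    """

    entity: Entity
    t: np.ndarray
    speed: np.ndarray
    w: np.ndarray  # walk-axis position aligned with t (for displacement)


def _extract_positions(
    traj: Trajectory, entity: Entity
) -> tuple[np.ndarray, np.ndarray]:
    """Times and (x, y, w) of the entity reference marker; NaN when occluded."""
    role = reference_role(entity)
    t = np.array(traj.times(), dtype=float)
    pos = np.full((len(t), 3), np.nan)
    for i, f in enumerate(traj.frames):
        pt = f.points.get(role)
        if pt is not None:
            pos[i] = (pt.x, pt.y, pt.w)
    return t, pos


def _interpolate_short_gaps(t: np.ndarray, pos: np.ndarray, max_gap: float) -> np.ndarray:
    """Linearly bridge occlusion gaps no longer than ``max_gap`` seconds."""
    out = pos.copy()
    ok = ~np.isnan(pos[:, 0])
    if ok.all() or not ok.any():
        return out
    idx = np.flatnonzero(ok)
    for a, b in zip(idx, idx[1:]):
        if b - a > 1 and (t[b] - t[a]) <= max_gap:
            frac = (t[a + 1 : b] - t[a]) / (t[b] - t[a])
            out[a + 1 : b] = pos[a] + frac[:, None] * (pos[b] - pos[a])
    return out


def _smooth(t: np.ndarray, v: np.ndarray, window: float) -> np.ndarray:
    """NaN-aware moving average over a time window (assumes near-uniform rate)."""
    if len(t) < 3:
        return v.copy()
    dt = np.median(np.diff(t))
    n = max(1, int(round(window / dt)))
    if n <= 1:
        return v.copy()
    kernel = np.ones(n)
    valid = (~np.isnan(v)).astype(float)
    filled = np.where(np.isnan(v), 0.0, v)
    num = np.convolve(filled * valid, kernel, mode="same")
    den = np.convolve(valid, kernel, mode="same")
    out = np.where(den > 0, num / np.maximum(den, 1e-12), np.nan)
    out[np.isnan(v)] = np.nan
    return out


def entity_speed(
    traj: Trajectory, entity: Entity, cfg: SegmentationConfig = SegmentationConfig()
) -> SpeedSeries:
    """Speed (m/s) of the entity reference marker.

    Positions are smoothed with a moving average over ``cfg.smooth_window``
    before centered finite differencing.  Occlusions up to
    ``cfg.max_interp_gap`` are linearly interpolated; longer gaps yield NaN
    and split the series for bout detection.

    Raises
    ------
    ValueError
        If the entity is observed in fewer than two frames.
    """
    t, pos = _extract_positions(traj, entity)
    if (~np.isnan(pos[:, 0])).sum() < 2:
        raise ValueError(f"{entity.value}: fewer than 2 observed frames")
    pos = _interpolate_short_gaps(t, pos, cfg.max_interp_gap)
    sm = np.column_stack([_smooth(t, pos[:, k], cfg.smooth_window) for k in range(3)])
    speed = np.full(len(t), np.nan)
    for i in range(len(t)):
        lo, hi = max(0, i - 1), min(len(t) - 1, i + 1)
        if lo == hi:
            continue
        if np.isnan(sm[lo, 0]) or np.isnan(sm[hi, 0]):
            continue
        speed[i] = np.linalg.norm(sm[hi] - sm[lo]) / (t[hi] - t[lo])
    return SpeedSeries(entity=entity, t=t, speed=speed, w=sm[:, 2])


def detect_movement_intervals(
    series: SpeedSeries, cfg: SegmentationConfig = SegmentationConfig()
) -> list[MovementInterval]:
    """Hysteresis bout detection on a speed series.

    A bout opens when speed rises above ``v_on`` and closes at the first
    sample of a sub-``v_off`` stretch lasting at least ``min_quiet`` (or at
    a NaN gap / end of data).  Bouts shorter than ``min_bout`` are dropped.

    ``displacement_w`` is measured between the quiet plateaus flanking the
    bout (the calmest sample within one smoothing window outside each
    endpoint) rather than at the threshold crossings themselves; the marker
    is static there, so this avoids the slow movement tails that threshold
    crossings cut off.
    """
    t, v, w = series.t, series.speed, series.w
    dt = np.median(np.diff(t)) if len(t) > 1 else 1.0
    pad = max(1, int(round(cfg.smooth_window / dt)))

    def plateau_w(idx: int, direction: int) -> float:
        """w at the calmest sample within ``pad`` steps of idx (inclusive)."""
        best_i, best_v = idx, v[idx] if not np.isnan(v[idx]) else np.inf
        j = idx
        for _ in range(pad):
            j += direction
            if j < 0 or j >= len(t) or np.isnan(v[j]) or np.isnan(w[j]):
                break
            if v[j] > cfg.v_on:  # bleeding into a neighboring bout
                break
            if v[j] <= best_v:
                best_i, best_v = j, v[j]
        return w[best_i]
    out: list[MovementInterval] = []
    i, n = 0, len(t)
    while i < n:
        if np.isnan(v[i]) or v[i] <= cfg.v_on:
            i += 1
            continue
        start = i
        # advance until the bout closes
        j = i + 1
        close = None  # index of first sample of the closing quiet stretch
        quiet_start = None
        while j < n:
            if np.isnan(v[j]):
                close = j
                break
            if v[j] < cfg.v_off:
                if quiet_start is None:
                    quiet_start = j
                if t[j] - t[quiet_start] >= cfg.min_quiet:
                    close = quiet_start
                    break
            else:
                quiet_start = None
            j += 1
        if close is None:
            close = quiet_start if quiet_start is not None else n - 1
        end = close
        # sub-frame refinement of the threshold crossings: the frame grid
        # (33 ms at 30 Hz) is otherwise the dominant timing error
        t_on = float(t[start])
        if start > 0 and not np.isnan(v[start - 1]) and v[start] > v[start - 1]:
            frac = (cfg.v_on - v[start - 1]) / (v[start] - v[start - 1])
            if 0.0 <= frac <= 1.0:
                t_on = float(t[start - 1] + frac * (t[start] - t[start - 1]))
        t_off = float(t[end])
        if end > start and not np.isnan(v[end]) and not np.isnan(v[end - 1]) and v[end - 1] > v[end]:
            frac = (v[end - 1] - cfg.v_off) / (v[end - 1] - v[end])
            if 0.0 <= frac <= 1.0:
                t_off = float(t[end - 1] + frac * (t[end] - t[end - 1]))
        if t_off - t_on >= cfg.min_bout:
            seg = slice(start, end + 1)
            w0, w1 = plateau_w(start, -1), plateau_w(end, +1)
            disp = w1 - w0 if not (np.isnan(w0) or np.isnan(w1)) else np.nan
            out.append(
                MovementInterval(
                    entity=series.entity,
                    t_on=t_on,
                    t_off=t_off,
                    displacement_w=float(disp),
                    peak_speed=float(np.nanmax(v[seg])),
                )
            )
        i = max(j, end) + 1
    return out


def segment_trajectory(
    traj: Trajectory,
    cfg: SegmentationConfig = SegmentationConfig(),
    entities: tuple[Entity, ...] = tuple(Entity),
) -> list[MovementInterval]:
    """Detect bouts for all entities and merge them in onset order."""
    intervals: list[MovementInterval] = []
    for ent in entities:
        try:
            series = entity_speed(traj, ent, cfg)
        except ValueError:
            continue
        intervals.extend(detect_movement_intervals(series, cfg))
    return sorted(intervals, key=lambda iv: (iv.t_on, iv.entity.value))


@dataclass(frozen=True)
class LossEpisode:
    entity: Entity
    t_start: float
    t_end: float


def detect_tracking_loss(
    traj: Trajectory, entity: Entity, max_gap: float = 1.0
) -> list[LossEpisode]:
    """Episodes where every marker of the entity is absent for > ``max_gap`` s.

    A session with any episode is not analyzable for that entity (the
    live display loses the crutch and the exercise cannot be scored).
    """
    roles = ENTITY_ROLES[entity]
    ts = traj.times()
    if not ts:
        return []
    obs = [f.t for f in traj.frames if any(r in f.points for r in roles)]
    episodes: list[LossEpisode] = []
    if not obs:
        return [LossEpisode(entity, ts[0], ts[-1])]
    if obs[0] - ts[0] > max_gap:
        episodes.append(LossEpisode(entity, ts[0], obs[0]))
    for a, b in zip(obs, obs[1:]):
        if b - a > max_gap:
            episodes.append(LossEpisode(entity, a, b))
    if ts[-1] - obs[-1] > max_gap:
        episodes.append(LossEpisode(entity, obs[-1], ts[-1]))
    return episodes
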