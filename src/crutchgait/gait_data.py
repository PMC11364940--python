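"""Domain types and file I/O for marker trajectories.

The capture setup tracks six reflective markers: handle and tip of each
forearm crutch, plus one marker per foot.  Coordinates follow a right-handed
convention with ``w`` increasing along the walking direction, ``y`` up and
``x`` lateral; all positions in metres, time in seconds.

Trajectory files are long-format delimited text with a mandatory header
``t,role,x,y,w`` (comma- or tab-separated), one row per observed marker per
frame.  Occluded markers are simply absent rows, so occlusion survives a
write/read round trip.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

__all__ = [
    "MarkerRole",
    "Entity",
    "ENTITY_ROLES",
    "ROLE_ENTITY",
    "Point3",
    "Frame",
    "Trajectory",
    "TrajectoryError",
    "ValidationIssue",
    "read_trajectory",
    "write_trajectory",
    "validate_trajectory",
]


class TrajectoryError(ValueError):
    """Malformed trajectory file or invalid trajectory structure."""


class MarkerRole(str, enum.Enum):
    LEFT_CRUTCH_HANDLE = "left_crutch_handle"
    LEFT_CRUTCH_TIP = "left_crutch_tip"
    RIGHT_CRUTCH_HANDLE = "right_crutch_handle"
    RIGHT_CRUTCH_TIP = "right_crutch_tip"
    LEFT_FOOT = "left_foot"
    RIGHT_FOOT = "right_foot"


class Entity(str, enum.Enum):
    LEFT_CRUTCH = "left_crutch"
    RIGHT_CRUTCH = "right_crutch"
    LEFT_FOOT = "left_foot"
    RIGHT_FOOT = "right_foot"


#: Fixed, total mapping from each tracked entity to the roles it owns.
ENTITY_ROLES: dict[Entity, tuple[MarkerRole, ...]] = {
    Entity.LEFT_CRUTCH: (MarkerRole.LEFT_CRUTCH_HANDLE, MarkerRole.LEFT_CRUTCH_TIP),
    Entity.RIGHT_CRUTCH: (MarkerRole.RIGHT_CRUTCH_HANDLE, MarkerRole.RIGHT_CRUTCH_TIP),
    Entity.LEFT_FOOT: (MarkerRole.LEFT_FOOT,),
    Entity.RIGHT_FOOT: (MarkerRole.RIGHT_FOOT,),
}

ROLE_ENTITY: dict[MarkerRole, Entity] = {
    role: ent for ent, roles in ENTITY_ROLES.items() for role in roles
}


def reference_role(entity: Entity) -> MarkerRole:
    """Marker used as the entity's reference point (crutches: the tip)."""
    return ENTITY_ROLES[entity][-1]


@dataclass(frozen=True)
class Point3:
    """3D marker position: x lateral, y vertical (up), w along walk axis (m)."""

    x: float
    y: float
    w: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.w)):
            raise TrajectoryError(f"non-finite coordinates: {self}")


@dataclass
class Frame:
    """One time sample: partial mapping of roles to positions (absent = occluded)."""

    t: float
    points: dict[MarkerRole, Point3] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not math.isfinite(self.t):
            raise TrajectoryError(f"non-finite timestamp {self.t!r}")
        if not self.points:
            raise TrajectoryError(f"frame at t={self.t} has no markers")


@dataclass
class Trajectory:
    """Ordered frames of a capture session."""

    frames: list[Frame]
    nominal_rate: float = 30.0

    def __post_init__(self) -> None:
        if self.nominal_rate <= 0:
            raise TrajectoryError("nominal_rate must be positive")
        ts = [f.t for f in self.frames]
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise TrajectoryError("timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        if len(self.frames) < 2:
            return 0.0
        return self.frames[-1].t - self.frames[0].t

    def times(self) -> list[float]:
        return [f.t for f in self.frames]


def read_trajectory(path: str | Path, dialect: str | None = None) -> Trajectory:
    """Read a long-format ``t,role,x,y,w`` trajectory file.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    dialect
        Field separator; ``None`` auto-detects comma vs tab from the header.

    Raises
    ------
    TrajectoryError
        On malformed rows (with line number), unknown role labels, or
        non-monotone timestamps.
    """
    path = Path(path)
    sep = dialect
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, comment="#", skip_blank_lines=True)
    expected = ["t", "role", "x", "y", "w"]
    if list(df.columns) != expected:
        raise TrajectoryError(
            f"{path}: expected header {expected}, found {list(df.columns)}"
        )
    valid_roles = {r.value for r in MarkerRole}
    frames: list[Frame] = []
    current_t: float | None = None
    current_points: dict[MarkerRole, Point3] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            t = float(row.t)
            x, y, w = float(row.x), float(row.y), float(row.w)
        except (TypeError, ValueError) as exc:
            raise TrajectoryError(f"{path}:{i}: malformed row: {exc}") from exc
        if row.role not in valid_roles:
            raise TrajectoryError(f"{path}:{i}: unknown role label {row.role!r}")
        role = MarkerRole(row.role)
        try:
            pt = Point3(x, y, w)
        except TrajectoryError as exc:
            raise TrajectoryError(f"{path}:{i}: {exc}") from exc
        if current_t is None or t == current_t:
            current_t = t
        else:
            frames.append(Frame(current_t, current_points))
            current_t, current_points = t, {}
        if role in current_points:
            raise TrajectoryError(f"{path}:{i}: role {role.value} repeated at t={t}")
        current_points[role] = pt
    if current_t is not None:
        frames.append(Frame(current_t, current_points))
    try:
        return Trajectory(frames)
    except TrajectoryError as exc:
        raise TrajectoryError(f"{path}: {exc}") from exc


def write_trajectory(traj: Trajectory, path: str | Path, sep: str = ",") -> None:
    """Write a trajectory as long-format delimited text (9 significant digits).

    Refuses to write a trajectory with no frames.
    """
    if not traj.frames:
        raise TrajectoryError("refusing to write trajectory with no frames")
    path = Path(path)
    rows = []
    for f in traj.frames:
        for role in MarkerRole:  # fixed role order keeps output deterministic
            pt = f.points.get(role)
            if pt is not None:
                rows.append(
                    sep.join(
                        [
                            repr(float(f.t)),
                            role.value,
                            repr(float(pt.x)),
                            repr(float(pt.y)),
                            repr(float(pt.w)),
                        ]
                    )
                )
    header = sep.join(["t", "role", "x", "y", "w"])
    path.write_text(header + "\n" + "\n".join(rows) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class ValidationIssue:
    kind: str  # tracking_loss | duplicate_timestamp | rate_deviation
    t: float
    detail: str


def validate_trajectory(traj: Trajectory, max_gap: float = 1.0) -> list[ValidationIssue]:
    """Report data-quality issues; never raises.

    Checks per-role observation gaps longer than ``max_gap`` seconds
    (tracking loss), duplicate timestamps, and deviation of the realized
    frame rate from ``nominal_rate`` by more than 20%.
    """
    issues: list[ValidationIssue] = []
    ts = traj.times()
    seen: set[float] = set()
    for t in ts:
        if t in seen:
            issues.append(ValidationIssue("duplicate_timestamp", t, f"t={t} repeated"))
        seen.add(t)
    if len(ts) >= 2:
        rate = (len(ts) - 1) / (ts[-1] - ts[0])
        if abs(rate - traj.nominal_rate) > 0.2 * traj.nominal_rate:
            issues.append(
                ValidationIssue(
                    "rate_deviation",
                    ts[0],
                    f"realized rate {rate:.2f} Hz vs nominal {traj.nominal_rate} Hz",
                )
            )
    end = ts[-1] if ts else 0.0
    for entity in Entity:
        roles = ENTITY_ROLES[entity]
        obs = [f.t for f in traj.frames if any(r in f.points for r in roles)]
        if not obs:
            continue
        gaps: list[tuple[float, float]] = []
        prev = obs[0]
        for t in obs[1:]:
            if t - prev > max_gap:
                gaps.append((prev, t))
            prev = t
        if end - obs[-1] > max_gap:
            gaps.append((obs[-1], end))
        for g0, g1 in gaps:
            issues.append(
                ValidationIssue(
                    "tracking_loss",
                    g0,
                    f"{entity.value} unobserved {g0:.3f}-{g1:.3f} s",
                )
            )
    return issues
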