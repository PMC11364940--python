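"""Finite-state model of crutch walking patterns and the online matcher.

A walking pattern is a cyclic sequence of states; each state names the set
of entities that must all move (in any interleaving) before the state
completes.  The 3-point gait has two states per cycle: the injured foot and
both crutches advance together, then the non-injured foot follows.

The matcher replays detected movement bouts in onset order against the
expected state, emitting corrective ``ErrorEvent`` records — the analysis
analog of the live alert shown to the user — and resetting the expected
state after each error (the user is asked to repeat the movement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .gait_data import Entity
from .segmentation import MovementInterval

__all__ = [
    "GaitState",
    "GaitPattern",
    "StateInstance",
    "ErrorEvent",
    "MatcherConfig",
    "three_point_gait",
    "match_pattern",
    "exercise_outcome",
]

logger = logging.getLogger("crutchgait.pattern")


@dataclass(frozen=True)
class GaitState:
    name: str
    required: frozenset[Entity]

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError("a gait state must require at least one entity")


@dataclass(frozen=True)
class GaitPattern:
    """Cyclic sequence of states; consecutive states must differ."""

    states: tuple[GaitState, ...]
    injured_side: str  # "left" | "right"

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("pattern needs at least one state")
        n = len(self.states)
        if n > 1:
            for i in range(n):
                if self.states[i].required == self.states[(i + 1) % n].required:
                    raise ValueError("consecutive states must have different required sets")

    def state_after(self, index: int) -> int:
        return (index + 1) % len(self.states)


@dataclass(frozen=True)
class StateInstance:
    """A completed state: one bout per required entity."""

    state_index: int
    cycle: int
    intervals: dict[Entity, MovementInterval]
    t_start: float
    t_end: float


@dataclass(frozen=True)
class ErrorEvent:
    """A detected violation of the expected movement sequence."""

    t: float
    kind: str  # wrong_entity | wrong_order | incomplete_state
    offending: Entity | None
    expected: GaitState


@dataclass(frozen=True)
class MatcherConfig:
    #: a non-required bout starting within this long before the current
    #: state completes is attributed to the next state, not flagged
    boundary_tol: float = 0.1


def three_point_gait(injured_side: str) -> GaitPattern:
    """The 3-point gait: injured foot + both crutches, then the other foot.

    ``injured_side='left'`` gives State A = {left_foot, left_crutch,
    right_crutch} and State B = {right_foot}; ``'right'`` mirrors it.
    """
    if injured_side not in ("left", "right"):
        raise ValueError("injured_side must be 'left' or 'right'")
    injured = Entity.LEFT_FOOT if injured_side == "left" else Entity.RIGHT_FOOT
    other = Entity.RIGHT_FOOT if injured_side == "left" else Entity.LEFT_FOOT
    return GaitPattern(
        states=(
            GaitState(
                "injured_foot_and_crutches",
                frozenset({injured, Entity.LEFT_CRUTCH, Entity.RIGHT_CRUTCH}),
            ),
            GaitState("noninjured_foot", frozenset({other})),
        ),
        injured_side=injured_side,
    )


def match_pattern(
    intervals: list[MovementInterval],
    pattern: GaitPattern,
    tol: MatcherConfig = MatcherConfig(),
) -> tuple[list[StateInstance], list[ErrorEvent]]:
    """Greedy online matching of movement bouts against the pattern.

    Bouts are consumed in onset order.  The expected state completes when
    every required entity has finished one bout; required bouts may overlap
    or interleave freely within the state.  Violations become ErrorEvents:

    * ``wrong_entity`` — a bout of an entity the expected state does not
      require (unless it starts within ``tol.boundary_tol`` of the state's
      completion and belongs to the next state, in which case it is
      attributed there);
    * ``wrong_order`` — a required entity moving again before the state has
      completed (a within-cycle sequencing violation);
    * ``incomplete_state`` — trailing partial state at the end of the data.

    After an error the matcher resets and expects the current state from
    scratch; the offending bout is never silently re-labelled as progress.
    """
    intervals = sorted(intervals, key=lambda iv: iv.t_on)
    instances: list[StateInstance] = []
    errors: list[ErrorEvent] = []
    state_idx = 0
    cycle = 0
    pending: dict[Entity, MovementInterval] = {}
    carried: dict[Entity, MovementInterval] = {}  # boundary-tolerance carry-over

    def complete_state() -> None:
        # a carried-over bout may immediately complete the next state too
        nonlocal state_idx, cycle, pending
        while set(pending) >= pattern.states[state_idx].required:
            state = pattern.states[state_idx]
            inst = StateInstance(
                state_index=state_idx,
                cycle=cycle,
                intervals={e: pending[e] for e in state.required},
                t_start=min(pending[e].t_on for e in state.required),
                t_end=max(pending[e].t_off for e in state.required),
            )
            instances.append(inst)
            logger.debug("state %s completed (cycle %d) at t=%.3f", state.name, cycle, inst.t_end)
            nxt = pattern.state_after(state_idx)
            if nxt <= state_idx:
                cycle += 1
            state_idx = nxt
            pending = dict(carried)
            carried.clear()
            if not pending:
                break

    i = 0
    n = len(intervals)
    while i < n:
        bout = intervals[i]
        state = pattern.states[state_idx]
        if bout.entity in state.required:
            if bout.entity in pending:
                errors.append(ErrorEvent(bout.t_on, "wrong_order", bout.entity, state))
                logger.warning(
                    "wrong_order at t=%.3f: %s moved again before state %s completed",
                    bout.t_on, bout.entity.value, state.name,
                )
                pending = {}
                carried.clear()
            else:
                pending[bout.entity] = bout
                if set(pending) >= state.required:
                    complete_state()
        else:
            # boundary tolerance: the bout may belong to the next state if
            # the current one completes within tol of this onset
            nxt_state = pattern.states[pattern.state_after(state_idx)]
            attributed = False
            if bout.entity in nxt_state.required and bout.entity not in carried:
                missing = state.required - set(pending)
                j = i + 1
                ok = True
                sim = dict(pending)
                while missing and j < n and intervals[j].t_on - bout.t_on <= tol.boundary_tol:
                    if intervals[j].entity in missing:
                        sim[intervals[j].entity] = intervals[j]
                        missing = missing - {intervals[j].entity}
                    j += 1
                if not missing:
                    carried[bout.entity] = bout
                    attributed = True
            if not attributed:
                errors.append(ErrorEvent(bout.t_on, "wrong_entity", bout.entity, state))
                logger.warning(
                    "wrong_entity at t=%.3f: %s moved while state %s expected",
                    bout.t_on, bout.entity.value, state.name,
                )
                pending = {}
                carried.clear()
        i += 1
    if pending:
        state = pattern.states[state_idx]
        t_last = max(iv.t_off for iv in pending.values())
        errors.append(ErrorEvent(t_last, "incomplete_state", None, state))
    return instances, errors


def exercise_outcome(
    instances: list[StateInstance],
    errors: list[ErrorEvent],
    required_cycles: int,
    pattern: GaitPattern | None = None,
) -> str:
    """``'success'`` iff at least ``required_cycles`` complete cycles and no errors."""
    states_per_cycle = len(pattern.states) if pattern is not None else 2
    complete_cycles = len(instances) // states_per_cycle
    if errors or complete_cycles < required_cycles:
        return "error"
    return "success"
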