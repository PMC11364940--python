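"""End-to-end exercise evaluation and cohort comparison.

One exercise = one walkway traversal analyzed as
read → validate → (exclude on tracking loss) → segment → match → metrics →
outcome.  Subjects whose crutch tracking drops out mid-session are excluded
from every group statistic, mirroring how non-analyzable sessions are
handled in practice.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .gait_data import Entity, Trajectory, read_trajectory, validate_trajectory
from .metrics import MetricConfig, MetricRecord, aggregate_metrics, compute_metrics
from .pattern import (
    ErrorEvent,
    GaitPattern,
    MatcherConfig,
    exercise_outcome,
    match_pattern,
    three_point_gait,
)
from .segmentation import SegmentationConfig, detect_tracking_loss, segment_trajectory
from .stats import (
    box_m_test,
    format_p,
    levene_test,
    manova_two_group,
    one_way_anova,
)

__all__ = ["RunConfig", "ExerciseResult", "run_exercise", "analyze_trajectory",
           "render_report", "compare_cohorts"]

logger = logging.getLogger("crutchgait.session")

PATTERNS = {"three_point": three_point_gait}


@dataclass
class RunConfig:
    """Full configuration of an analysis run."""

    pattern: str = "three_point"
    injured_side: str = "left"
    required_cycles: int = 3
    max_gap: float = 1.0  # tracking-loss threshold (s)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    metric: MetricConfig = field(default_factory=MetricConfig)
    matcher: MatcherConfig = field(default_factory=MatcherConfig)
    log_level: str = "WARNING"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.required_cycles < 1:
            raise ValueError("required_cycles must be >= 1")
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")

    def build_pattern(self) -> GaitPattern:
        return PATTERNS[self.pattern](self.injured_side)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        met = MetricConfig(**raw.pop("metric", {}))
        mat = MatcherConfig(**raw.pop("matcher", {}))
        return cls(segmentation=seg, metric=met, matcher=mat, **raw)


@dataclass
class ExerciseResult:
    subject: str
    exercise: int
    status: str  # success | error | excluded
    error_events: list[ErrorEvent]
    metrics: list[MetricRecord]
    exclusion_reason: str | None = None  # tracking_loss | None

    def __post_init__(self) -> None:
        if (self.status == "excluded") != (self.exclusion_reason is not None):
            raise ValueError("status 'excluded' iff exclusion_reason set")


def analyze_trajectory(
    traj: Trajectory, cfg: RunConfig, subject: str = "S01", exercise: int = 0
) -> ExerciseResult:
    """Run the full pipeline on an in-memory trajectory."""
    for issue in validate_trajectory(traj, max_gap=cfg.max_gap):
        logger.info("%s ex%d: %s at t=%.2f: %s", subject, exercise, issue.kind, issue.t, issue.detail)
    for entity in Entity:
        if detect_tracking_loss(traj, entity, max_gap=cfg.max_gap):
            logger.warning("%s ex%d: tracking loss on %s — excluded", subject, exercise, entity.value)
            return ExerciseResult(subject, exercise, "excluded", [], [], "tracking_loss")
    pattern = cfg.build_pattern()
    intervals = segment_trajectory(traj, cfg.segmentation)
    instances, errors = match_pattern(intervals, pattern, cfg.matcher)
    records = compute_metrics(traj, instances, pattern, cfg.metric)
    status = exercise_outcome(instances, errors, cfg.required_cycles, pattern)
    return ExerciseResult(subject, exercise, status, errors, records)


def run_exercise(
    path: str | Path, cfg: RunConfig, subject: str | None = None, exercise: int = 0
) -> ExerciseResult:
    """Read a trajectory file and evaluate it as one exercise."""
    path = Path(path)
    traj = read_trajectory(path)
    return analyze_trajectory(traj, cfg, subject=subject or path.stem, exercise=exercise)


def render_report(results: list[ExerciseResult], out: str | Path) -> dict:
    """Write the status grid and a summary; returns the summary dict.

    Emits ``<out>.tsv`` (subject x exercise status grid) and ``<out>.json``
    (machine-readable summary).  Excluded subjects are listed separately and
    never enter the error counts.
    """
    if not results:
        raise ValueError("no results to report")
    out = Path(out)
    subjects = sorted({r.subject for r in results})
    exercises = sorted({r.exercise for r in results})
    grid = {(r.subject, r.exercise): r.status for r in results}
    lines = ["subject\t" + "\t".join(f"exercise_{e}" for e in exercises)]
    for s in subjects:
        lines.append(s + "\t" + "\t".join(grid.get((s, e), "") for e in exercises))
    out.with_suffix(".tsv").write_text("\n".join(lines) + "\n")

    excluded = sorted({r.subject for r in results if r.status == "excluded"})
    analyzable = [s for s in subjects if s not in excluded]
    err_counts = {
        s: sum(1 for r in results if r.subject == s and r.status == "error")
        for s in analyzable
    }
    by_count: dict[int, int] = {}
    for c in err_counts.values():
        if c > 0:
            by_count[c] = by_count.get(c, 0) + 1
    summary = {
        "subjects": len(subjects),
        "excluded": excluded,
        "analyzable": len(analyzable),
        "error_counts": {str(k): v for k, v in sorted(by_count.items())},
        "summary_lines": [
            f"{n} subjects with {k} incorrect exercise" + ("s" if k > 1 else "")
            for k, n in sorted(by_count.items())
        ],
    }
    out.with_suffix(".json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _subject_means(results_by_subject: dict[str, list[ExerciseResult]]) -> dict[str, dict]:
    """Per-subject metric means over all valid cycles; skips excluded subjects."""
    out = {}
    for subj, results in results_by_subject.items():
        if any(r.status == "excluded" for r in results):
            continue
        records = [m for r in results for m in r.metrics]
        if not records:
            continue
        out[subj] = aggregate_metrics(records)
    return out


def compare_cohorts(
    results_a: dict[str, list[ExerciseResult]],
    results_b: dict[str, list[ExerciseResult]],
    variables: tuple[str, str] = ("crutch_angle", "crutch_position"),
) -> dict:
    """Two-cohort comparison on per-subject metric means.

    Runs Levene (per variable) and Box's M diagnostics, the two-group MANOVA
    on the chosen variables, and a one-way ANOVA on correct-run counts.
    Excluded subjects never contribute to any statistic.
    """
    means_a = _subject_means(results_a)
    means_b = _subject_means(results_b)
    if len(means_a) < 2 or len(means_b) < 2:
        raise ValueError("need at least 2 analyzable subjects per cohort")

    def matrix(means: dict[str, dict]) -> np.ndarray:
        return np.array(
            [[means[s][v]["mean"] for v in variables] for s in sorted(means)]
        )

    A, B = matrix(means_a), matrix(means_b)
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("NaN metric means in analyzable subjects")
    man = manova_two_group(A, B)
    levene = {
        v: levene_test([A[:, i], B[:, i]]) for i, v in enumerate(variables)
    }
    M, chi2, df, p_box = box_m_test([A, B])

    def run_counts(results: dict[str, list[ExerciseResult]], keep: dict) -> list[int]:
        return [
            sum(1 for r in results[s] if r.status == "success") for s in sorted(keep)
        ]

    runs_a = run_counts(results_a, means_a)
    runs_b = run_counts(results_b, means_b)
    F, df1, df2, p_runs = one_way_anova([runs_a, runs_b])

    return {
        "n_a": len(means_a),
        "n_b": len(means_b),
        "variables": list(variables),
        "group_means": {
            "a": {v: float(A[:, i].mean()) for i, v in enumerate(variables)},
            "b": {v: float(B[:, i].mean()) for i, v in enumerate(variables)},
        },
        "group_sds": {
            "a": {v: float(A[:, i].std(ddof=1)) for i, v in enumerate(variables)},
            "b": {v: float(B[:, i].std(ddof=1)) for i, v in enumerate(variables)},
        },
        "manova": {
            "pillai": man.pillai,
            "wilks": man.wilks,
            "hotelling_trace": man.hotelling_trace,
            "roy": man.roy,
            "F": man.F,
            "df": [man.df1, man.df2],
            "p": man.p,
            "p_formatted": format_p(man.p),
        },
        "levene": {v: {"W": w, "p": p} for v, (w, p) in levene.items()},
        "box_m": {"M": M, "chi2": chi2, "df": df, "p": p_box},
        "correct_runs": {
            "a": runs_a,
            "b": runs_b,
            "F": F,
            "df": [df1, df2],
            "p": p_runs,
        },
    }


def format_manova_table(report: dict) -> str:
    """Render the MANOVA block in the conventional four-statistic layout."""
    m = report["manova"]
    dfs = f"({m['df'][0]}, {m['df'][1]})"
    rows = [
        ("Pillai trace", m["pillai"]),
        ("Wilks Lambda", m["wilks"]),
        ("Hotelling trace", m["hotelling_trace"]),
        ("Roy largest root", m["roy"]),
    ]
    lines = ["Test\tValue\tF (df)\tP value"]
    for name, val in rows:
        lines.append(f"{name}\t{val:.3f}\t{m['F']:.2f} {dfs}\t{m['p_formatted']}")
    return "\n".join(lines)
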