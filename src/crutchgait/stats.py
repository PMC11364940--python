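"""Evaluation statistics for the two-group crutch-training comparison.

Implements the statistical toolbox the study design calls for:

* the two-group MANOVA family — for two groups the matrix
  ``E^-1 H`` (within- and between-group SSCP) has a single nonzero
  eigenvalue ``lambda``, and the four classical statistics are closed
  forms of it: Pillai = lambda/(1+lambda), Wilks = 1/(1+lambda),
  Hotelling trace = Roy's largest root = lambda, with exact
  ``F = lambda (N - p - 1) / p`` on ``(p, N - p - 1)`` degrees of freedom;
* Levene's homogeneity-of-variance test and Box's M test for equality of
  covariance matrices (the MANOVA's assumption checks);
* one-way ANOVA for the correct-run comparison;
* exact pooling of group summaries (mean, SD) into a combined summary;
* System Usability Scale (SUS) scoring with the conventional 68-point
  above-average threshold, questionnaire proportions, and Pearson
  correlation.

Only scipy's F/chi-square/t distribution functions are used; the test
statistics themselves are computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _dist

__all__ = [
    "GroupSummary",
    "ManovaResult",
    "SusResponse",
    "manova_two_group",
    "manova_stats_from_eigenvalue",
    "levene_test",
    "box_m_test",
    "one_way_anova",
    "combined_summary",
    "sus_score",
    "above_average_fraction",
    "proportion_yes",
    "pearson_correlation",
    "welch_t_test",
    "pooled_t_test",
    "format_p",
]


# --------------------------------------------------------------------------
# group summaries


@dataclass(frozen=True)
class GroupSummary:
    """Per-variable mean and sample SD (n-1 denominator) of one group."""

    n: int
    mean: Mapping[str, float]
    sd: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if set(self.mean) != set(self.sd):
            raise ValueError("mean and sd must cover the same variables")
        if any(s < 0 for s in self.sd.values()):
            raise ValueError("SDs must be non-negative")


def combined_summary(a: GroupSummary, b: GroupSummary) -> GroupSummary:
    """Exact pooling of two group summaries.

    Combined mean is the n-weighted mean; combined SD is recovered from the
    total sum of squares (within + between) with the usual ``N - 1``
    denominator, i.e. the SD one would compute from the concatenated data.
    """
    if set(a.mean) != set(b.mean):
        raise ValueError("groups summarize different variables")
    N = a.n + b.n
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    for var in a.mean:
        m = (a.n * a.mean[var] + b.n * b.mean[var]) / N
        ss = (
            (a.n - 1) * a.sd[var] ** 2
            + (b.n - 1) * b.sd[var] ** 2
            + a.n * (a.mean[var] - m) ** 2
            + b.n * (b.mean[var] - m) ** 2
        )
        mean[var] = m
        sd[var] = math.sqrt(ss / (N - 1))
    return GroupSummary(n=N, mean=mean, sd=sd)


# --------------------------------------------------------------------------
# two-group MANOVA


@dataclass(frozen=True)
class ManovaResult:
    eigenvalue: float  # the single nonzero eigenvalue of E^-1 H
    pillai: float
    wilks: float
    hotelling_trace: float
    roy: float
    F: float
    df1: int
    df2: int
    p: float


def manova_stats_from_eigenvalue(lam: float, N: int, p: int) -> ManovaResult:
    """Closed-form two-group MANOVA statistics from the eigenvalue.

    With two groups there is exactly one nonzero eigenvalue ``lam`` of
    ``E^-1 H`` and the exact F transform is
    ``F = lam (N - p - 1) / p`` on ``(p, N - p - 1)`` df.
    """
    if lam < 0:
        raise ValueError("eigenvalue must be non-negative")
    if p < 1 or N <= p + 1:
        raise ValueError("need N > p + 1 and p >= 1")
    df1, df2 = p, N - p - 1
    F = lam * df2 / df1
    pval = float(_dist.f.sf(F, df1, df2)) if F > 0 else 1.0
    return ManovaResult(
        eigenvalue=lam,
        pillai=lam / (1.0 + lam),
        wilks=1.0 / (1.0 + lam),
        hotelling_trace=lam,
        roy=lam,
        F=F,
        df1=df1,
        df2=df2,
        p=pval,
    )


def manova_two_group(samples_a: np.ndarray, samples_b: np.ndarray) -> ManovaResult:
    """Two-group MANOVA from raw per-subject observations (rows x variables).

    Forms the between-group (H) and within-group (E) SSCP matrices and
    extracts the single nonzero eigenvalue of ``E^-1 H``.
    """
    A = np.atleast_2d(np.asarray(samples_a, dtype=float))
    B = np.atleast_2d(np.asarray(samples_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must have the same variables")
    p = A.shape[1]
    n_a, n_b = A.shape[0], B.shape[0]
    N = n_a + n_b
    if N < p + 2:
        raise ValueError(f"need at least p + 2 = {p + 2} observations, got {N}")
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    grand = (n_a * ma + n_b * mb) / N
    H = n_a * np.outer(ma - grand, ma - grand) + n_b * np.outer(mb - grand, mb - grand)
    E = (A - ma).T @ (A - ma) + (B - mb).T @ (B - mb)
    # singular E -> name the deficient variable(s)
    diag = np.diag(E)
    if np.any(diag <= 0) or np.linalg.matrix_rank(E) < p:
        bad = [str(i) for i in np.flatnonzero(diag <= 0)]
        raise ValueError(
            "within-group SSCP is singular"
            + (f" (zero-variance variable index {', '.join(bad)})" if bad else "")
        )
    eig = np.linalg.eigvals(np.linalg.solve(E, H))
    lam = float(np.max(eig.real))
    lam = max(lam, 0.0)
    return manova_stats_from_eigenvalue(lam, N, p)


# --------------------------------------------------------------------------
# assumption checks


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, int, int, float]:
    """Classic one-way ANOVA; returns (F, df1, df2, p).

    Zero between- and within-group variance gives F = 0, p = 1 by
    convention.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 1 for g in gs):
        raise ValueError("empty group")
    N = sum(len(g) for g in gs)
    k = len(gs)
    if N <= k:
        raise ValueError("need total n > number of groups")
    grand = np.concatenate(gs).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in gs)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in gs)
    df1, df2 = k - 1, N - k
    if ssw == 0:
        if ssb == 0:
            return 0.0, df1, df2, 1.0
        return math.inf, df1, df2, 0.0
    F = (ssb / df1) / (ssw / df2)
    return float(F), df1, df2, float(_dist.f.sf(F, df1, df2))


def levene_test(
    groups: Sequence[Sequence[float]], center: str = "mean"
) -> tuple[float, float]:
    """Levene's test of variance homogeneity; returns (W, p).

    The classic form uses absolute deviations from the group means fed into
    a one-way ANOVA; ``center='median'`` gives the Brown-Forsythe variant.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    devs = [
        np.abs(g - (g.mean() if center == "mean" else np.median(g))) for g in gs
    ]
    W, _, _, p = one_way_anova(devs)
    return W, p


def box_m_test(groups: Sequence[np.ndarray]) -> tuple[float, float, int, float]:
    """Box's M test of covariance-matrix equality; returns (M, chi2, df, p).

    Standard log-determinant form with the chi-square approximation.
    """
    gs = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    k = len(gs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    p = gs[0].shape[1]
    if any(g.shape[1] != p for g in gs):
        raise ValueError("groups must share variables")
    ns = [g.shape[0] for g in gs]
    if any(n <= p for n in ns):
        raise ValueError("each group needs n > p")
    covs = [np.cov(g, rowvar=False, ddof=1) for g in gs]
    covs = [np.atleast_2d(c) for c in covs]
    for i, c in enumerate(covs):
        if np.linalg.det(c) <= 0:
            raise ValueError(f"group {i} covariance is singular")
    N = sum(ns)
    S_pooled = sum((n - 1) * c for n, c in zip(ns, covs)) / (N - k)
    M = (N - k) * math.log(np.linalg.det(S_pooled)) - sum(
        (n - 1) * math.log(np.linalg.det(c)) for n, c in zip(ns, covs)
    )
    c1 = (
        (2 * p**2 + 3 * p - 1)
        / (6 * (p + 1) * (k - 1))
        * (sum(1 / (n - 1) for n in ns) - 1 / (N - k))
    )
    chi2 = M * (1 - c1)
    df = (k - 1) * p * (p + 1) // 2
    return float(M), float(chi2), df, float(_dist.chi2.sf(chi2, df))


# --------------------------------------------------------------------------
# univariate follow-ups (neither claims to reproduce any published value)


def pooled_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return float(t), float(2 * _dist.t.sf(abs(t), df))


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(t), float(2 * _dist.t.sf(abs(t), df))


# --------------------------------------------------------------------------
# questionnaires


@dataclass(frozen=True)
class SusResponse:
    """One System Usability Scale response: 10 Likert items in 1..5."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != 10:
            raise ValueError("SUS has exactly 10 items")
        if any(not (1 <= int(v) <= 5) or int(v) != v for v in self.items):
            raise ValueError("items must be integers in 1..5")


def sus_score(resp: SusResponse | Sequence[int]) -> float:
    """Brooke's SUS score in [0, 100].

    Odd items (1-indexed) contribute ``r - 1``, even items ``5 - r``; the
    sum is scaled by 2.5.
    """
    if not isinstance(resp, SusResponse):
        resp = SusResponse(tuple(int(v) for v in resp))
    total = 0
    for i, r in enumerate(resp.items, start=1):
        total += (r - 1) if i % 2 == 1 else (5 - r)
    return total * 2.5


def above_average_fraction(
    scores: Sequence[float], threshold: float = 68.0
) -> tuple[int, int]:
    """(count, percent) of scores strictly above the usability threshold."""
    scores = list(scores)
    if not scores:
        raise ValueError("need at least one score")
    count = sum(1 for s in scores if s > threshold)
    return count, proportion_yes(count, len(scores))


def proportion_yes(k: int, n: int) -> int:
    """Integer percent of agreement, rounded half away from zero."""
    if n <= 0 or not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n, n > 0")
    x = 100.0 * k / n
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p-value."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx, sy = math.sqrt((xd**2).sum()), math.sqrt((yd**2).sum())
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float((xd * yd).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r**2))
    return r, float(2 * _dist.t.sf(abs(t), n - 2))


def format_p(p: float) -> str:
    """Clinical-journal style: 3 decimals without leading zero, '<.001' floor."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0")
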