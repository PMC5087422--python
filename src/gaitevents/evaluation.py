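"""Accuracy (precision / recall / F1) and timing agreement between event streams.

Detected events are matched to a reference stream one-to-one, greedily by
nearest time within a tolerance (default 400 ms) and same kind.  Timing
agreement is summarised Bland-Altman style: mean difference (MD), absolute mean
difference (AMD), limits of agreement MD +/- 1.96 SD, and a normal-theory 95%
confidence interval of the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import EventKind, GaitEvent

__all__ = [
    "MatchResult",
    "AccuracyReport",
    "TimingReport",
    "match_events",
    "prf1",
    "timing_agreement",
    "plot_bland_altman",
]


@dataclass(frozen=True)
class MatchResult:
    """One-to-one event matches plus the per-kind TP/FP/FN tallies."""

    pairs: list[tuple[GaitEvent, GaitEvent]]  # (detected, reference)
    TP: dict[EventKind, int]
    FP: dict[EventKind, int]
    FN: dict[EventKind, int]
    tolerance: float

    def counts(self, kind: EventKind | None = None) -> tuple[int, int, int]:
        """(TP, FP, FN), pooled over kinds when ``kind`` is None."""
        if kind is not None:
            return self.TP[kind], self.FP[kind], self.FN[kind]
        return (sum(self.TP.values()), sum(self.FP.values()), sum(self.FN.values()))


@dataclass(frozen=True)
class AccuracyReport:
    P: float
    R: float
    F1: float


@dataclass(frozen=True)
class TimingReport:
    """Bland-Altman style timing summary; all times in milliseconds."""

    diffs: np.ndarray  # per-pair t_detected - t_reference, ms
    means: np.ndarray  # per-pair (t_detected + t_reference)/2, the plot x-axis
    MD: float
    MD_SD: float
    AMD: float
    AMD_SD: float
    loa_low: float
    loa_high: float
    ci95: tuple[float, float]


def match_events(
    detected: list[GaitEvent],
    reference: list[GaitEvent],
    tolerance: float = 0.4,
) -> MatchResult:
    """Greedy nearest-in-time one-to-one matching within ``tolerance`` seconds.

    Candidate pairs require equal kind; pairs are taken in order of increasing
    time difference, each event participating at most once.  Unmatched detected
    events count as false positives, unmatched references as false negatives.
    """
    candidates = [
        (abs(d.t - r.t), i, j)
        for i, d in enumerate(detected)
        for j, r in enumerate(reference)
        if d.kind == r.kind and abs(d.t - r.t) <= tolerance
    ]
    candidates.sort()
    used_d: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[GaitEvent, GaitEvent]] = []
    for _, i, j in candidates:
        if i in used_d or j in used_r:
            continue
        used_d.add(i)
        used_r.add(j)
        pairs.append((detected[i], reference[j]))
    pairs.sort(key=lambda p: p[1].t)
    TP = {k: 0 for k in EventKind}
    FP = {k: 0 for k in EventKind}
    FN = {k: 0 for k in EventKind}
    for d, _ in pairs:
        TP[d.kind] += 1
    for i, d in enumerate(detected):
        if i not in used_d:
            FP[d.kind] += 1
    for j, r in enumerate(reference):
        if j not in used_r:
            FN[r.kind] += 1
    return MatchResult(pairs=pairs, TP=TP, FP=FP, FN=FN, tolerance=tolerance)


def prf1(TP: int, FP: int, FN: int) -> AccuracyReport:
    """Precision, recall and F1 with zero-denominator conventions set to 0."""
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be non-negative")
    P = TP / (TP + FP) if TP + FP else 0.0
    R = TP / (TP + FN) if TP + FN else 0.0
    F1 = 2 * P * R / (P + R) if P + R else 0.0
    return AccuracyReport(P=P, R=R, F1=F1)


def timing_agreement(match: MatchResult) -> TimingReport:
    """Bland-Altman summary of the matched pairs' timing differences (ms)."""
    if len(match.pairs) < 2:
        raise ValueError("timing agreement needs at least 2 matched pairs")
    diffs = np.array([(d.t - r.t) * 1000.0 for d, r in match.pairs])
    means = np.array([(d.t + r.t) / 2.0 * 1000.0 for d, r in match.pairs])
    n = len(diffs)
    MD = float(np.mean(diffs))
    SD = float(np.std(diffs, ddof=1))
    abs_diffs = np.abs(diffs)
    return TimingReport(
        diffs=diffs,
        means=means,
        MD=MD,
        MD_SD=SD,
        AMD=float(np.mean(abs_diffs)),
        AMD_SD=float(np.std(abs_diffs, ddof=1)),
        loa_low=MD - 1.96 * SD,
        loa_high=MD + 1.96 * SD,
        ci95=(MD - 1.96 * SD / np.sqrt(n), MD + 1.96 * SD / np.sqrt(n)),
    )


def plot_bland_altman(report: TimingReport, ax=None, title: str | None = None):
    """Bland-Altman plot: per-pair differences vs means with MD and 1.96 SD limits."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(report.means, report.diffs, s=12)
    ax.axhline(report.MD, color="k", label=f"MD = {report.MD:.1f} ms")
    for y in (report.loa_low, report.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel("mean of the two timings (ms)")
    ax.set_ylabel("timing difference (ms)")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
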