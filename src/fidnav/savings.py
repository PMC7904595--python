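"""Scan-abort analysis: running motion scores, time savings, and costs.

A motion-monitoring workflow aborts a scan as soon as its running integrated
motion score crosses a predefined threshold.  For a truly non-diagnostic scan
(a true positive) the fraction of the scan remaining at detection, FR, is
time saved — the scan would otherwise run to completion and be repeated, at
a baseline cost of twice the acquisition time TA.  For a diagnostic scan
falsely aborted (a false positive) the fraction already acquired, FA, is time
wasted restarting.  The aggregate time saving over a cohort is

    T_savings(%) = 100 * (sum_TP FR - sum_FP FA) / (2*(nTP + nFN) + nTN + nFP)

in units of TA, with every non-diagnostic scan counted twice in the
no-monitoring baseline.  Dollar figures follow from the cost of a scanner
slot: cost_per_minute = slot_cost / slot_minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fidnav.metrics import MotionMetricSeries


@dataclass(frozen=True)
class CostModel:
    """Scanner-slot economics: slot price (USD), slot length and scan length (min)."""

    slot_cost: float = 2828.0
    slot_minutes: float = 45.0
    ta_minutes: float = 4.2

    def __post_init__(self) -> None:
        if self.slot_cost <= 0 or self.slot_minutes <= 0 or self.ta_minutes <= 0:
            raise ValueError("cost model fields must be positive")

    @property
    def cost_per_minute(self) -> float:
        return self.slot_cost / self.slot_minutes


@dataclass
class AbortOutcome:
    """Threshold-crossing result for one scan.

    ``truth`` is True for a genuinely non-diagnostic scan.  ``fr`` and
    ``fa`` are None when the threshold is never crossed.
    """

    subject_id: str
    detected: bool
    truth: bool
    crossing_index: int | None = None
    fr: float | None = None
    fa: float | None = None

    @property
    def is_tp(self) -> bool:
        return self.detected and self.truth

    @property
    def is_fp(self) -> bool:
        return self.detected and not self.truth


@dataclass
class SavingsReport:
    t_savings_pct: float
    ntp: int
    nfp: int
    ntn: int
    nfn: int
    minutes_saved: float | None = None
    minutes_wasted: float | None = None
    repeat_cost: float | None = None
    net_cost_saving: float | None = None
    cost_per_minute: float | None = None


def running_score(metric: MotionMetricSeries, n: int, tr_seconds: float) -> np.ndarray:
    """Per-TR cumulative motion score, scaled by ``1/(n*TR)``.

    Non-decreasing; the final element equals the integrated score of the
    full trace.  Element ``k`` is the score available after acquiring TR
    ``metric.start_index + k``.
    """
    if len(metric) == 0:
        raise ValueError("empty metric trace")
    if np.any(metric.values < 0):
        raise ValueError("running score requires non-negative metric values")
    if tr_seconds <= 0 or n < len(metric):
        raise ValueError("invalid n or tr_seconds")
    return np.cumsum(metric.values) / (n * tr_seconds)


def abort_decision(
    running: np.ndarray,
    threshold: float,
    n: int,
    start_index: int = 2,
    subject_id: str = "",
    truth: bool = False,
) -> AbortOutcome:
    """First threshold crossing of a running score.

    The crossing TR is ``i* = start_index + k`` for the first element ``k``
    with ``running[k] >= threshold``; then ``FA = i*/n`` and ``FR = 1 - FA``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    running = np.asarray(running, dtype=float)
    hits = np.nonzero(running >= threshold)[0]
    if hits.size == 0:
        return AbortOutcome(subject_id=subject_id, detected=False, truth=truth)
    i_star = start_index + int(hits[0])
    fa = i_star / n
    return AbortOutcome(
        subject_id=subject_id,
        detected=True,
        truth=truth,
        crossing_index=i_star,
        fa=fa,
        fr=1.0 - fa,
    )


def _counts(outcomes: list[AbortOutcome]) -> tuple[int, int, int, int]:
    ntp = sum(o.is_tp for o in outcomes)
    nfp = sum(o.is_fp for o in outcomes)
    nfn = sum((not o.detected) and o.truth for o in outcomes)
    ntn = sum((not o.detected) and not o.truth for o in outcomes)
    return ntp, nfp, ntn, nfn


def time_savings(
    outcomes: list[AbortOutcome], baseline: str = "all_nondiagnostic_double"
) -> SavingsReport:
    """Aggregate percentage time saving over a cohort of abort outcomes.

    The numerator is the FR sum over true positives minus the FA sum over
    false positives.  The default baseline counts every non-diagnostic scan
    (detected or not) at ``2*TA`` — acquisition plus repeat — giving the
    denominator ``2*(nTP + nFN) + nTN + nFP``; ``baseline="detected_double"``
    instead doubles only the detected ones (``2*nTP + nFN + nTN + nFP``).
    """
    if not outcomes:
        raise ValueError("empty cohort")
    ntp, nfp, ntn, nfn = _counts(outcomes)
    fr_sum = sum(o.fr for o in outcomes if o.is_tp)
    fa_sum = sum(o.fa for o in outcomes if o.is_fp)
    if baseline == "all_nondiagnostic_double":
        denom = 2 * (ntp + nfn) + ntn + nfp
    elif baseline == "detected_double":
        denom = 2 * ntp + nfn + ntn + nfp
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    pct = 100.0 * (fr_sum - fa_sum) / denom
    return SavingsReport(t_savings_pct=pct, ntp=ntp, nfp=nfp, ntn=ntn, nfn=nfn)


def cost_report(
    grades: np.ndarray,
    outcomes: list[AbortOutcome],
    cost: CostModel = CostModel(),
    baseline: str = "all_nondiagnostic_double",
) -> SavingsReport:
    """Dollar-figure savings report for a cohort.

    ``repeat_cost`` is the no-monitoring cost of reacquiring every grade-1/2
    scan; ``net_cost_saving`` converts the saved-minus-wasted minutes of
    monitoring into dollars at the per-minute slot rate.
    """
    report = time_savings(outcomes, baseline=baseline)
    grades = np.asarray(grades, dtype=int)
    n_repeat = int(np.sum(grades <= 2))
    cpm = cost.cost_per_minute
    minutes_saved = sum(o.fr for o in outcomes if o.is_tp) * cost.ta_minutes
    minutes_wasted = sum(o.fa for o in outcomes if o.is_fp) * cost.ta_minutes
    report.cost_per_minute = cpm
    report.repeat_cost = n_repeat * cost.ta_minutes * cpm
    report.minutes_saved = minutes_saved
    report.minutes_wasted = minutes_wasted
    report.net_cost_saving = (minutes_saved - minutes_wasted) * cpm
    return report


def optimize_threshold_for_savings(
    runnings: list[np.ndarray],
    truths: list[bool],
    n: int,
    start_indices: list[int] | int = 2,
    baseline: str = "all_nondiagnostic_double",
) -> tuple[float, float]:
    """Threshold directly maximizing the aggregate time saving.

    Grid search over the union of all final integrated scores plus the
    midpoints between consecutive candidates; ties are broken toward the
    larger threshold (fewer false aborts).
    """
    if not runnings or len(runnings) != len(truths):
        raise ValueError("need matching running scores and truth labels")
    if not any(truths) or all(truths):
        raise ValueError("need at least one subject per class")
    if isinstance(start_indices, int):
        start_indices = [start_indices] * len(runnings)
    finals = np.unique([r[-1] for r in runnings if r[-1] > 0])
    if finals.size == 0:
        raise ValueError("all running scores are zero; no candidate thresholds")
    mids = (finals[:-1] + finals[1:]) / 2.0
    candidates = np.unique(np.concatenate([finals, mids]))
    savings_at = np.empty(len(candidates))
    for k, c in enumerate(candidates):
        outcomes = [
            abort_decision(r, c, n, start_index=s, subject_id=str(m), truth=t)
            for m, (r, s, t) in enumerate(zip(runnings, start_indices, truths))
        ]
        savings_at[k] = time_savings(outcomes, baseline=baseline).t_savings_pct
    best = savings_at.max()
    eligible = candidates[savings_at >= best - 1e-12]
    return float(eligible.max()), float(best)
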