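"""Per-scan integrated motion scores, with optional k-space partition weighting.

A per-TR metric trace is collapsed into a single motion score per scan by
numerical integration over the acquisition,

    score = 1 / (n * TR) * sum_i metric_i            (units: 1/s)

where ``n`` is the number of outer phase-encoding steps (one per TR).  The
weighted variant multiplies each term by a non-negative weight ``w_i``
proportional to the energy of the k-space plane acquired at step ``i``:
motion during the high-energy central planes degrades the image more than
motion at the periphery.  Weights are normalized to unit mean so weighted and
unweighted scores are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fidnav.metrics import MotionMetricSeries

#: Display multiplier per metric (the ccc score is conventionally reported x100).
REPORT_SCALE = {"delta_ref": 1.0, "delta": 1.0, "delta_max": 1.0, "ccc": 100.0}


@dataclass
class KspaceWeighting:
    """Non-negative per-phase-encoding-step weights, unit mean, in acquisition order."""

    w: np.ndarray
    source: str = ""
    normalized: bool = True

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1 or self.w.size == 0:
            raise ValueError("weights must be a non-empty 1-D array")
        if np.any(self.w < 0) or not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite and non-negative")
        if self.normalized and abs(self.w.mean() - 1.0) > 1e-9:
            raise ValueError("weights must be normalized to unit mean")

    def __len__(self) -> int:
        return len(self.w)


@dataclass
class IntegratedScore:
    """Integrated motion score of one scan for one metric, in 1/s."""

    value: float
    metric_name: str
    weighted: bool = False
    report_scale: float = 1.0

    @property
    def display_value(self) -> float:
        """Score on the reporting scale (e.g. ccc x 100)."""
        return self.value * self.report_scale


def integrate_score(
    metric: MotionMetricSeries, n: int, tr_seconds: float
) -> IntegratedScore:
    """Integrate a per-TR metric trace into a per-scan score.

    ``n`` is the total number of phase-encoding steps; a trace starting at
    TR 2 contributes ``n - 1`` terms.
    """
    if len(metric) == 0:
        raise ValueError("empty metric trace")
    if n < len(metric):
        raise ValueError(f"n={n} smaller than trace length {len(metric)}")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    value = float(metric.values.sum() / (n * tr_seconds))
    return IntegratedScore(
        value=value,
        metric_name=metric.metric_name,
        weighted=False,
        report_scale=REPORT_SCALE.get(metric.metric_name, 1.0),
    )


def kspace_weights_from_reference(volumes: list[np.ndarray]) -> KspaceWeighting:
    """Weights from the norms of acquired k-space planes of reference subjects.

    Each volume is a magnitude k-space array whose first axis is the outer
    phase-encoding direction, in acquisition order.  Per plane the Euclidean
    norm is taken, the per-plane norms are averaged across subjects, and the
    profile is normalized to unit mean.
    """
    if not volumes:
        raise ValueError("no reference volumes")
    n = volumes[0].shape[0]
    norms = []
    for v in volumes:
        v = np.asarray(v)
        if v.shape[0] != n:
            raise ValueError("reference volumes disagree on the plane count")
        norms.append(np.sqrt((np.abs(v) ** 2).reshape(v.shape[0], -1).sum(axis=1)))
    mean_norm = np.mean(norms, axis=0)
    if mean_norm.sum() == 0:
        raise ValueError("reference k-space is identically zero")
    return KspaceWeighting(mean_norm / mean_norm.mean(), source=f"{len(volumes)} reference subject(s)")


def default_weighting(n: int) -> KspaceWeighting:
    """Packaged smooth center-peaked weighting for CSV-only users.

    Emulates the empirical plane-norm profile of a compliant adult cohort: a
    Gaussian bump centered halfway through the acquisition (the k-space
    center) on a flat baseline, peak-to-periphery ratio ~4, unit mean.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    steps = np.arange(1, n + 1, dtype=float)
    center = (n + 1) / 2.0
    w = 1.0 + 3.0 * np.exp(-0.5 * ((steps - center) / (n / 8.0)) ** 2)
    return KspaceWeighting(w / w.mean(), source="packaged default (center-peaked)")


def weighted_integrate(
    metric: MotionMetricSeries,
    weights: KspaceWeighting,
    n: int,
    tr_seconds: float,
) -> IntegratedScore:
    """Partition-weighted integrated score: ``1/(n*TR) * sum_i w_i * metric_i``.

    The trace index is mapped to the phase-encoding step in acquisition
    order: ``metric.values[k]`` pairs with ``w[start_index - 1 + k]``.
    """
    if len(weights) != n:
        raise ValueError(f"weights length {len(weights)} != n={n}")
    if len(metric) == 0:
        raise ValueError("empty metric trace")
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    lo = metric.start_index - 1
    hi = lo + len(metric)
    if hi > n:
        raise ValueError("metric trace extends beyond the weight vector")
    value = float((weights.w[lo:hi] * metric.values).sum() / (n * tr_seconds))
    return IntegratedScore(
        value=value,
        metric_name=metric.metric_name,
        weighted=True,
        report_scale=REPORT_SCALE.get(metric.metric_name, 1.0),
    )
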