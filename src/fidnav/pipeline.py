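"""End-to-end helpers chaining preprocessing, metrics and integration.

These functions are the library's working surface for cohort-level analysis:
score one navigator series, or walk a cohort directory (as produced by
:func:`fidnav.simulate.generate_cohort` or assembled by hand) and return a
tidy per-subject score table ready for the detection and savings stages.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from fidnav.integration import KspaceWeighting, integrate_score, weighted_integrate
from fidnav.io import read_navigator_csv
from fidnav.metrics import METRIC_NAMES, MotionMetricSeries, compute_all_metrics
from fidnav.preprocess import FidnavSeries, reference_signal, trim_presteady


def process_series(
    series: FidnavSeries,
    n_discard: int = 3,
    n_ref: int = 3,
    top_k: int = 3,
) -> tuple[FidnavSeries, dict[str, MotionMetricSeries]]:
    """Trim the pre-steady-state TRs and compute the four metric traces."""
    trimmed = trim_presteady(series, n_discard=n_discard)
    ref = reference_signal(trimmed, n_ref=n_ref)
    return trimmed, compute_all_metrics(trimmed, ref=ref, top_k=top_k)


def score_series(
    series: FidnavSeries,
    weights: KspaceWeighting | None = None,
    n_discard: int = 3,
    n_ref: int = 3,
) -> dict[str, float]:
    """Integrated (and, given weights, partition-weighted) scores of one scan.

    Returns ``{metric: score}`` plus ``{"w_" + metric: weighted score}``
    when a weighting is supplied, all in 1/s on the natural scale.
    """
    trimmed, metrics = process_series(series, n_discard=n_discard, n_ref=n_ref)
    n = trimmed.n_steps
    out: dict[str, float] = {}
    for name, trace in metrics.items():
        out[name] = integrate_score(trace, n, trimmed.tr_seconds).value
        if weights is not None:
            out["w_" + name] = weighted_integrate(
                trace, weights, n, trimmed.tr_seconds
            ).value
    return out


def score_cohort(
    cohort_dir: str | Path,
    weights: KspaceWeighting | None = None,
    n_discard: int = 3,
    n_ref: int = 3,
) -> pd.DataFrame:
    """Score every subject listed in ``<cohort_dir>/manifest.csv``.

    If ``weights`` is None and the directory contains ``weights.csv`` (as
    written by the simulator), that weighting is used.  Returns one row per
    subject with the grade and all integrated score variants.
    """
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    if weights is None:
        wfile = cohort_dir / "weights.csv"
        if wfile.exists():
            wdf = pd.read_csv(wfile)
            weights = KspaceWeighting(
                wdf["weight"].to_numpy(), source=str(wfile)
            )
    rows = []
    for rec in manifest.itertuples():
        series = read_navigator_csv(cohort_dir / rec.path)
        scores = score_series(series, weights=weights, n_discard=n_discard, n_ref=n_ref)
        rows.append({"subject_id": rec.subject_id, "grade": int(rec.grade), **scores})
    return pd.DataFrame(rows)


def running_scores_for_cohort(
    cohort_dir: str | Path,
    metric_name: str = "ccc",
    n_discard: int = 3,
    n_ref: int = 3,
) -> tuple[list[np.ndarray], list[int], pd.DataFrame]:
    """Per-subject running cumulative scores for the abort analysis.

    Returns the running score arrays, their start indices, and the manifest.
    """
    from fidnav.savings import running_score

    if metric_name not in METRIC_NAMES:
        raise ValueError(f"unknown metric {metric_name!r}")
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    runnings, starts = [], []
    for rec in manifest.itertuples():
        series = read_navigator_csv(cohort_dir / rec.path)
        trimmed, metrics = process_series(series, n_discard=n_discard, n_ref=n_ref)
        trace = metrics[metric_name]
        runnings.append(running_score(trace, trimmed.n_steps, trimmed.tr_seconds))
        starts.append(trace.start_index)
    return runnings, starts, manifest
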