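"""Per-TR multi-channel coil-combination motion metrics.

Each metric compresses the ``N_c``-channel complex navigator vector at TR
``i`` into one non-negative scalar per TR:

* ``delta_ref`` — mean over channels of the normalized absolute complex
  change relative to a fixed reference vector,
* ``delta_prev`` — the same change relative to the previous TR (motion is
  detected against where the head just was, since subjects rarely return to
  their initial position),
* ``delta_max`` — mean relative magnitude change over the few channels with
  the largest change at each TR (sensitive to fast, spatially local motion),
* ``ccc`` — one minus the Pearson correlation across channels between
  consecutive magnitude vectors; a drop in correlation means the load
  distribution over the coil elements has changed, i.e. the head moved.

All metric traces start at TR index 2 (the first TR has no predecessor, and
the reference-based trace is kept on the same support for comparability).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from fidnav.preprocess import FidnavSeries, reference_signal

METRIC_NAMES = ("delta_ref", "delta", "delta_max", "ccc")

#: Relative denominator floor guarding division by a vanishing channel signal.
DENOM_FLOOR_REL = 1e-12


class DegenerateReferenceError(ValueError):
    """A denominator channel signal is (numerically) zero."""


@dataclass
class MotionMetricSeries:
    """Real-valued per-TR motion metric trace for one algorithm.

    ``values[k]`` corresponds to TR index ``start_index + k`` (1-based) of
    the trimmed navigator series.  Traces are stored with an explicit start
    index rather than zero-padded so integrators know how many terms exist.
    """

    values: np.ndarray
    start_index: int
    metric_name: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("metric values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite metric values")
        if self.metric_name not in METRIC_NAMES:
            raise ValueError(f"unknown metric {self.metric_name!r}")

    def __len__(self) -> int:
        return len(self.values)


def _check_denominator(denom_abs: np.ndarray, scale: float, context: str) -> None:
    floor = DENOM_FLOOR_REL * scale
    bad = np.nonzero(denom_abs <= floor)
    if bad[0].size:
        if denom_abs.ndim == 1:
            where = f"channel {bad[0][0] + 1}"
        else:
            where = f"channel {bad[0][0] + 1}, TR {bad[1][0] + 2}"
        raise DegenerateReferenceError(f"{context}: vanishing signal at {where}")


def delta_ref(series: FidnavSeries, ref: np.ndarray | None = None) -> MotionMetricSeries:
    """Normalized mean absolute change relative to a reference vector.

    ``value(i) = mean_j |s_j(i) - s_j(ref)| / |s_j(ref)|`` for TR ``i >= 2``.
    ``ref`` defaults to the per-channel mean of the first three retained TRs.
    """
    if ref is None:
        ref = reference_signal(series)
    ref = np.asarray(ref, dtype=complex)
    if ref.shape != (series.n_channels,):
        raise ValueError("reference must have one value per channel")
    ref_abs = np.abs(ref)
    scale = float(max(np.abs(series.signal).max(), ref_abs.max()))
    _check_denominator(ref_abs, scale, "delta_ref reference")
    rel = np.abs(series.signal[:, 1:] - ref[:, None]) / ref_abs[:, None]
    return MotionMetricSeries(rel.mean(axis=0), start_index=2, metric_name="delta_ref")


def delta_prev(series: FidnavSeries) -> MotionMetricSeries:
    """Normalized mean absolute change relative to the previous TR.

    ``value(i) = mean_j |s_j(i) - s_j(i-1)| / |s_j(i-1)|`` for ``i >= 2``.
    """
    if series.n_tr < 2:
        raise ValueError("need at least 2 TRs")
    prev = series.signal[:, :-1]
    prev_abs = np.abs(prev)
    _check_denominator(prev_abs, float(np.abs(series.signal).max()), "delta")
    rel = np.abs(series.signal[:, 1:] - prev) / prev_abs
    return MotionMetricSeries(rel.mean(axis=0), start_index=2, metric_name="delta")


def delta_max(series: FidnavSeries, top_k: int = 3) -> MotionMetricSeries:
    """Mean relative magnitude change over the ``top_k`` maximally changing channels.

    Per TR, the relative change of channel ``j`` is
    ``r_j = | |s_j(i)| - |s_j(i-1)| | / |s_j(i-1)|`` (a magnitude-domain
    change, unlike the complex difference of ``delta_prev``); the channel set
    is re-selected at every TR.  With fewer channels than ``top_k`` the mean
    runs over all channels.
    """
    if series.n_tr < 2:
        raise ValueError("need at least 2 TRs")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    mag = np.abs(series.signal)
    prev = mag[:, :-1]
    _check_denominator(prev, float(mag.max()), "delta_max")
    r = np.abs(mag[:, 1:] - prev) / prev
    if series.n_channels < top_k:
        warnings.warn(
            f"delta_max: only {series.n_channels} channels < top_k={top_k}; "
            "averaging over all channels",
            stacklevel=2,
        )
        values = r.mean(axis=0)
    else:
        top = np.sort(r, axis=0)[-top_k:, :]
        values = top.mean(axis=0)
    return MotionMetricSeries(values, start_index=2, metric_name="delta_max")


def ccc(series: FidnavSeries) -> MotionMetricSeries:
    """One minus the cross-channel correlation of consecutive magnitude vectors.

    Per TR ``i >= 2`` the Pearson correlation (sample, ``N_c - 1``
    normalization) across channels between ``|s(i)|`` and ``|s(i-1)|`` is
    computed; the metric is ``1 - r``, in ``[0, 2]``.  A zero-variance
    magnitude vector makes the correlation undefined; such TRs yield 0 (no
    detectable load redistribution) with a warning.
    """
    if series.n_channels < 2:
        raise ValueError("ccc requires at least 2 channels")
    if series.n_tr < 2:
        raise ValueError("need at least 2 TRs")
    mag = np.abs(series.signal)
    cur = mag[:, 1:] - mag[:, 1:].mean(axis=0)
    prv = mag[:, :-1] - mag[:, :-1].mean(axis=0)
    var_cur = (cur**2).sum(axis=0)
    var_prv = (prv**2).sum(axis=0)
    denom = np.sqrt(var_cur * var_prv)
    degenerate = denom == 0
    if np.any(degenerate):
        warnings.warn(
            "ccc: zero-variance magnitude vector; correlation undefined, "
            "returning 0 for the affected TRs",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(degenerate, 1.0, (cur * prv).sum(axis=0) / np.where(degenerate, 1.0, denom))
    # clip |r| <= 1 against round-off before forming 1 - r
    corr = np.clip(corr, -1.0, 1.0)
    return MotionMetricSeries(1.0 - corr, start_index=2, metric_name="ccc")


def compute_all_metrics(
    series: FidnavSeries,
    ref: np.ndarray | None = None,
    top_k: int = 3,
) -> dict[str, MotionMetricSeries]:
    """All four metric traces for one trimmed navigator series."""
    return {
        "delta_ref": delta_ref(series, ref=ref),
        "delta": delta_prev(series),
        "delta_max": delta_max(series, top_k=top_k),
        "ccc": ccc(series),
    }
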