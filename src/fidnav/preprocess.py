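"""Raw FID navigator readouts to per-TR, per-channel complex signal vectors.

The raw navigator signal from each receive channel is a short train of
complex ADC samples (64 points over 0.2 ms by default) acquired after every
RF excitation.  Preprocessing reduces this to one complex number per channel
and TR: the middle samples of each readout are averaged (the edge samples are
contaminated by ADC electronics transients), all readouts of one echo train
are averaged, and the first few TRs are discarded while the longitudinal
magnetization reaches steady state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


class PreprocessError(ValueError):
    """Invalid input to a navigator preprocessing step."""


@dataclass(frozen=True)
class RawFidReadout:
    """One navigator ADC readout: ``(N_c, S)`` complex samples.

    Parameters
    ----------
    channel_samples
        Complex samples, shape ``(n_channels, n_samples)``.
    excitation_index
        Position of this readout within the echo train (1-based).
    tr_index
        The TR this readout belongs to (1-based).
    """

    channel_samples: np.ndarray
    excitation_index: int = 1
    tr_index: int = 1

    def __post_init__(self) -> None:
        samples = np.asarray(self.channel_samples, dtype=complex)
        if samples.ndim != 2:
            raise PreprocessError("channel_samples must be 2-D (channels x samples)")
        n_c, s = samples.shape
        if n_c < 1 or s < 2:
            raise PreprocessError(f"need >= 1 channel and >= 2 samples, got {samples.shape}")
        if not np.all(np.isfinite(samples)):
            raise PreprocessError("non-finite raw navigator samples")
        object.__setattr__(self, "channel_samples", samples)

    @property
    def n_channels(self) -> int:
        return self.channel_samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channel_samples.shape[1]


@dataclass
class FidnavSeries:
    """Per-TR, per-channel complex navigator signal matrix.

    ``signal[j, i]`` is the navigator value of channel ``j`` at the
    ``i``-th retained TR.  ``n_steps`` is the number of outer phase-encoding
    steps of the host acquisition (one per TR); after assembly and trimming it
    equals the number of TRs in the matrix.
    """

    signal: np.ndarray
    tr_seconds: float
    n_steps: int | None = None
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=complex)
        if self.signal.ndim != 2 or self.signal.shape[0] < 1:
            raise PreprocessError("signal must be (n_channels x n_tr) with >= 1 channel")
        if not np.all(np.isfinite(self.signal)):
            raise PreprocessError("non-finite navigator signal")
        if self.tr_seconds <= 0:
            raise PreprocessError("tr_seconds must be positive")
        if self.n_steps is None:
            self.n_steps = self.signal.shape[1]
        if not self.channel_labels:
            self.channel_labels = [f"ch{j + 1}" for j in range(self.signal.shape[0])]
        if len(self.channel_labels) != self.signal.shape[0]:
            raise PreprocessError("channel_labels length mismatch")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_tr(self) -> int:
        return self.signal.shape[1]


def default_window(n_samples: int) -> tuple[int, int]:
    """Central half of the readout, 1-based inclusive (samples 17-48 of 64)."""
    return n_samples // 4 + 1, 3 * n_samples // 4


def average_adc_samples(
    readout: RawFidReadout, window: tuple[int, int] | None = None
) -> np.ndarray:
    """Average ADC samples within a 1-based inclusive window, per channel.

    The default window keeps the middle half of the samples, discarding the
    leading and trailing quarters that are affected by ADC electronics
    adjustments.
    """
    if window is None:
        window = default_window(readout.n_samples)
    lo, hi = window
    if lo < 1 or hi > readout.n_samples or lo > hi:
        raise PreprocessError(
            f"invalid sample window [{lo}, {hi}] for {readout.n_samples} samples"
        )
    return readout.channel_samples[:, lo - 1 : hi].mean(axis=1)


def collapse_echo_train(readout_means: np.ndarray) -> np.ndarray:
    """Average per-channel readout means across all excitations of one TR.

    ``readout_means`` has shape ``(n_excitations, n_channels)``; a 1-D input
    is treated as a single channel.  Returns one complex value per channel.
    """
    means = np.atleast_2d(np.asarray(readout_means, dtype=complex))
    if means.shape[0] == 0 or means.size == 0:
        raise PreprocessError("echo train contains no readouts")
    return means.mean(axis=0)


def assemble_series(
    readouts: list[RawFidReadout],
    tr_seconds: float,
    window: tuple[int, int] | None = None,
) -> FidnavSeries:
    """Build a :class:`FidnavSeries` from raw readouts of one scan.

    Readouts are grouped by ``tr_index``; within each TR the sample window is
    averaged and then the echo train is collapsed.  TRs are ordered by index.
    """
    if not readouts:
        raise PreprocessError("no readouts supplied")
    by_tr: dict[int, list[np.ndarray]] = {}
    for r in readouts:
        by_tr.setdefault(r.tr_index, []).append(average_adc_samples(r, window))
    columns = [collapse_echo_train(np.array(by_tr[i])) for i in sorted(by_tr)]
    return FidnavSeries(signal=np.array(columns).T, tr_seconds=tr_seconds)


def trim_presteady(series: FidnavSeries, n_discard: int = 3) -> FidnavSeries:
    """Drop the first ``n_discard`` TRs (approach to steady state).

    TR indices are re-based so the first retained TR becomes index 1, and
    ``n_steps`` is reduced accordingly.
    """
    if n_discard < 0:
        raise PreprocessError("n_discard must be >= 0")
    if series.n_tr <= n_discard:
        raise PreprocessError(
            f"series has {series.n_tr} TRs, cannot discard {n_discard}"
        )
    return replace(
        series,
        signal=series.signal[:, n_discard:],
        n_steps=series.n_tr - n_discard,
        channel_labels=list(series.channel_labels),
    )


def reference_signal(series: FidnavSeries, n_ref: int = 3) -> np.ndarray:
    """Per-channel complex mean of the first ``n_ref`` retained TRs.

    Applied after :func:`trim_presteady`, so the reference is taken from
    steady-state data rather than the discarded transient.
    """
    if n_ref < 1:
        raise PreprocessError("n_ref must be >= 1")
    if n_ref > series.n_tr:
        raise PreprocessError(f"n_ref={n_ref} exceeds series length {series.n_tr}")
    return series.signal[:, :n_ref].mean(axis=1)
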