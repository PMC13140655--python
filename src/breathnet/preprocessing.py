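"""Cleaning of raw breath-by-breath series and analysis-window extraction.

Breath-by-breath gas-exchange data contain isolated artifacts (swallowed
breaths, mask leaks, transmission glitches).  The default cleaning is a
Hampel filter — flag samples deviating from a rolling median by more than
a threshold in robust-sigma units (1.4826 x rolling MAD) — followed by
linear interpolation across the flagged breaths.  Analysis windows are
event-indexed: a 5-min window at an estimated breathing frequency ``rf``
spans ``round(rf * 5)`` breaths.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .series import BreathSeries, ParticipantRecording

__all__ = ["detect_outliers", "interpolate_gaps", "clean_series",
           "clean_recording", "extract_window", "MAD_SCALE"]

log = logging.getLogger(__name__)

#: Consistency factor making the MAD an estimate of sigma for normal data.
MAD_SCALE = 1.4826


def detect_outliers(series, window: int = 11, threshold: float = 3.0) -> np.ndarray:
    """Hampel outlier mask: ``|x - rolling_median| > threshold * 1.4826 * MAD``.

    Windows shrink at the series edges.  A window whose scaled MAD is zero
    flags only samples that differ from the window median at all (a
    constant window therefore flags nothing).  Series shorter than 3
    samples return an all-false mask with a logged warning.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = series.values if isinstance(series, BreathSeries) else np.asarray(series, float)
    n = values.size
    mask = np.zeros(n, dtype=bool)
    if n < 3:
        log.warning("series of length %d too short for outlier detection", n)
        return mask
    half = window // 2
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        win = values[lo:hi]
        med = np.median(win)
        # n/(n - 0.8): finite-sample consistency correction for the MAD,
        # which underestimates sigma in short windows
        correction = win.size / (win.size - 0.8)
        sigma = MAD_SCALE * correction * np.median(np.abs(win - med))
        dev = abs(values[i] - med)
        mask[i] = dev > threshold * sigma if sigma > 0 else dev > 0
    return mask


def interpolate_gaps(series: BreathSeries, mask: np.ndarray) -> BreathSeries:
    """Replace masked samples by linear interpolation over the breath index.

    Leading/trailing masked samples take the nearest unmasked value.
    Raises if every sample is masked.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.values.shape:
        raise ValueError("mask length must match series length")
    if mask.all():
        raise ValueError("all samples masked: nothing to interpolate from")
    if not mask.any():
        return series.with_values(series.values)
    good = ~mask
    filled = series.values.copy()
    filled[mask] = np.interp(series.breath_index[mask],
                             series.breath_index[good],
                             series.values[good])
    return series.with_values(filled)


def clean_series(series: BreathSeries, window: int = 11,
                 threshold: float = 3.0) -> BreathSeries:
    """Detect-and-interpolate in one step (the per-channel default clean)."""
    return interpolate_gaps(series, detect_outliers(series, window, threshold))


def clean_recording(recording: ParticipantRecording, window: int = 11,
                    threshold: float = 3.0) -> ParticipantRecording:
    """Apply the Hampel clean to all seven channels of a recording."""
    return recording.map_channels(lambda s: clean_series(s, window, threshold))


def extract_window(recording: ParticipantRecording, start_breath: int = 0,
                   duration_minutes: float = 5.0,
                   rf_estimate: float = 20.0) -> ParticipantRecording:
    """Slice all channels to ``round(rf_estimate * duration)`` breaths.

    Slices are half-open ``[start, start + n)`` on 0-based breath
    positions; labels are preserved and the operation is idempotent for
    identical arguments.
    """
    n = int(round(rf_estimate * duration_minutes))
    stop = start_breath + n
    if start_breath < 0 or stop > recording.n_samples:
        raise ValueError(
            f"window [{start_breath}, {stop}) exceeds recording of "
            f"{recording.n_samples} breaths (short by "
            f"{max(stop - recording.n_samples, -start_breath)} samples)")
    sliced = recording.map_channels(
        lambda s: BreathSeries(s.channel, s.values[start_breath:stop],
                               s.breath_index[start_breath:stop]))
    if recording.times is not None:
        sliced = replace(sliced, times=recording.times[start_breath:stop])
    return sliced
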