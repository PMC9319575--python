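"""Signal conditioning for electrohysterogram (EHG) records.

The raw abdominal EHG distributes its energy below a few Hz; uterine
activity of interest lives in 0.1-4 Hz. Records are band-pass filtered
with a zero-phase Butterworth filter, expert-annotated artifact intervals
are excluded, and the remaining clean signal is cut into 120 s sliding
windows with 50 % overlap. Window-level features are summarised per
record by the sample median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

logger = logging.getLogger("ehgselect")

#: default analysis window (seconds) and overlap fraction
WINDOW_LENGTH_S = 120.0
WINDOW_OVERLAP = 0.5


def bandpass(
    x: np.ndarray,
    fs: float,
    f_low: float = 0.1,
    f_high: float = 4.0,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass filter.

    A filter of the given ``order`` is designed and applied forward and
    backward (``sosfiltfilt``), so the effective magnitude response is
    that of a filter of twice the order while the phase is exactly zero.
    Output length equals input length.

    Parameters
    ----------
    x : 1-D signal (or 2-D, filtered along the last axis).
    fs : sampling rate in Hz; must exceed ``2 * f_high``.
    f_low, f_high : passband edges in Hz.
    order : per-pass filter order.
    """
    if f_low >= f_high:
        raise ValueError(f"f_low ({f_low}) must be < f_high ({f_high})")
    if fs <= 2.0 * f_high:
        raise ValueError(f"fs ({fs}) must exceed the Nyquist bound 2*f_high ({2 * f_high})")
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 3 * order:
        raise ValueError("signal too short for the requested filter order")
    sos = sps.butter(order, [f_low, f_high], btype="bandpass", fs=fs, output="sos")
    # generous reflect padding: the 0.1 Hz edge settles over ~1/f_low
    # seconds, far longer than the default padlen would cover
    padlen = min(x.shape[-1] - 1, int(3 * fs / f_low))
    return sps.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    if not intervals:
        return []
    out: list[list[float]] = []
    for a, b in sorted((float(a), float(b)) for a, b in intervals):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def clean_intervals(
    artifact_intervals: list[tuple[float, float]], duration_s: float
) -> list[tuple[float, float]]:
    """Complement of the (merged) artifact intervals within [0, duration)."""
    dirty = _merge_intervals(artifact_intervals)
    out = []
    cursor = 0.0
    for a, b in dirty:
        a = max(a, 0.0)
        b = min(b, duration_s)
        if a > cursor:
            out.append((cursor, a))
        cursor = max(cursor, b)
    if cursor < duration_s:
        out.append((cursor, duration_s))
    return out


@dataclass
class WindowSet:
    """Sliding analysis windows of one record.

    ``start_samples`` are shared by all channels (artifact annotations are
    per record); ``windows`` holds ``(channel_index, start_sample, samples)``
    triples sliced from the record's signals.
    """

    start_samples: list[int]
    fs: float
    window_length_s: float = WINDOW_LENGTH_S
    overlap: float = WINDOW_OVERLAP
    windows: list[tuple[int, int, np.ndarray]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return int(round(self.window_length_s * self.fs))

    @property
    def starts_s(self) -> list[float]:
        return [s / self.fs for s in self.start_samples]


def window_starts(
    artifact_intervals: list[tuple[float, float]],
    duration_s: float,
    window_length_s: float = WINDOW_LENGTH_S,
    overlap: float = WINDOW_OVERLAP,
) -> list[float]:
    """Maximal set of window start times avoiding artifact intervals.

    Within every maximal clean segment the grid restarts at the segment
    start and steps by ``window_length_s * (1 - overlap)``, which yields
    ``floor((T_clean - W) / step) + 1`` windows per segment.
    """
    step = window_length_s * (1.0 - overlap)
    starts: list[float] = []
    for a, b in clean_intervals(artifact_intervals, duration_s):
        t = a
        while t + window_length_s <= b + 1e-9:
            starts.append(t)
            t += step
    return starts


def segment(
    record,
    window_length_s: float = WINDOW_LENGTH_S,
    overlap: float = WINDOW_OVERLAP,
) -> WindowSet:
    """Cut a record into clean sliding windows.

    ``record`` needs ``signals`` (channels x samples), ``fs`` and
    ``artifact_intervals`` attributes. Every returned window lies entirely
    inside a clean interval. Raises if no clean window fits.
    """
    signals = np.asarray(record.signals, dtype=float)
    fs = float(record.fs)
    duration = signals.shape[1] / fs
    if duration < window_length_s:
        raise ValueError(
            f"record {getattr(record, 'record_id', '?')}: duration {duration:.1f} s "
            f"is shorter than one {window_length_s:.0f} s window"
        )
    starts = window_starts(record.artifact_intervals, duration, window_length_s, overlap)
    if not starts:
        raise ValueError(
            f"record {getattr(record, 'record_id', '?')}: no clean "
            f"{window_length_s:.0f} s window available"
        )
    n_win = int(round(window_length_s * fs))
    start_samples = [int(round(t * fs)) for t in starts]
    ws = WindowSet(start_samples=start_samples, fs=fs,
                   window_length_s=window_length_s, overlap=overlap)
    for ch in range(signals.shape[0]):
        for s0 in start_samples:
            ws.windows.append((ch, s0, signals[ch, s0:s0 + n_win]))
    return ws


def window_manifest_csv(ws: WindowSet, path) -> None:
    """Debug dump of the window grid (channel, start sample, start second)."""
    lines = ["channel,start_sample,start_s"]
    for ch, s0, _ in ws.windows:
        lines.append(f"{ch},{s0},{s0 / ws.fs:.3f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def aggregate_median(window_values) -> float:
    """Per-record summary of window-level feature values: the sample median.

    For an even count this is the mean of the two central order statistics.
    """
    values = np.asarray(list(window_values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot aggregate an empty list of window values")
    return float(np.median(values))
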