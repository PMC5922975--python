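"""Egestion (radial contraction) detection from body-width dynamics.

Egestion empties the body cavity through a sub-second radial narrowing of
the body column — too fast and too subtle for frame-by-frame annotation, but
visible as a sharp drop in the minor-axis width extracted by preprocessing.
The width trace is filtered by subtracting, at each time point t, the mean
width over the 15 minutes after t from the mean width over the 15 minutes
before t; a sharp and lasting width decrease then shows up as a positive
peak at the drop.  Events are peaks of the filtered trace with prominence
above a robust (MAD-based) noise threshold, separated by at least one half
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks


@dataclass
class WidthTrace:
    """Per-frame body-column width (ellipse minor axis), px."""

    width_px: np.ndarray
    frame_rate_hz: float
    interpolated: np.ndarray | None = None  # bool flags for filled gaps


@dataclass
class EgestionEvent:
    frame: int
    time_s: float
    height_px: float
    edge: bool = False


def width_trace(geometry: pd.DataFrame, frame_rate_hz: float = 5.0
                ) -> WidthTrace:
    """Minor-axis width series from the per-frame geometry table.

    Missing frames (NaN minor axis) are linearly interpolated and flagged.
    """
    w = geometry["minor"].to_numpy(dtype=float)
    missing = ~np.isfinite(w)
    if missing.all():
        raise ValueError("no valid width measurements")
    if missing.any():
        idx = np.arange(w.size)
        w = w.copy()
        w[missing] = np.interp(idx[missing], idx[~missing], w[~missing])
    return WidthTrace(w, frame_rate_hz, missing)


def filter_width(trace: WidthTrace, half_window_min: float = 15.0
                 ) -> np.ndarray:
    """Before-minus-after mean-width difference at every time point.

    value[t] = mean(width[t-n : t]) - mean(width[t : t+n]) with n frames per
    ``half_window_min`` minutes; the windows are truncated at the trace
    ends so early and late events remain detectable.  A lasting width drop
    at t0 yields a positive peak of the drop's height at t0.
    """
    w = trace.width_px
    n = max(1, int(round(half_window_min * 60.0 * trace.frame_rate_hz)))
    if w.size <= 1:
        raise ValueError("trace too short to filter")
    csum = np.concatenate([[0.0], np.cumsum(w)])
    t = np.arange(w.size)
    lo = np.maximum(t - n, 0)
    hi = np.minimum(t + n, w.size)
    before_n = t - lo
    after_n = hi - t
    before = np.where(before_n > 0, (csum[t] - csum[lo]) / np.maximum(before_n, 1),
                      w)  # at t=0 fall back to the current sample
    after = (csum[hi] - csum[t]) / np.maximum(after_n, 1)
    return before - after


def detect_events(filtered: np.ndarray, frame_rate_hz: float = 5.0,
                  half_window_min: float = 15.0,
                  min_prominence: float | None = None,
                  raw_trace: WidthTrace | None = None) -> list[EgestionEvent]:
    """Peaks of the filtered trace above a robust prominence threshold.

    Default prominence is 3x a robust noise scale of the filtered trace:
    the MAD of its first differences scaled to a sample standard deviation
    (so the slow event bumps themselves do not inflate the threshold), with
    a floor at one tenth of the MAD of the trace.  Minimum peak separation
    is one half window.

    Near the trace ends the mean-width windows are truncated and the
    filtered value's standard error grows; when ``raw_trace`` is supplied,
    its frame-to-frame noise is estimated robustly and peaks whose height
    is below 3x their pointwise standard error are discarded.  Surviving
    end-region events are still flagged as edge events.
    """
    filtered = np.asarray(filtered, float)
    n = max(1, int(round(half_window_min * 60.0 * frame_rate_hz)))
    if min_prominence is None:
        diffs = np.diff(filtered)
        noise = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2)
        floor = 0.1 * 1.4826 * np.median(np.abs(filtered - np.median(filtered)))
        min_prominence = 3.0 * max(noise, floor, 1e-12)
    peaks, _ = find_peaks(filtered, prominence=min_prominence, distance=n)

    if raw_trace is not None and len(peaks):
        w = raw_trace.width_px
        dw = np.diff(w)
        sigma_w = 1.4826 * np.median(np.abs(dw - np.median(dw))) / np.sqrt(2)
        t = peaks
        m_before = np.maximum(np.minimum(t, n), 1)
        m_after = np.maximum(np.minimum(filtered.size - t, n), 1)
        stderr = sigma_w * np.sqrt(1.0 / m_before + 1.0 / m_after)
        peaks = peaks[filtered[peaks] >= 3.0 * stderr]

    return [
        EgestionEvent(int(p), p / frame_rate_hz, float(filtered[p]),
                      edge=(p < n or p >= filtered.size - n))
        for p in peaks
    ]


def events_table(events: list[EgestionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"frame": e.frame, "time_s": e.time_s, "height_px": e.height_px,
          "edge_flag": e.edge} for e in events],
        columns=["frame", "time_s", "height_px", "edge_flag"])
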