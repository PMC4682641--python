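"""Trace extraction and normalization.

The fixed pipeline order is extract -> subtract_background ->
detect_bleach -> normalize:

1. mean ROI intensity per frame;
2. subtract the minimal mean intensity of the series;
3. locate the bleach frame (the frame right after the largest
   single-step drop);
4. divide by the mean of the last 15 acquired time points, so the
   recovered plateau sits at 1.

Pre-bleach frames are kept in the trace but excluded from fitting; the
fit's time origin is the first post-bleach frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stackio import ImageStack, ROISpec

log = logging.getLogger(__name__)

PLATEAU_WINDOW = 15


class BleachDetectionError(ValueError):
    pass


@dataclass
class FrapTrace:
    """One bleach experiment's per-frame mean ROI intensity."""

    times: np.ndarray
    raw: np.ndarray
    frame_interval: float
    normalized: np.ndarray | None = None
    bleach_index: int | None = None
    background_subtracted: bool = False
    experiment_id: str = "exp0"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        if self.times.shape != self.raw.shape:
            raise ValueError("times and raw must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.bleach_index is not None and self.bleach_index < 1:
            raise ValueError("bleach_index must leave at least one pre-bleach frame")

    @property
    def n_frames(self) -> int:
        return len(self.raw)

    @property
    def n_prebleach(self) -> int | None:
        return self.bleach_index

    def postbleach_xy(self):
        """(t, y) of the post-bleach segment, normalized values, with the
        time origin on the first post-bleach frame.

        This origin is self-consistent with minimum subtraction: when the
        series minimum falls on the first post-bleach frame, the
        subtracted, rescaled recovery is exactly of the fitted form
        a(1 - exp(-b t)) with an unbiased rate, whatever fluorescence
        already returned between the bleach pulse and that frame.
        """
        if self.bleach_index is None:
            raise ValueError("bleach_index not set; run detect_bleach_frame first")
        if self.normalized is None:
            raise ValueError("trace not normalized")
        i = self.bleach_index
        return self.times[i:] - self.times[i], self.normalized[i:]

    def to_frame(self) -> pd.DataFrame:
        n = self.n_frames
        return pd.DataFrame(
            {
                "experiment_id": self.experiment_id,
                "frame": np.arange(n),
                "time_s": self.times,
                "raw": self.raw,
                "normalized": self.normalized if self.normalized is not None else np.nan,
                "bleach": [
                    1 if self.bleach_index is not None and i == self.bleach_index else 0
                    for i in range(n)
                ],
            }
        )


def trace_from_frame(df: pd.DataFrame) -> FrapTrace:
    df = df.sort_values("frame")
    times = df["time_s"].to_numpy(dtype=float)
    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    bleach = df.index[df["bleach"] == 1]
    bleach_index = int(df.loc[bleach[0], "frame"]) if len(bleach) else None
    norm = df["normalized"].to_numpy(dtype=float)
    return FrapTrace(
        times=times,
        raw=df["raw"].to_numpy(dtype=float),
        frame_interval=dt,
        normalized=None if np.all(np.isnan(norm)) else norm,
        bleach_index=bleach_index,
        experiment_id=str(df["experiment_id"].iloc[0]),
    )


def extract_trace(stack: ImageStack, roi: ROISpec, experiment_id: str = "exp0") -> FrapTrace:
    """Per-frame mean of the pixels inside the ROI."""
    if stack.role != "timeseries":
        raise ValueError("extract_trace expects a timeseries stack")
    mask = roi.mask(stack.shape)
    if not mask.any():
        raise ValueError(f"ROI '{roi.label}' selects no pixels")
    raw = stack.data[:, mask].mean(axis=1)
    return FrapTrace(
        times=stack.times(),
        raw=raw,
        frame_interval=stack.frame_interval,
        experiment_id=experiment_id,
    )


def subtract_background(trace: FrapTrace) -> FrapTrace:
    """Subtract the minimal mean intensity of the series (the analysis's
    background estimate); idempotent up to the shift already applied."""
    return replace(trace, raw=trace.raw - trace.raw.min(), background_subtracted=True)


def detect_bleach_frame(trace: FrapTrace, threshold: float = 3.0) -> int:
    """Frame index immediately after the largest single-step intensity drop.

    Ties break to the earliest index. Raises ``BleachDetectionError``
    unless the drop exceeds ``threshold`` times the frame-to-frame noise
    of the preceding (pre-drop) steps.
    """
    if trace.n_frames < 3:
        raise ValueError("need at least 3 frames to detect a bleach")
    d = np.diff(trace.raw)
    i = int(np.argmin(d))
    drop = -d[i]
    ref = d[:i] if i >= 2 else np.delete(d, i)
    noise = float(np.std(ref)) if len(ref) >= 2 else 0.0
    if drop <= 0 or drop <= threshold * noise:
        raise BleachDetectionError(
            f"no bleach detected: largest drop {drop:.4g} within {threshold}x noise"
        )
    return i + 1


def mark_bleach(trace: FrapTrace, threshold: float = 3.0) -> FrapTrace:
    return replace(trace, bleach_index=detect_bleach_frame(trace, threshold))


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Normalize to the mean of the last 15 acquired time points.

    If fewer than 15 post-bleach frames exist, all post-bleach frames are
    used (with a logged warning). The trace must be background-subtracted
    and carry a bleach index. Normalizing twice equals normalizing once.
    """
    if not trace.background_subtracted:
        raise ValueError("subtract background before normalizing")
    if trace.bleach_index is None:
        raise ValueError("bleach_index not set; run detect_bleach_frame first")
    n_post = trace.n_frames - trace.bleach_index
    window = PLATEAU_WINDOW
    if n_post < PLATEAU_WINDOW:
        window = n_post
        log.warning(
            "only %d post-bleach frames; plateau window shrunk to %d", n_post, window
        )
    plateau = trace.raw[-window:].mean()
    if plateau <= 0:
        raise ValueError("degenerate trace: plateau mean <= 0")
    return replace(trace, normalized=trace.raw / plateau)


def average_traces(traces) -> pd.DataFrame:
    """Pointwise mean of normalized traces aligned at the bleach frame.

    Returns a frame with columns (time, mean, n); time 0 is the first
    post-bleach frame. Traces may have different lengths; the mean at each
    aligned frame runs over the traces that cover it.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to average")
    dt = traces[0].frame_interval
    for tr in traces:
        if tr.normalized is None or tr.bleach_index is None:
            raise ValueError("all traces must be normalized with a bleach index")
        if not np.isclose(tr.frame_interval, dt):
            raise ValueError("mixed frame intervals")
    lo = min(-tr.bleach_index for tr in traces)
    hi = max(tr.n_frames - tr.bleach_index for tr in traces)
    rel = np.arange(lo, hi)
    total = np.zeros(len(rel))
    count = np.zeros(len(rel), dtype=int)
    for tr in traces:
        idx = np.arange(tr.n_frames) - tr.bleach_index - lo
        total[idx] += tr.normalized
        count[idx] += 1
    have = count > 0
    return pd.DataFrame(
        {"time": rel[have] * dt, "mean": total[have] / count[have], "n": count[have]}
    )
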