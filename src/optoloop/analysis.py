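"""Offline analysis: ΔF/F traces, oracle re-detection, cycle statistics, maps, error rates.

Everything here consumes recorded artefacts — TIFF stacks, session logs — and
recomputes quantities independently of the online engine, so it doubles as the
validation oracle for the closed loop: :func:`offline_detect` replays the
exact detector statistic over a saved trace, and the error rates are defined
directly on the per-frame accounting records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frames import Frame
from .loop import DetectorConfig, SessionLog, roi_mean
from .tissue import PixelRect, StimMask, TissueParams

__all__ = [
    "RoiTrace",
    "CycleStats",
    "extract_trace",
    "dff",
    "offline_detect",
    "cycle_stats",
    "predict_period",
    "il_error_rate",
    "rtl_error_rate",
    "activation_map",
    "fit_conduction_velocity",
]


@dataclass(frozen=True)
class RoiTrace:
    """ROI-mean fluorescence per frame, with the frame timestamps (µs)."""

    times_us: np.ndarray
    values: np.ndarray
    roi: PixelRect

    def __post_init__(self) -> None:
        if len(self.times_us) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times_us) > 1 and not np.all(np.diff(self.times_us) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class CycleStats:
    """Cycle-length statistics of a detected (or paced) rhythm."""

    event_times_us: np.ndarray
    mean_period_us: float
    sd_period_us: float

    @property
    def cv_period(self) -> float:
        return self.sd_period_us / self.mean_period_us


def extract_trace(frames: Sequence[Frame], roi: PixelRect) -> RoiTrace:
    """ROI mean of every frame in a stack."""
    if len(frames) == 0:
        raise ValueError("empty stack")
    times = np.array([f.camera_timestamp_us for f in frames], dtype=np.int64)
    values = np.array([roi_mean(f.pixels, roi) for f in frames])
    return RoiTrace(times_us=times, values=values, roi=roi)


def dff(trace: RoiTrace, baseline_window: tuple[int, int]) -> np.ndarray:
    """ΔF/F = (F0 - F) / F0 with F0 the mean over a baseline sample range.

    Positive during depolarization (the dye darkens).  ``baseline_window`` is
    a half-open sample-index range that should precede any activity.
    """
    lo, hi = baseline_window
    base = trace.values[lo:hi]
    if base.size == 0:
        raise ValueError("empty baseline window")
    f0 = float(base.mean())
    if f0 == 0:
        raise ValueError("zero baseline fluorescence")
    return (f0 - trace.values) / f0


def offline_detect(
    trace: RoiTrace,
    cfg: DetectorConfig,
    blanked: Sequence[tuple[float, float]] | None = None,
    protocol_window_us: float | None = None,
) -> np.ndarray:
    """Replay the shift-register detector over a recorded trace.

    Samples strictly inside a blanked interval are skipped and the buffer is
    cleared at each interval's end, mirroring the online protocol window.
    Blanking is given either explicitly (``blanked``, e.g. taken from a
    session log) or generated on the fly: with ``protocol_window_us`` each
    emitted event opens a window of that length.  This is the brute-force
    oracle for the online detector.
    """
    intervals = sorted(blanked) if blanked else []
    ptr = 0
    dyn_rearm: float | None = None
    buffer: list[float] = []
    events: list[float] = []
    for t, m in zip(trace.times_us, trace.values):
        while ptr < len(intervals) and intervals[ptr][1] <= t:
            buffer.clear()
            ptr += 1
        if ptr < len(intervals) and intervals[ptr][0] < t < intervals[ptr][1]:
            continue
        if dyn_rearm is not None:
            if t < dyn_rearm:
                continue
            buffer.clear()
            dyn_rearm = None
        if not buffer:
            buffer.append(m)
            continue
        b = np.asarray(buffer)
        if np.any((b - m) / b > cfg.th):
            events.append(float(t))
            if protocol_window_us is not None:
                dyn_rearm = t + protocol_window_us
            continue
        buffer.append(m)
        if len(buffer) > cfg.buffer_len:
            buffer.pop(0)
    return np.asarray(events)


def cycle_stats(event_times_us) -> CycleStats:
    """Mean, SD (population) and CV of the periods between consecutive events."""
    t = np.asarray(event_times_us, dtype=np.float64)
    if t.size < 3:
        raise ValueError("need at least 3 events to speak of a sustained rhythm")
    periods = np.diff(t)
    return CycleStats(
        event_times_us=t,
        mean_period_us=float(periods.mean()),
        sd_period_us=float(periods.std(ddof=0)),
    )


def predict_period(
    tissue: TissueParams,
    mask: StimMask,
    roi: PixelRect,
    th: float,
    pre_delay_us: float,
    exposure_us: float,
) -> tuple[float, float]:
    """Closed-form interval for the re-entry loop period, in µs.

    Each cycle is: pre-activation delay, wavefront travel from the stimulus
    spot to the detection ROI, and the detection latency — the part of the
    upstroke needed for ΔF/F to cross Th, plus up to one frame interval of
    sampling quantization.  The bounds use the nearest/farthest ROI pixel
    distance to the spot.  Valid for zero processing costs, noise off, and a
    period longer than the refractory period (otherwise the spot cannot be
    recaptured and the rhythm dies).
    """
    d = roi.center_distances_mm(mask, tissue)
    travel_lo = d.min() / tissue.cv_mm_ms * 1000.0
    travel_hi = d.max() / tissue.cv_mm_ms * 1000.0
    t_cross = tissue.upstroke_ms * 1000.0 * min(1.0, th / tissue.sensitivity)
    lo = pre_delay_us + travel_lo + t_cross
    hi = pre_delay_us + travel_hi + t_cross + exposure_us
    return lo, hi


def il_error_rate(log: SessionLog) -> float:
    """Fraction of produced frames lost by the imaging loop."""
    if log.produced == 0:
        raise ValueError("no frames produced")
    return log.lost / log.produced


def rtl_error_rate(log: SessionLog) -> float:
    """Fraction of frames the RTL failed to analyze, among those it should have.

    Intentional protocol-window skips are excluded from both numerator and
    denominator: the metric measures analysis capacity, not protocol design.
    """
    if log.mode != "closed-loop":
        raise ValueError("RTL was not enabled in this session")
    denom = log.acquired - log.skipped_protocol
    if denom == 0:
        return 0.0
    return log.skipped_rtl_busy / denom


def activation_map(
    frames: Sequence[Frame],
    params: TissueParams,
    min_depth_fraction: float = 0.5,
    window: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-pixel activation time (µs) from the maximum negative fluorescence slope.

    The VSD signal falls on depolarization, so the steepest *decrease* marks
    the upstroke; the activation time is the midpoint of the frame pair with
    the most negative temporal difference.  Pixels whose signal excursion is
    below ``min_depth_fraction`` of the full AP depth (sensitivity * f0) are
    returned as NaN.  ``window`` restricts the search to a sample range.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    lo, hi = window if window is not None else (0, len(frames))
    sub = frames[lo:hi]
    if len(sub) < 2:
        raise ValueError("analysis window holds fewer than two frames")
    stack = np.stack([f.pixels for f in sub]).astype(np.float32)
    times = np.array([f.camera_timestamp_us for f in sub], dtype=np.float64)
    depth = stack.max(axis=0) - stack.min(axis=0)
    active = depth >= min_depth_fraction * params.sensitivity * params.f0
    diffs = np.diff(stack, axis=0)
    k = diffs.argmin(axis=0)
    t_mid = (times[k] + times[k + 1]) / 2.0
    return np.where(active, t_mid, np.nan)


def fit_conduction_velocity(
    act_map: np.ndarray, origin_mm: tuple[float, float], params: TissueParams
) -> float:
    """Conduction velocity (mm/ms) from a linear fit of distance vs activation time."""
    xg, yg = params.pixel_centers_mm()
    dist = np.hypot(xg - origin_mm[0], yg - origin_mm[1])
    ok = np.isfinite(act_map)
    if ok.sum() < 2:
        raise ValueError("too few activated pixels for a fit")
    t_ms = act_map[ok] / 1000.0
    slope, _ = np.polyfit(dist[ok], t_ms, 1)  # ms per mm
    if slope <= 0:
        raise ValueError("activation times do not increase with distance")
    return 1.0 / slope


def plot_trace(trace: RoiTrace, detections=None, stim_times=None, path=None):
    """ΔF/F-style trace plot with optional event markers (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(trace.times_us / 1e6, trace.values, lw=0.7, color="k")
    if detections is not None:
        for t in np.atleast_1d(detections):
            ax.axvline(t / 1e6, color="g", lw=0.5, alpha=0.6)
    if stim_times is not None:
        for t in np.atleast_1d(stim_times):
            ax.axvline(t / 1e6, color="b", lw=0.5, alpha=0.6)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ROI fluorescence (counts)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
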