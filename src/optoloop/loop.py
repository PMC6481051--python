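"""The closed loop: imaging loop + real-time analysis loop on a deterministic event clock.

The platform runs two asynchronous tasks.  The *imaging loop* (IL) polls the
camera, stacks every frame it manages to read into RAM, and monitors the
effective frame rate.  The *real-time analysis loop* (RTL) computes the mean
fluorescence m over a user ROI for each stacked frame, compares it against a
shift-register buffer of recent means, and declares a depolarization event
when any relative variation (buffer_i - m)/buffer_i exceeds the threshold Th
(the voltage-sensitive dye darkens on depolarization, so a drop is positive).
An event launches a three-phase stimulation protocol — pre-activation delay,
light pulse, post-activation delay — during which detection is disarmed while
imaging continues; at the end of the post delay the buffer is reset and the
detector re-arms.

Instead of wall-clock threads, both tasks run on a simulated microsecond
clock with configurable per-frame processing costs, which makes every run
bit-reproducible and lets the stability boundary ("the RTL must be faster
than the IL, which is timed by the exposure") be probed exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .frames import CameraConfig, Frame, FrameSlot, VirtualCamera
from .tissue import PixelRect, StimMask, TissueParams

__all__ = [
    "DetectorConfig",
    "DetectorState",
    "DetectionEvent",
    "StimProtocol",
    "LoadModel",
    "SessionLog",
    "SessionResult",
    "roi_mean",
    "relative_variation",
    "detect",
    "detector_step",
    "protocol_schedule",
    "run_session",
    "effective_frame_rate",
]

# per-frame record statuses
LOST = "lost"
ANALYZED = "analyzed"
SKIP_PROTOCOL = "protocol-window"
SKIP_RTL_BUSY = "rtl-busy"
RTL_OFF = "rtl-off"


@dataclass(frozen=True)
class DetectorConfig:
    """ROI, threshold Th (fraction of ΔF/F) and shift-register depth."""

    roi: PixelRect
    th: float = 0.01
    buffer_len: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.th < 1.0:
            raise ValueError("th must lie in (0, 1)")
        if self.buffer_len < 1:
            raise ValueError("buffer_len must be >= 1")


@dataclass
class DetectorState:
    """Shift-register buffer of past ROI means plus armed/blocked status."""

    buffer: list[float] = field(default_factory=list)
    armed: bool = True
    last_event_time: float | None = None


@dataclass(frozen=True)
class DetectionEvent:
    time_us: float
    max_relative_variation: float


@dataclass(frozen=True)
class StimProtocol:
    """Three-phase stimulation: pre-activation delay, pulse, post-activation delay."""

    mask: StimMask
    pre_delay_us: int = 200_000
    pulse_us: int = 5_000
    post_delay_us: int = 5_000
    amplitude: float = 1.0  # light-intensity label, logged only

    def __post_init__(self) -> None:
        if self.pre_delay_us < 0 or self.post_delay_us < 0:
            raise ValueError("delays must be >= 0")
        if self.pulse_us <= 0:
            raise ValueError("pulse_us must be > 0")

    @property
    def window_us(self) -> int:
        """Full blanking window from event to re-arm."""
        return self.pre_delay_us + self.pulse_us + self.post_delay_us


@dataclass(frozen=True)
class LoadModel:
    """Per-frame processing costs emulating data-transfer / workstation load.

    Costs are constant plus an optional uniform jitter in [0, *_jitter_us),
    drawn from a seeded stream so runs stay reproducible.
    """

    il_cost_us: float = 0.0
    rtl_cost_us: float = 0.0
    il_jitter_us: float = 0.0
    rtl_jitter_us: float = 0.0

    def __post_init__(self) -> None:
        if min(self.il_cost_us, self.rtl_cost_us, self.il_jitter_us, self.rtl_jitter_us) < 0:
            raise ValueError("load costs must be >= 0")


class SessionLog:
    """Every produced frame and every detection/stimulation event of one run."""

    def __init__(self, mode: str, exposure_us: int, duration_us: int) -> None:
        self.mode = mode
        self.exposure_us = exposure_us
        self.duration_us = duration_us
        # (frame_index, camera_timestamp_us, read_time_us or None, status)
        self.frame_records: list[tuple[int, int, float | None, str]] = []
        # (time_us, frame_index, max_relative_variation)
        self.detections: list[tuple[float, int, float]] = []
        # (on_us, off_us, amplitude)
        self.stimulations: list[tuple[float, float, float]] = []

    # -- accounting -------------------------------------------------------
    def _count(self, status: str) -> int:
        return sum(1 for r in self.frame_records if r[3] == status)

    @property
    def produced(self) -> int:
        return len(self.frame_records)

    @property
    def lost(self) -> int:
        return self._count(LOST)

    @property
    def acquired(self) -> int:
        return self.produced - self.lost

    @property
    def analyzed(self) -> int:
        return self._count(ANALYZED)

    @property
    def skipped_protocol(self) -> int:
        return self._count(SKIP_PROTOCOL)

    @property
    def skipped_rtl_busy(self) -> int:
        return self._count(SKIP_RTL_BUSY)

    @property
    def skipped_rtl_off(self) -> int:
        return self._count(RTL_OFF)

    @property
    def detection_times(self) -> np.ndarray:
        return np.array([d[0] for d in self.detections])

    # -- export -----------------------------------------------------------
    def frames_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.frame_records,
            columns=["frame_index", "camera_timestamp_us", "read_time_us", "status"],
        )

    def events_df(self) -> pd.DataFrame:
        rows = [
            {"event_type": "detection", "time_us": t, "frame_index": k,
             "relative_variation": rv, "off_us": np.nan, "amplitude": np.nan}
            for (t, k, rv) in self.detections
        ] + [
            {"event_type": "stimulation", "time_us": on, "frame_index": -1,
             "relative_variation": np.nan, "off_us": off, "amplitude": amp}
            for (on, off, amp) in self.stimulations
        ]
        df = pd.DataFrame(
            rows,
            columns=["event_type", "time_us", "frame_index",
                     "relative_variation", "off_us", "amplitude"],
        )
        return df.sort_values("time_us", kind="stable").reset_index(drop=True)

    def to_csv(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.frames_df().to_csv(out / "frames.csv", index=False)
        self.events_df().to_csv(out / "events.csv", index=False)


@dataclass
class SessionResult:
    frames: list[Frame]
    log: SessionLog


# ---------------------------------------------------------------------------
# detector primitives
# ---------------------------------------------------------------------------

def roi_mean(pixels: np.ndarray, roi: PixelRect) -> float:
    """Arithmetic mean of the ROI pixels, in camera counts (not rounded)."""
    if not roi.inside(pixels.shape):
        raise ValueError("ROI extends outside the frame")
    return float(pixels[roi.slices].mean(dtype=np.float64))


def relative_variation(buffer, m: float) -> np.ndarray:
    """Element-wise (buffer_i - m) / buffer_i; positive means a fluorescence drop."""
    b = np.asarray(buffer, dtype=np.float64)
    if b.size == 0:
        raise ValueError("buffer is empty")
    if np.any(b == 0):
        raise ValueError("zero buffer entry: relative variation undefined")
    return (b - m) / b


def detect(buffer, m: float, th: float) -> bool:
    """True iff any relative variation is strictly greater than Th."""
    return bool(np.any(relative_variation(buffer, m) > th))


def detector_step(
    state: DetectorState, m: float, t_us: float, cfg: DetectorConfig
) -> tuple[DetectorState, DetectionEvent | None]:
    """Advance the shift-register detector by one ROI mean.

    First sample ever: stored, no comparison.  Armed + any relative variation
    above Th: a detection is emitted and the triggering mean is *not* stored
    (the protocol takes over and the buffer is reset before the next armed
    sample anyway).  Otherwise the mean is appended, evicting the oldest once
    the buffer is full.
    """
    if not state.buffer:
        state.buffer.append(m)
        return state, None
    if state.armed:
        rv = relative_variation(state.buffer, m)
        if np.any(rv > cfg.th):
            state.last_event_time = t_us
            return state, DetectionEvent(time_us=t_us, max_relative_variation=float(rv.max()))
    state.buffer.append(m)
    if len(state.buffer) > cfg.buffer_len:
        state.buffer.pop(0)
    return state, None


def protocol_schedule(protocol: StimProtocol, t_event_us: float) -> dict:
    """Times of the three protocol phases relative to a detection event."""
    on = t_event_us + protocol.pre_delay_us
    off = on + protocol.pulse_us
    rearm = off + protocol.post_delay_us
    return {"stim_on_us": on, "stim_off_us": off, "rearm_us": rearm}


# ---------------------------------------------------------------------------
# the event engine
# ---------------------------------------------------------------------------

def run_session(
    *,
    tissue: TissueParams,
    camera: CameraConfig,
    duration_us: int,
    mode: str = "closed-loop",
    detector: DetectorConfig | None = None,
    protocol: StimProtocol | None = None,
    load: LoadModel | None = None,
    init_stim_time_us: int | None = None,
    init_stim_mask: StimMask | None = None,
    seed: int | None = None,
    keep_frames: bool = True,
) -> SessionResult:
    """Run one acquisition session on the simulated clock.

    The camera publishes a frame at every multiple of the exposure time below
    ``duration_us``.  The IL reads the single-slot mailbox as soon as it is
    free; a frame replaced before being read is lost.  In closed-loop mode
    each stacked frame is offered to the RTL, which skips it if a protocol
    window is open (intentional) or if it is still busy with the previous
    frame (capacity), and otherwise runs the detector.  Detections trigger the
    three-phase protocol; the light pulse excites the tissue once, at pulse
    onset.  Identical configuration and seed give bit-identical output.
    """
    if mode not in ("free-run", "closed-loop"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "closed-loop":
        if detector is None or protocol is None:
            raise ValueError("closed-loop mode needs a detector and a protocol")
        if not detector.roi.inside(camera.area):
            raise ValueError("detector ROI extends outside the camera area")
    if duration_us < 0:
        raise ValueError("duration_us must be >= 0")
    load = load or LoadModel()

    seed_val = tissue.seed if seed is None else seed
    cam = VirtualCamera(camera, tissue, seed=seed_val)
    jitter_rng = np.random.default_rng([seed_val & 0x7FFFFFFF, 0x10AD])
    has_jitter = load.il_jitter_us > 0 or load.rtl_jitter_us > 0

    exposure = camera.exposure_us
    n_frames = duration_us // exposure
    log = SessionLog(mode=mode, exposure_us=exposure, duration_us=duration_us)
    frames: list[Frame] = []
    slot = FrameSlot()

    # pending optogenetic stimuli: (time_us, sequence, mask)
    stim_heap: list[tuple[float, int, StimMask]] = []
    stim_seq = 0
    if init_stim_time_us is not None:
        m0 = init_stim_mask if init_stim_mask is not None else (
            protocol.mask if protocol is not None else None
        )
        if m0 is None:
            raise ValueError("an initiating stimulus needs a mask")
        heapq.heappush(stim_heap, (float(init_stim_time_us), stim_seq, m0))
        stim_seq += 1

    il_free = 0.0
    rtl_free = 0.0
    rearm_time = 0.0
    det_state = DetectorState()

    for k in range(n_frames):
        t = k * exposure
        while stim_heap and stim_heap[0][0] <= t:
            s_time, _, s_mask = heapq.heappop(stim_heap)
            cam.stimulate(s_mask, s_time)
        frame = cam.frame_at(k)
        slot.publish(frame)

        # The IL will read this frame at r unless a newer frame lands first;
        # on an exact tie the read wins (the IL grabs the slot as the new
        # frame arrives), so il_cost == exposure is still loss-free.
        r = max(il_free, float(t))
        boundary = float(t + exposure) if k < n_frames - 1 else float(duration_us)
        if r > boundary:
            log.frame_records.append((k, t, None, LOST))
            continue

        f = slot.read()
        il_cost = load.il_cost_us
        if has_jitter and load.il_jitter_us > 0:
            il_cost += jitter_rng.uniform(0.0, load.il_jitter_us)
        il_free = r + il_cost
        avail = il_free  # moment the frame lands in RAM, visible to the RTL
        if keep_frames:
            frames.append(f)

        if mode == "free-run":
            log.frame_records.append((k, t, r, RTL_OFF))
            continue
        if avail < rearm_time:
            log.frame_records.append((k, t, r, SKIP_PROTOCOL))
            continue
        if rtl_free > avail:
            log.frame_records.append((k, t, r, SKIP_RTL_BUSY))
            continue

        rtl_cost = load.rtl_cost_us
        if has_jitter and load.rtl_jitter_us > 0:
            rtl_cost += jitter_rng.uniform(0.0, load.rtl_jitter_us)
        rtl_free = avail + rtl_cost
        t_e = rtl_free
        m = roi_mean(f.pixels, detector.roi)
        det_state.armed = True
        det_state, event = detector_step(det_state, m, t_e, detector)
        log.frame_records.append((k, t, r, ANALYZED))
        if event is not None:
            log.detections.append((event.time_us, k, event.max_relative_variation))
            sched = protocol_schedule(protocol, event.time_us)
            heapq.heappush(stim_heap, (sched["stim_on_us"], stim_seq, protocol.mask))
            stim_seq += 1
            log.stimulations.append(
                (sched["stim_on_us"], sched["stim_off_us"], protocol.amplitude)
            )
            rearm_time = sched["rearm_us"]
            # detection is blocked until re-arm; the buffer reset scheduled for
            # the end of the post delay is applied here, which is equivalent
            # because no sample touches the detector while it is disarmed
            det_state.buffer.clear()
            det_state.armed = False

    return SessionResult(frames=frames, log=log)


def effective_frame_rate(log: SessionLog) -> np.ndarray:
    """Per consecutive acquired-frame pair, 1/Δt in frames per second.

    Uses the workstation read timestamps, mirroring the IL frame-rate monitor;
    with zero processing cost these coincide with the camera timestamps.
    """
    reads = [r[2] for r in log.frame_records if r[3] != LOST]
    if len(reads) < 2:
        raise ValueError("need at least two acquired frames")
    dt = np.diff(np.asarray(reads, dtype=np.float64))
    return 1e6 / dt
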