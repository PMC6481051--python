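"""Frame sources, the single-slot latest-frame hand-off, and TIFF stack persistence.

The acquisition side of the platform is abstracted as a *frame source*: an
object the event engine polls at successive multiples of the exposure time.
Two sources are provided: a virtual camera that renders the tissue model live
(free-run mode: the frame rate is set purely by the exposure time), and a
replay source that re-emits a previously recorded stack with its original
timestamps.

The camera-to-imaging-loop hand-off is a single-slot mailbox: the newest frame
overwrites an unread one, which is then counted as lost.  This is the simplest
mechanism consistent with a get-frame/wait-next-frame polling camera API and
reproduces the frame loss seen at short exposures under load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import tifffile

from .tissue import StimMask, TissueParams, TissueState, advance_to, apply_stimulus, render_frame

__all__ = [
    "Frame",
    "CameraConfig",
    "FrameSlot",
    "VirtualCamera",
    "ReplaySource",
    "open_virtual_camera",
    "save_stack",
    "load_stack",
    "write_metadata",
    "read_metadata",
]

_TS_DIGITS = 12  # zero padding keeps lexicographic == numeric order up to ~11.5 days


@dataclass(frozen=True)
class Frame:
    """One acquired image: pixels, camera timestamp (µs), and producer index."""

    pixels: np.ndarray
    camera_timestamp_us: int
    frame_index: int

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint16:
            raise ValueError("frame pixels must be unsigned 16-bit")


@dataclass(frozen=True)
class CameraConfig:
    """Virtual sCMOS configuration: central sub-area of a large sensor, free-run."""

    exposure_us: int = 2000
    area: tuple[int, int] = (128, 128)
    sensor_shape: tuple[int, int] = (2048, 2048)
    mode: str = "free-run"

    def __post_init__(self) -> None:
        if self.exposure_us <= 0:
            raise ValueError("exposure_us must be > 0")
        if any(a <= 0 for a in self.area) or any(
            a > s for a, s in zip(self.area, self.sensor_shape)
        ):
            raise ValueError("camera area must be positive and within the sensor")
        if self.mode != "free-run":
            raise ValueError("only free-run acquisition is modelled")


@dataclass
class FrameSlot:
    """Single-slot latest-frame mailbox between producer and imaging loop."""

    current: Frame | None = None
    overwrites: int = 0
    reads: int = 0

    def publish(self, f: Frame) -> "FrameSlot":
        if self.current is not None:
            self.overwrites += 1
        self.current = f
        return self

    def read(self) -> Frame:
        if self.current is None:
            raise LookupError("no frame available")
        f = self.current
        self.current = None
        self.reads += 1
        return f


class VirtualCamera:
    """Frame source that renders the virtual heart in free-run mode.

    Polling :meth:`frame_at` with successive indices yields frames with
    ``camera_timestamp = frame_index * exposure_us`` (exact integer
    arithmetic, no drift).  Optogenetic stimuli are injected through
    :meth:`stimulate`; the engine is responsible for calling it in time order
    relative to the frames it requests.
    """

    def __init__(
        self,
        config: CameraConfig,
        tissue: TissueParams,
        seed: int | None = None,
    ) -> None:
        if config.area != tissue.grid_shape:
            raise ValueError("camera area and tissue grid must agree")
        self.config = config
        self.tissue = tissue
        self.state = TissueState.quiescent(tissue)
        self.rng = np.random.default_rng(tissue.seed if seed is None else seed)

    def stimulate(self, mask: StimMask, t_us: float) -> None:
        apply_stimulus(self.state, mask, t_us, self.tissue)

    def frame_at(self, index: int) -> Frame:
        t = index * self.config.exposure_us
        advance_to(self.state, t, self.tissue)
        pixels = render_frame(self.state, t, self.tissue, self.rng)
        return Frame(pixels=pixels, camera_timestamp_us=t, frame_index=index)


def open_virtual_camera(
    config: CameraConfig, tissue: TissueParams, seed: int | None = None
) -> VirtualCamera:
    """Construct the simulated acquisition source (replaces hardware camera setup)."""
    return VirtualCamera(config, tissue, seed)


class ReplaySource:
    """Re-emit a recorded stack with its original timestamps (offline replay)."""

    def __init__(self, frames: list[Frame]) -> None:
        self.frames = list(frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __len__(self) -> int:
        return len(self.frames)


def save_stack(frames, out_dir) -> int:
    """Write one uncompressed 16-bit grayscale TIFF per frame.

    The camera timestamp (µs), zero-padded to 12 digits, is the filename, so
    an alphabetical listing is also chronological.  Duplicate timestamps mean
    corrupted timestamping and raise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seen: set[int] = set()
    n = 0
    for f in frames:
        ts = int(f.camera_timestamp_us)
        if ts in seen:
            raise ValueError(f"duplicate frame timestamp {ts} µs")
        seen.add(ts)
        tifffile.imwrite(
            out / f"{ts:0{_TS_DIGITS}d}.tif",
            f.pixels,
            photometric="minisblack",
            compression=None,
        )
        n += 1
    return n


def load_stack(in_dir, expected_shape: tuple[int, int] | None = (128, 128)) -> list[Frame]:
    """Read a stack directory back into Frames, sorted by filename timestamp."""
    paths = sorted(Path(in_dir).glob("*.tif"))
    frames: list[Frame] = []
    for idx, p in enumerate(paths):
        if not re.fullmatch(r"\d+", p.stem):
            raise ValueError(f"{p.name}: stack filenames must be numeric timestamps")
        pixels = tifffile.imread(p)
        if pixels.dtype != np.uint16:
            raise ValueError(f"{p.name}: expected 16-bit grayscale, got {pixels.dtype}")
        if expected_shape is not None and pixels.shape != tuple(expected_shape):
            raise ValueError(
                f"{p.name}: expected shape {tuple(expected_shape)}, got {pixels.shape}"
            )
        frames.append(Frame(pixels=pixels, camera_timestamp_us=int(p.stem), frame_index=idx))
    return frames


def write_metadata(path, items: dict) -> None:
    """Session metadata as a small `key = value` text file."""
    lines = [f"{k} = {v}" for k, v in items.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_metadata(path) -> dict:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        k, _, v = line.partition("=")
        out[k.strip()] = v.strip()
    return out
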