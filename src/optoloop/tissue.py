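"""Virtual cardiac tissue: an activation-time wave model rendered as VSD fluorescence.

This module stands in for the heart + optics of an all-optical mapping rig.
A 2D sheet of excitable tissue is modelled at the resolution of the camera
grid (default 128x128 px over a ~10x10 mm field of view).  Excitation is
eikonal-style: a stimulus activates the pixels under its light pattern, and
the wavefront reaches every other pixel after (Euclidean distance to the
nearest activated source) / conduction velocity.  Each pixel then follows a
piecewise-linear action-potential template (upstroke, plateau, linear
repolarization), and fluorescence of the voltage-sensitive dye is rendered as
a *negative-going* signal: F = f0 * (1 - sensitivity * V), plus optional
per-pixel Gaussian noise.

Times handed to the public functions are integer-or-float microseconds on the
session clock; durations in :class:`TissueParams` are milliseconds, matching
how they are quoted in the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "TissueParams",
    "TissueState",
    "StimMask",
    "PixelRect",
    "make_circular_mask",
    "make_rect_mask",
    "apply_stimulus",
    "advance_to",
    "ap_waveform",
    "render_frame",
]


@dataclass(frozen=True)
class TissueParams:
    """Physical and optical parameters of the virtual heart.

    Defaults describe a murine-scale preparation imaged over a 10 mm field:
    conduction velocity 0.5 mm/ms, a 2 ms upstroke, a 40 ms plateau with a
    20 ms repolarization ramp, and a dye that loses 4% of its resting
    fluorescence at full depolarization.  ``noise_sigma_px`` is the per-pixel
    additive noise std as a fraction of ``f0``; 0.004 puts the std of a
    ~4-pixel ROI mean at ~0.2% of rest, the upper end of realistic ROI shot
    noise for this kind of recording.
    """

    grid_shape: tuple[int, int] = (128, 128)
    px_size_mm: float = 10.0 / 128.0
    cv_mm_ms: float = 0.5
    upstroke_ms: float = 2.0
    apd_ms: float = 40.0
    repol_ms: float = 20.0
    refractory_ms: float = 70.0
    f0: float = 10000.0
    sensitivity: float = 0.04
    noise_sigma_px: float = 0.004
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 2 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be two positive integers")
        for name in ("upstroke_ms", "apd_ms", "repol_ms", "refractory_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.refractory_ms < self.upstroke_ms + self.apd_ms:
            raise ValueError("refractory_ms must be >= upstroke_ms + apd_ms")
        if not 0.0 < self.sensitivity < 1.0:
            raise ValueError("sensitivity must lie in (0, 1)")
        if self.noise_sigma_px < 0:
            raise ValueError("noise_sigma_px must be >= 0")
        if self.f0 <= 0 or self.f0 * (1.0 + 5.0 * self.noise_sigma_px) > 65535:
            raise ValueError("f0 (plus 5 sigma of noise) must fit in 16 bits")
        if self.px_size_mm <= 0:
            raise ValueError("px_size_mm must be > 0")
        if self.cv_mm_ms <= 0:
            raise ValueError("cv_mm_ms must be > 0")

    @property
    def ap_duration_ms(self) -> float:
        return self.upstroke_ms + self.apd_ms + self.repol_ms

    @property
    def refractory_us(self) -> float:
        return self.refractory_ms * 1000.0

    def pixel_centers_mm(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every pixel center, each shaped like the grid.

        The mm origin sits at the outer corner of pixel (0, 0); x runs along
        columns (rightwards), y along rows (downwards).
        """
        rows, cols = self.grid_shape
        y = (np.arange(rows) + 0.5) * self.px_size_mm
        x = (np.arange(cols) + 0.5) * self.px_size_mm
        xg, yg = np.meshgrid(x, y)
        return xg, yg


@dataclass
class TissueState:
    """Per-pixel activation bookkeeping.

    ``last_activation`` holds the time (µs) each pixel last depolarized,
    -inf for never.  ``pending_arrivals`` is a list of wavefront arrival-time
    maps (µs, +inf where no arrival is scheduled), one per stimulus, kept in
    the order the stimuli were applied.
    """

    last_activation: np.ndarray
    pending_arrivals: list[np.ndarray] = field(default_factory=list)
    clock: float = 0.0

    @classmethod
    def quiescent(cls, params: TissueParams) -> "TissueState":
        return cls(last_activation=np.full(params.grid_shape, -np.inf))

    @property
    def has_pending(self) -> bool:
        return bool(self.pending_arrivals)


@dataclass(frozen=True)
class StimMask:
    """Boolean membership map of a patterned light stimulus."""

    pixels: np.ndarray
    descriptor: dict

    def __post_init__(self) -> None:
        if not self.pixels.any():
            raise ValueError(
                "stimulus mask selects no pixels; such a stimulus cannot excite tissue"
            )

    @property
    def n_pixels(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class PixelRect:
    """A rectangular pixel region, rows [row0, row0+n_rows) x cols [col0, col0+n_cols)."""

    row0: int
    col0: int
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("PixelRect must be non-empty")
        if self.row0 < 0 or self.col0 < 0:
            raise ValueError("PixelRect must start inside the frame")

    @classmethod
    def from_mm(
        cls, corner_mm: Sequence[float], size_mm: Sequence[float], params: TissueParams
    ) -> "PixelRect":
        """Pixels whose centers fall in the half-open box [x, x+w) x [y, y+h)."""
        x, y = corner_mm
        w, h = size_mm
        p = params.px_size_mm
        row0 = max(0, int(np.ceil(y / p - 0.5)))
        row1 = min(params.grid_shape[0], int(np.ceil((y + h) / p - 0.5)))
        col0 = max(0, int(np.ceil(x / p - 0.5)))
        col1 = min(params.grid_shape[1], int(np.ceil((x + w) / p - 0.5)))
        if row1 <= row0 or col1 <= col0:
            raise ValueError("rectangle contains no pixel centers inside the field")
        return cls(row0, col0, row1 - row0, col1 - col0)

    @property
    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.n_rows),
            slice(self.col0, self.col0 + self.n_cols),
        )

    def inside(self, shape: tuple[int, int]) -> bool:
        return self.row0 + self.n_rows <= shape[0] and self.col0 + self.n_cols <= shape[1]

    def center_distances_mm(self, mask: StimMask, params: TissueParams) -> np.ndarray:
        """Distance from each ROI pixel center to the nearest mask pixel center."""
        xg, yg = params.pixel_centers_mm()
        mx = xg[mask.pixels]
        my = yg[mask.pixels]
        rx = xg[self.slices].ravel()
        ry = yg[self.slices].ravel()
        d = np.hypot(rx[:, None] - mx[None, :], ry[:, None] - my[None, :])
        return d.min(axis=1)


def make_circular_mask(
    center_mm: Sequence[float], diameter_mm: float, params: TissueParams
) -> StimMask:
    """Circular light spot; a pixel belongs iff its center lies within the radius."""
    xg, yg = params.pixel_centers_mm()
    cx, cy = center_mm
    inside = np.hypot(xg - cx, yg - cy) <= diameter_mm / 2.0
    return StimMask(
        pixels=inside,
        descriptor={"shape": "circle", "center_mm": (float(cx), float(cy)),
                    "diameter_mm": float(diameter_mm)},
    )


def make_rect_mask(
    corner_mm: Sequence[float], size_mm: Sequence[float], params: TissueParams
) -> StimMask:
    """Rectangular pattern over the half-open box [x, x+w) x [y, y+h) in mm."""
    xg, yg = params.pixel_centers_mm()
    x, y = corner_mm
    w, h = size_mm
    inside = (xg >= x) & (xg < x + w) & (yg >= y) & (yg < y + h)
    return StimMask(
        pixels=inside,
        descriptor={"shape": "rect", "corner_mm": (float(x), float(y)),
                    "size_mm": (float(w), float(h))},
    )


def advance_to(state: TissueState, t_us: float, params: TissueParams) -> TissueState:
    """Apply every scheduled wavefront arrival up to and including ``t_us``.

    An arrival activates its pixel only if the pixel has been recovered for at
    least the refractory period at the arrival time; otherwise the arrival is
    discarded (the wave does not re-enter refractory tissue).
    """
    refr = params.refractory_us
    keep: list[np.ndarray] = []
    for arrivals in state.pending_arrivals:
        due = arrivals <= t_us
        if due.any():
            ok = due & (arrivals - state.last_activation >= refr)
            state.last_activation[ok] = arrivals[ok]
            arrivals[due] = np.inf
        if np.isfinite(arrivals).any():
            keep.append(arrivals)
    state.pending_arrivals = keep
    state.clock = max(state.clock, t_us)
    return state


def apply_stimulus(
    state: TissueState, mask: StimMask, t_us: float, params: TissueParams
) -> TissueState:
    """Activate non-refractory masked pixels at ``t_us`` and launch the wavefront.

    From the set of pixels the stimulus actually captures, arrival times are
    scheduled for every other pixel at t + d/cv, with d the Euclidean distance
    (between pixel centers) to the nearest captured pixel.  A fully refractory
    target leaves the tissue unchanged apart from the clock.
    """
    if t_us < state.clock:
        raise ValueError("stimulus time precedes the tissue clock")
    advance_to(state, t_us, params)
    captured = mask.pixels & (t_us - state.last_activation >= params.refractory_us)
    if not captured.any():
        return state
    state.last_activation[captured] = t_us
    dist_mm = ndimage.distance_transform_edt(
        ~captured, sampling=(params.px_size_mm, params.px_size_mm)
    )
    arrivals = t_us + dist_mm / params.cv_mm_ms * 1000.0
    arrivals[captured] = np.inf
    if np.isfinite(arrivals).any():
        state.pending_arrivals.append(arrivals)
    return state


def ap_waveform(tau_ms, params: TissueParams):
    """Normalized membrane potential as a function of time since activation (ms).

    Piecewise linear: 0 before activation, a linear upstroke to 1, a flat
    plateau, a linear repolarization ramp back to 0, and 0 afterwards.
    Accepts scalars or arrays.
    """
    knots_t = (
        0.0,
        params.upstroke_ms,
        params.upstroke_ms + params.apd_ms,
        params.upstroke_ms + params.apd_ms + params.repol_ms,
    )
    return np.interp(tau_ms, knots_t, (0.0, 1.0, 1.0, 0.0))


def render_frame(
    state: TissueState,
    t_us: float,
    params: TissueParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render the fluorescence image at ``t_us`` as a 16-bit matrix.

    F = f0 * (1 - sensitivity * V(tau)) + N(0, noise_sigma_px * f0), rounded
    half-away-from-zero and clipped to the 16-bit range.  Depolarized tissue is
    *darker* than rest.  All pending arrivals up to ``t_us`` must have been
    applied (use :func:`advance_to`); the driving engine does this.
    """
    last = state.last_activation
    max_last = last.max()
    quiet = (not state.has_pending) and (
        max_last == -np.inf or (t_us - max_last) / 1000.0 > params.ap_duration_ms
    )
    if quiet:
        f = np.full(params.grid_shape, params.f0)
    else:
        tau_ms = (t_us - last) / 1000.0
        v = ap_waveform(tau_ms, params)
        f = params.f0 * (1.0 - params.sensitivity * v)
    if rng is not None and params.noise_sigma_px > 0:
        f = f + rng.normal(0.0, params.noise_sigma_px * params.f0, size=params.grid_shape)
    return np.clip(np.floor(f + 0.5), 0, 65535).astype(np.uint16)
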