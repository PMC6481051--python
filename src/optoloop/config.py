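"""Run-configuration file handling: explicit-unit keys, strict validation.

A run is described by one YAML (or JSON, which YAML subsumes) file with
sections ``tissue``, ``camera``, ``detector``, ``protocol``, ``load`` and
``session``.  Every physical quantity carries its unit in the key name
(``_us``, ``_mm``, ``_ms``, ``_fraction``).  Unknown keys are rejected with
the offending key named, so typos fail fast instead of silently running a
default.  LED drive settings are accepted for fidelity with the bench
instrument but only appear in logs — light intensity does not modulate the
activation-time tissue model.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .frames import CameraConfig
from .loop import DetectorConfig, LoadModel, StimProtocol
from .tissue import PixelRect, StimMask, TissueParams, make_circular_mask

__all__ = ["ConfigError", "RunConfig", "load_config", "parse_config", "dump_config"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


_TISSUE_KEYS = {
    "px_size_mm", "cv_mm_per_ms", "upstroke_ms", "apd_ms", "repol_ms",
    "refractory_ms", "f0_counts", "sensitivity_fraction", "noise_sigma_fraction",
}
_CAMERA_KEYS = {"exposure_us", "area_px"}
_DETECTOR_MM_KEYS = {"roi_x_mm", "roi_y_mm", "roi_w_mm", "roi_h_mm"}
_DETECTOR_PX_KEYS = {"roi_row0_px", "roi_col0_px", "roi_rows_px", "roi_cols_px"}
_DETECTOR_KEYS = _DETECTOR_MM_KEYS | _DETECTOR_PX_KEYS | {"threshold_fraction", "buffer_len"}
_PROTOCOL_KEYS = {
    "pre_delay_us", "pulse_us", "post_delay_us",
    "spot_center_x_mm", "spot_center_y_mm", "spot_diameter_mm", "led_amplitude_v",
}
_LOAD_KEYS = {"il_cost_us", "rtl_cost_us", "il_jitter_us", "rtl_jitter_us"}
_SESSION_KEYS = {
    "mode", "duration_us", "seed", "init_stim_time_us", "keep_frames", "out_dir",
}
_SECTIONS = {
    "tissue": _TISSUE_KEYS,
    "camera": _CAMERA_KEYS,
    "detector": _DETECTOR_KEYS,
    "protocol": _PROTOCOL_KEYS,
    "load": _LOAD_KEYS,
    "session": _SESSION_KEYS,
}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration, ready to hand to the engine."""

    tissue: TissueParams
    camera: CameraConfig
    detector: DetectorConfig | None
    protocol: StimProtocol | None
    load: LoadModel
    mode: str
    duration_us: int
    seed: int
    init_stim_time_us: int | None
    keep_frames: bool
    out_dir: str | None
    raw: dict


def _check_keys(section: str, data: dict) -> None:
    allowed = _SECTIONS[section]
    for key in data:
        if key not in allowed:
            raise ConfigError(f"unknown key '{key}' in section '{section}'")


def parse_config(data: dict) -> RunConfig:
    """Validate a configuration mapping and build the typed run objects."""
    if not isinstance(data, dict):
        raise ConfigError("configuration root must be a mapping")
    for section in data:
        if section not in _SECTIONS:
            raise ConfigError(f"unknown section '{section}'")

    t = dict(data.get("tissue") or {})
    _check_keys("tissue", t)
    try:
        tissue = TissueParams(
            px_size_mm=float(t.get("px_size_mm", 10.0 / 128.0)),
            cv_mm_ms=float(t.get("cv_mm_per_ms", 0.5)),
            upstroke_ms=float(t.get("upstroke_ms", 2.0)),
            apd_ms=float(t.get("apd_ms", 40.0)),
            repol_ms=float(t.get("repol_ms", 20.0)),
            refractory_ms=float(t.get("refractory_ms", 70.0)),
            f0=float(t.get("f0_counts", 10000.0)),
            sensitivity=float(t.get("sensitivity_fraction", 0.04)),
            noise_sigma_px=float(t.get("noise_sigma_fraction", 0.004)),
        )
    except ValueError as e:
        raise ConfigError(f"tissue: {e}") from e

    c = dict(data.get("camera") or {})
    _check_keys("camera", c)
    area = tuple(c.get("area_px", (128, 128)))
    try:
        camera = CameraConfig(exposure_us=int(c.get("exposure_us", 2000)), area=area)
    except ValueError as e:
        raise ConfigError(f"camera: {e}") from e

    s = dict(data.get("session") or {})
    _check_keys("session", s)
    mode = str(s.get("mode", "closed-loop"))
    if mode not in ("free-run", "closed-loop"):
        raise ConfigError(f"session: unknown mode '{mode}'")
    duration_us = int(s.get("duration_us", 0))
    if duration_us < 0:
        raise ConfigError("session: duration_us must be >= 0")
    seed = int(s.get("seed", 0))
    init_raw = s.get("init_stim_time_us")
    init_stim = None if init_raw is None else int(init_raw)
    keep_frames = bool(s.get("keep_frames", True))
    out_dir = s.get("out_dir")

    detector = None
    if "detector" in data or mode == "closed-loop":
        d = dict(data.get("detector") or {})
        _check_keys("detector", d)
        has_mm = _DETECTOR_MM_KEYS & d.keys()
        has_px = _DETECTOR_PX_KEYS & d.keys()
        if has_mm and has_px:
            raise ConfigError("detector: give the ROI in mm or in pixels, not both")
        try:
            if has_px:
                roi = PixelRect(
                    int(d["roi_row0_px"]), int(d["roi_col0_px"]),
                    int(d["roi_rows_px"]), int(d["roi_cols_px"]),
                )
            else:
                roi = PixelRect.from_mm(
                    (float(d.get("roi_x_mm", 4.85)), float(d.get("roi_y_mm", 0.70))),
                    (float(d.get("roi_w_mm", 0.30)), float(d.get("roi_h_mm", 0.10))),
                    tissue,
                )
            detector = DetectorConfig(
                roi=roi,
                th=float(d.get("threshold_fraction", 0.01)),
                buffer_len=int(d.get("buffer_len", 10)),
            )
        except (KeyError, ValueError) as e:
            raise ConfigError(f"detector: {e}") from e

    protocol = None
    if "protocol" in data or mode == "closed-loop":
        p = dict(data.get("protocol") or {})
        _check_keys("protocol", p)
        try:
            mask = make_circular_mask(
                (float(p.get("spot_center_x_mm", 5.0)), float(p.get("spot_center_y_mm", 9.5))),
                float(p.get("spot_diameter_mm", 1.0)),
                tissue,
            )
            protocol = StimProtocol(
                mask=mask,
                pre_delay_us=int(p.get("pre_delay_us", 200_000)),
                pulse_us=int(p.get("pulse_us", 5_000)),
                post_delay_us=int(p.get("post_delay_us", 5_000)),
                amplitude=float(p.get("led_amplitude_v", 1.0)),
            )
        except ValueError as e:
            raise ConfigError(f"protocol: {e}") from e

    ld = dict(data.get("load") or {})
    _check_keys("load", ld)
    try:
        load = LoadModel(
            il_cost_us=float(ld.get("il_cost_us", 0.0)),
            rtl_cost_us=float(ld.get("rtl_cost_us", 0.0)),
            il_jitter_us=float(ld.get("il_jitter_us", 0.0)),
            rtl_jitter_us=float(ld.get("rtl_jitter_us", 0.0)),
        )
    except ValueError as e:
        raise ConfigError(f"load: {e}") from e

    return RunConfig(
        tissue=tissue, camera=camera, detector=detector, protocol=protocol,
        load=load, mode=mode, duration_us=duration_us, seed=seed,
        init_stim_time_us=init_stim, keep_frames=keep_frames,
        out_dir=str(out_dir) if out_dir is not None else None, raw=data,
    )


def load_config(path) -> RunConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse {path}: {e}") from e
    if data is None:
        data = {}
    return parse_config(data)


def dump_config(cfg: RunConfig) -> dict:
    """Serializable mapping that re-parses to an identical validated structure."""
    t, c = cfg.tissue, cfg.camera
    out: dict = {
        "tissue": {
            "px_size_mm": t.px_size_mm, "cv_mm_per_ms": t.cv_mm_ms,
            "upstroke_ms": t.upstroke_ms, "apd_ms": t.apd_ms,
            "repol_ms": t.repol_ms, "refractory_ms": t.refractory_ms,
            "f0_counts": t.f0, "sensitivity_fraction": t.sensitivity,
            "noise_sigma_fraction": t.noise_sigma_px,
        },
        "camera": {"exposure_us": c.exposure_us, "area_px": list(c.area)},
        "load": {
            "il_cost_us": cfg.load.il_cost_us, "rtl_cost_us": cfg.load.rtl_cost_us,
            "il_jitter_us": cfg.load.il_jitter_us, "rtl_jitter_us": cfg.load.rtl_jitter_us,
        },
        "session": {
            "mode": cfg.mode, "duration_us": cfg.duration_us, "seed": cfg.seed,
            "keep_frames": cfg.keep_frames,
        },
    }
    if cfg.init_stim_time_us is not None:
        out["session"]["init_stim_time_us"] = cfg.init_stim_time_us
    if cfg.out_dir is not None:
        out["session"]["out_dir"] = cfg.out_dir
    if cfg.detector is not None:
        roi = cfg.detector.roi
        out["detector"] = {
            "roi_row0_px": roi.row0, "roi_col0_px": roi.col0,
            "roi_rows_px": roi.n_rows, "roi_cols_px": roi.n_cols,
            "threshold_fraction": cfg.detector.th, "buffer_len": cfg.detector.buffer_len,
        }
    if cfg.protocol is not None:
        p = cfg.protocol
        desc = p.mask.descriptor
        out["protocol"] = {
            "pre_delay_us": p.pre_delay_us, "pulse_us": p.pulse_us,
            "post_delay_us": p.post_delay_us,
            "spot_center_x_mm": desc["center_mm"][0],
            "spot_center_y_mm": desc["center_mm"][1],
            "spot_diameter_mm": desc["diameter_mm"],
            "led_amplitude_v": p.amplitude,
        }
    return out
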