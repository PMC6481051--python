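import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from optoloop import CameraConfig, PixelRect, TissueParams, make_circular_mask
from optoloop.loop import DetectorConfig, StimProtocol

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def params() -> TissueParams:
    """Default murine-scale tissue over a 10x10 mm field."""
    return TissueParams()


@pytest.fixture
def quiet_params() -> TissueParams:
    """Noise-free variant, for exact-value checks."""
    return TissueParams(noise_sigma_px=0.0)


@pytest.fixture
def small_params() -> TissueParams:
    """Tiny 16x16 grid for brute-force comparisons."""
    return TissueParams(grid_shape=(16, 16), px_size_mm=10.0 / 16.0, noise_sigma_px=0.0)


@pytest.fixture
def camera() -> CameraConfig:
    return CameraConfig(exposure_us=2000)


@pytest.fixture
def base_roi() -> PixelRect:
    """Detection ROI at the heart base (0.1 x 0.3 mm at the top of the field)."""
    return PixelRect.from_mm((4.85, 0.70), (0.30, 0.10), TissueParams())


@pytest.fixture
def detector(base_roi) -> DetectorConfig:
    return DetectorConfig(roi=base_roi, th=0.01, buffer_len=10)


@pytest.fixture
def apex_mask(params):
    """1 mm circular stimulation spot at the ventricular apex."""
    return make_circular_mask((5.0, 9.5), 1.0, params)


@pytest.fixture
def protocol(apex_mask) -> StimProtocol:
    """Three-phase protocol: 200 ms pre-delay, 5 ms pulse, 5 ms post-delay."""
    return StimProtocol(mask=apex_mask, pre_delay_us=200_000, pulse_us=5_000,
                        post_delay_us=5_000)


def brute_force_circle_count(center_mm, diameter_mm, p: TissueParams) -> int:
    n = 0
    for r in range(p.grid_shape[0]):
        for c in range(p.grid_shape[1]):
            x = (c + 0.5) * p.px_size_mm
            y = (r + 0.5) * p.px_size_mm
            if np.hypot(x - center_mm[0], y - center_mm[1]) <= diameter_mm / 2:
                n += 1
    return n


def brute_force_rect_count(corner_mm, size_mm, p: TissueParams) -> int:
    n = 0
    for r in range(p.grid_shape[0]):
        for c in range(p.grid_shape[1]):
            x = (c + 0.5) * p.px_size_mm
            y = (r + 0.5) * p.px_size_mm
            if corner_mm[0] <= x < corner_mm[0] + size_mm[0] and \
               corner_mm[1] <= y < corner_mm[1] + size_mm[1]:
                n += 1
    return n
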