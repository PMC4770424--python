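"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from tonomap.config import PipelineConfig
from tonomap.pipeline import PipelineResult, analyze
from tonomap.response import ResponseMap


@pytest.fixture(scope="session")
def default_run() -> PipelineResult:
    """One full end-to-end analysis under the default study conditions
    (5 animals, 20 trials, 0.1-mm jitter SD, noise at 20% of amplitude),
    shared across tests that inspect its products."""
    cfg = PipelineConfig()
    cfg.cohort.seed = 0
    return analyze(cfg)


def disk_response_map(
    radius_um: float = 150.0,
    pitch_um: float = 20.4,
    amplitude: float = 0.02,
    shape: tuple[int, int] = (64, 64),
    center_px: tuple[float, float] | None = None,
) -> tuple[ResponseMap, tuple[float, float]]:
    """A flat ΔF/F₀ disk (amplitude inside the radius, 0 outside).

    Returns the map and the disk center in (row, col) pixels. The disk's
    >60%-of-peak level set is exactly the disk itself.
    """
    if center_px is None:
        center_px = ((shape[0] - 1) / 2 + 0.3, (shape[1] - 1) / 2 - 0.2)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    r_um = np.hypot(rows - center_px[0], cols - center_px[1]) * pitch_um
    values = np.where(r_um < radius_um, amplitude, 0.0)
    return ResponseMap(values, pitch_um), center_px


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
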