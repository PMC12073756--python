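"""Shared fixtures: small simulated scans and their reconstructions.

Session scope keeps the rendering/reconstruction cost paid once; tests must
treat these objects as read-only.
"""

import numpy as np
import pytest

import algascan as ag
from algascan.config import PipelineConfig


@pytest.fixture(scope="session")
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def demo_scan(cfg):
    """Default four-species scene, 128x160, 240 frames, noise 0.005."""
    return ag.simulate_scan(cfg, seed=1)


@pytest.fixture(scope="session")
def demo_result(demo_scan, cfg):
    stack, _ = demo_scan
    return ag.build_cube(stack, config=cfg, keep_intensity=True)


@pytest.fixture(scope="session")
def flat_scan(cfg):
    """Flat R = 0.5 patch on the grey plate."""
    return ag.simulate_scan(cfg, layout="flat_patch", seed=3)


@pytest.fixture(scope="session")
def flat_result(flat_scan, cfg):
    stack, _ = flat_scan
    return ag.build_cube(stack, config=cfg)


@pytest.fixture(scope="session")
def demo_library(demo_result, demo_scan, cfg):
    """Spectral library extracted from the demo cube's ground-truth boxes."""
    _, scene = demo_scan
    anns = ag.annotations_from_scene(scene, "demo", margin=cfg.scene.margin)
    return ag.extract_labeled_pixels({"demo": demo_result.cube}, anns)
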