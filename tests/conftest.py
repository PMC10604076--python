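import numpy as np
import pytest

import dropswarm as dw
from dropswarm import image_restore as ir


def small_well_config(seed=0, **overrides):
    """A fast well for unit tests: 12 full-scale particles on a small crop."""
    cfg = dw.SceneConfig(
        image_height_px=520, image_width_px=640, n_particles=12, seed=seed
    )
    return cfg.replace(**overrides) if overrides else cfg


@pytest.fixture(scope="session")
def small_cfg():
    return small_well_config(seed=3)


@pytest.fixture(scope="session")
def small_well(small_cfg):
    """(config, truth, frames, bright_field, dark_field) for a small well."""
    truth = dw.sample_scene(small_cfg)
    frames, bf, df = dw.render_modalities(truth, small_cfg)
    return small_cfg, truth, frames, bf, df


@pytest.fixture(scope="session")
def compact_well():
    """The standard half-field study well (~150 particles)."""
    cfg = dw.compact_well_config(seed=7)
    truth = dw.sample_scene(cfg)
    frames, bf, df = dw.render_modalities(truth, cfg)
    return cfg, truth, frames, bf, df


@pytest.fixture(scope="session")
def small_hdr(small_well):
    cfg, truth, frames, bf, df = small_well
    stack = ir.LDRStack(frames, list(cfg.exposure_times_ms), cfg.saturation_value)
    return ir.synthesize_hdr(ir.register_stack(stack))
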