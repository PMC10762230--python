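"""Shared fixtures: small phantoms and rendered videos, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from rotomo.phantom import (
    PhantomSpec,
    default_phantom_spec,
    make_phantom,
    render_rotation_video,
)
from rotomo.phantom import scaled_default_spec


@pytest.fixture(scope="session")
def mini_spec() -> PhantomSpec:
    """Default phantom geometry on a fast 48³ grid (same physical cell)."""
    return scaled_default_spec(48, seed=0)


@pytest.fixture(scope="session")
def mini_phantom(mini_spec):
    return make_phantom(mini_spec)


@pytest.fixture(scope="session")
def mini_video(mini_spec):
    """24-frame rotation video of the mini phantom (with 1% noise)."""
    return render_rotation_video(mini_spec, n_frames=24, total_angle=180.0)


@pytest.fixture(scope="session")
def clean_mini_video(mini_spec):
    """Noise-free 24-frame rotation video (bit-reproducible projections)."""
    from rotomo.phantom import NoiseSpec

    return render_rotation_video(
        mini_spec, n_frames=24, total_angle=180.0, noise=NoiseSpec(0.0, 0.0)
    )


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default 128³ phantom video (seed 0).

    Session-scoped because it is the most expensive fixture (~1 min); the
    acceptance tests share it.
    """
    from rotomo.pipeline import PipelineConfig, run_pipeline

    out = tmp_path_factory.mktemp("default_run")
    cfg = PipelineConfig(
        phantom=default_phantom_spec(), out_dir=str(out), seed=0
    )
    return run_pipeline(cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
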