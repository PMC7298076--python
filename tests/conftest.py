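"""Shared fixtures: small synthetic scenes and a trained patch classifier.

Everything is generated programmatically with pinned seeds; the scenes use
a reduced plot (1 m x 0.5 m at 0.25 cm/px, 400 x 200 px) so the whole
suite runs in minutes on one CPU.
"""

import numpy as np
import pytest

import standcount as sc
from standcount.indices import LEAF, SOIL, WEED


def small_config(seed: int, role: str = "train", **kw) -> sc.SimConfig:
    defaults = dict(
        plot_size=(1.0, 0.5),
        resolution=0.25,
        rows=2,
        row_spacing=20.0,
        plants_per_plot=10,
        weed_density=12.0,
        stage=sc.GrowthStageSpec.from_dap(53),
        seed=seed,
        plot_id=f"plot-s{seed}",
        role=role,
    )
    defaults.update(kw)
    return sc.SimConfig(**defaults)


@pytest.fixture(scope="session")
def train_scenes():
    return [sc.generate_scene(small_config(s)) for s in (1, 2)]


@pytest.fixture(scope="session")
def test_scene():
    return sc.generate_scene(small_config(9, role="test"))


@pytest.fixture(scope="session")
def train_maps(train_scenes):
    return [sc.label_pixels(s) for s in train_scenes]


@pytest.fixture(scope="session")
def trained_model(train_scenes, train_maps):
    """Patch-16 classifier trained on the two small training scenes."""
    samples = sc.sample_patches(
        train_scenes, train_maps, 16, {LEAF: 600, WEED: 300, SOIL: 300}, seed=5
    )
    spec = sc.CnnSpec(patch_size=16, epochs=12, optimizer="adam", seed=0)
    return sc.train(spec, samples)
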