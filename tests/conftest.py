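from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from crowdseg import BinaryMask, SceneSpec


def random_mask(rng: np.random.Generator, height: int = 8, width: int = 8,
                density: float = 0.4) -> BinaryMask:
    return BinaryMask(rng.random((height, width)) < density)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene() -> SceneSpec:
    return SceneSpec(
        width=32,
        height=32,
        structures={
            "bowel": {"presence_probability": 0.7, "blob_radius": (3, 8)},
            "abdominal_wall": {"presence_probability": 0.8, "blob_radius": (3, 8)},
        },
        seed=11,
    )
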