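import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from tonguedx.pipeline import ManifestDataset
from tonguedx.synthetic import GeneratorConfig, build_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_dataset(tmp_path_factory) -> ManifestDataset:
    """Small, strongly label-conditional dataset shared by pipeline tests."""
    root = tmp_path_factory.mktemp("easy_data")
    cfg = GeneratorConfig(n_samples=96, image_size=32, effect_size=2.0,
                          cross_modal_agreement=1.0, seed=5)
    build_dataset(cfg, root)
    return ManifestDataset(root / "manifest.jsonl")
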