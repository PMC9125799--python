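from __future__ import annotations

import numpy as np
import pytest

from orfanscan.simulate import SyntheticParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20220423)


def noise_free_params(seed: int, **overrides) -> SyntheticParams:
    """Generator settings for a clean, quickly simulated bundle."""
    defaults = dict(n_host=4, n_viruses=3, n_samples=4,
                    depth_per_contig=150.0, substitution_error_rate=0.0,
                    plus_fraction=0.5, contig_len_range=(1500, 2600),
                    seed=seed)
    defaults.update(overrides)
    return SyntheticParams(**defaults)


@pytest.fixture
def synthetic_bundle(tmp_path):
    """One noise-free bundle on disk plus its truth manifest."""
    params = noise_free_params(seed=11)
    paths, manifest = generate_dataset(params, tmp_path / "bundle")
    return paths, manifest
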