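import numpy as np
import pytest

from splicediv import synthdata


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_splice_dataset():
    """200-event two-strain dataset with 20% planted strain effects."""
    cfg = synthdata.SimConfig(
        n_events=200, depth_mean=200.0, effect_frac=0.2, effect_dpsi=0.25,
        bb_concentration=None, seed=101,
    )
    return cfg, *synthdata.gen_splice_dataset(cfg)


@pytest.fixture(scope="session")
def f1_dataset():
    """300-event F1 design: one third cis-only, one third trans-only."""
    cfg = synthdata.SimConfig(
        n_events=300, depth_mean=200.0, effect_dpsi=0.25,
        bb_concentration=None, seed=77,
    )
    parents, hybrids, truth = synthdata.gen_f1_dataset(
        cfg, cis_frac=1 / 3, trans_frac=1 / 3
    )
    return cfg, parents, hybrids, truth


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    cfg = synthdata.SimConfig(n_events=100, seed=3)
    return synthdata.write_fixture_bundle(out / "fix", cfg), cfg
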