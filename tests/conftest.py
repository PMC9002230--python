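import numpy as np
import pytest

from tgmlp.network import NetworkConfig, StageConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_config(input_size: int = 32, grid: int = 2, *, use_tm=True, use_lgp=True,
                use_gate=True) -> NetworkConfig:
    """A miniature network for fast structural tests (same topology)."""
    cfg = NetworkConfig(stem_channels=4, local_patch_grid=grid,
                        input_size=input_size)
    cfg.global_stages = [StageConfig(channels=4), StageConfig(channels=8)]
    cfg.local_stages = [StageConfig(channels=4), StageConfig(channels=4),
                        StageConfig(channels=8), StageConfig(channels=8),
                        StageConfig(channels=8, downsample=1)]
    for st, extent in zip(cfg.global_stages, cfg.global_extents()):
        st.partition_h = max(extent // 2, 1)
    for st, extent in zip(cfg.local_stages, cfg.local_extents()):
        st.partition_h = max(extent // 2, 1)
    for st in cfg.global_stages + cfg.local_stages:
        st.use_tm, st.use_lgp, st.use_gate = use_tm, use_lgp, use_gate
    cfg.validate()
    return cfg


@pytest.fixture
def tiny_cfg():
    return tiny_config()


@pytest.fixture
def tiny_samples():
    """Four small lesion samples for fast training tests."""
    from tgmlp.synthetic import default_spec, generate_sample

    spec = default_spec("lesion", 32, seed=11)
    return [generate_sample(spec, i) for i in range(4)]
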