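import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gait_ssl as g

settings.register_profile(
    "default", derandomize=True, max_examples=25, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three subjects, one cycle per condition: 9 cycles of 100 samples."""
    cfg = g.SyntheticDatasetConfig(n_subjects=3, cycles_per_condition=1, seed=42)
    return g.generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_windows(tiny_dataset):
    """Standardized 32-sample windows with moment targets (step 8)."""
    return g.standardize(g.prepare_windows(tiny_dataset, window=32, step=8))


@pytest.fixture(scope="session")
def tiny_model_spec():
    """A minimal but structurally complete architecture for fast tests."""
    return g.ModelSpec(
        window=32, patch_length=1, n_channels_in=18, d_model=8, n_blocks=2, n_heads=2, ffn_dim=16
    )


# ---------------------------------------------------------------------------
# Shared desk-scale benchmark state (used by the acceptance suite).
# Built once per session: ~2,500-window cohort, pre-trained encoder,
# label-scarce splits for the knee.
# ---------------------------------------------------------------------------

DESK_SEED = 1


@pytest.fixture(scope="session")
def desk_windows():
    _, windows = g.build_desk_windows(seed=DESK_SEED)
    return windows


@pytest.fixture(scope="session")
def desk_encoder(desk_windows):
    return g.desk_pretrained(desk_windows, seed=DESK_SEED)


@pytest.fixture(scope="session")
def desk_splits(desk_windows):
    return g.desk_labeled_splits(desk_windows, joint="knee", split_seed=DESK_SEED + 7)
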