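"""Shared fixtures: small seeded synthetic datasets built at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from megfusion.conditions import (
    CATEGORIES,
    N_EXEMPLARS_PER_CATEGORY,
)
from megfusion.synthgen import (
    EpochedDataset,
    SimulationConfig,
    generate_behavior,
    generate_meg_epochs,
)


def balanced_labels(reps: int) -> pd.DataFrame:
    """Deterministic labels with every exemplar x outcome cell filled
    ``reps`` times (guarantees all 40 conditions are present)."""
    rows = []
    for outcome in ("recognized", "unrecognized"):
        for cat in CATEGORIES:
            for ex in range(1, N_EXEMPLARS_PER_CATEGORY + 1):
                rows.extend(
                    {"exemplar": ex, "category": cat, "outcome": outcome}
                    for _ in range(reps)
                )
    return pd.DataFrame(rows)


def null_dataset(
    reps: int = 2,
    n_sensors: int = 16,
    n_times: int = 11,
    sfreq_hz: float = 20.0,
    seed: int = 0,
    t0_ms: float = -500.0,
) -> EpochedDataset:
    """Pure-noise epochs with balanced condition labels."""
    labels = balanced_labels(reps)
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((len(labels), n_sensors, n_times))
    dt = 1000.0 / sfreq_hz
    time_ms = t0_ms + dt * np.arange(n_times)
    return EpochedDataset(data=data, time_ms=time_ms, labels=labels, sfreq_hz=sfreq_hz)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Planted-geometry study at a size that keeps the suite fast."""
    from megfusion.synthgen import RoiProfile

    return SimulationConfig(
        n_trials=300,
        n_sensors=48,
        n_voxels_per_roi=80,
        sfreq_hz=20.0,
        roi_profiles={
            "V1": RoiProfile(1.0, 0.3, "Visual"),
            "L_MFG": RoiProfile(0.1, 1.0, "FPCN"),
            "null_roi": RoiProfile(0.0, 0.0, "DMN"),
        },
        seed=7,
    )


@pytest.fixture(scope="session")
def small_behavior(small_config):
    return generate_behavior(small_config)


@pytest.fixture(scope="session")
def small_epochs(small_config, small_behavior):
    epochs, ground_truth = generate_meg_epochs(small_config, small_behavior)
    return epochs, ground_truth


@pytest.fixture(scope="session")
def group_rdms(small_config):
    """Group-average MEG RDM timecourse over four synthetic subjects."""
    from megfusion import rsa

    rdms = []
    for s in range(4):
        cfg = small_config.with_seed(1000 + s)
        behavior = generate_behavior(cfg)
        epochs, _ = generate_meg_epochs(cfg, behavior)
        r, times = rsa.rdm_timecourse(epochs, step_ms=100.0)
        rdms.append(r)
    return np.mean(rdms, axis=0), times
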