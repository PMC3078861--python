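import numpy as np
import pytest

from jointfa import (
    SyntheticSpec,
    fit_joint_model,
    match_factors,
    simulate_dataset,
)
from jointfa.preprocess import max_fold_change_filter, normalize_rows


def noise_spec(seed: int, n_mrna: int = 500) -> SyntheticSpec:
    """Pure-noise spec: no planted loadings, scores or clusters."""
    return SyntheticSpec(
        seed=seed,
        n_mrna=n_mrna,
        class_design={},
        latent_design={},
        counterweights={},
        background_active_fraction=0.0,
        signal_score=0.0,
        clusters=[],
    )


def run_pipeline(dataset, n_factors=3, rotation="promax"):
    """Canonical chain: fold-change filter -> unit normalization -> FA."""
    joint, _ = max_fold_change_filter(dataset.expression)
    joint = normalize_rows(joint)
    return fit_joint_model(joint, n_factors=n_factors, rotation=rotation)


def centered(m: np.ndarray) -> np.ndarray:
    return m - m.mean(axis=0, keepdims=True)


def matched_recovery(dataset, result):
    """Match recovered factors to planted ones on centered loading columns."""
    return match_factors(centered(result.model.loadings), centered(dataset.loadings))


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    return run_pipeline(default_dataset)


@pytest.fixture(scope="session")
def default_match(default_dataset, default_result):
    return matched_recovery(default_dataset, default_result)
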