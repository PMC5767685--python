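import numpy as np
import pytest

from partwhole.config import CONDITIONS, EMOTIONS, DesignSpec, ScenarioConfig
from partwhole.datasets import PatternDataset


@pytest.fixture(scope="session")
def paper_design() -> DesignSpec:
    """The default 18-block / 8-trial / TR 2 s design."""
    return DesignSpec()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_pattern_dataset(cells: dict, roi_names=("EBA",), n_subjects=1, n_runs=3):
    """Build a PatternDataset from explicit {(s, r, roi, bt, emo): vector} cells."""
    return PatternDataset(
        patterns={k: np.asarray(v, dtype=float) for k, v in cells.items()},
        roi_names=tuple(roi_names),
        n_subjects=n_subjects,
        n_runs=n_runs,
    )


def full_cells_from_run_vectors(run_vectors, roi="EBA"):
    """One subject, 3 runs: run_vectors[(run, bt, emo)] -> vector."""
    cells = {}
    for r in range(3):
        for bt, emo in CONDITIONS:
            cells[(0, r, roi, bt, emo)] = run_vectors[(r, bt, emo)]
    return cells


@pytest.fixture(scope="session")
def part_based_dataset():
    """20 subjects, one ROI, gamma=1, noise tuned so person-synthetic r ~ 0.8."""
    from partwhole.simulate import (
        generate_condition_patterns,
        noise_for_person_synthetic_r,
    )

    cfg = ScenarioConfig(
        scenario="part_based",
        alpha_true={e: 0.5 for e in EMOTIONS},
        sigma_noise=noise_for_person_synthetic_r(0.8, alpha=0.5, gamma=1.0),
        n_voxels=600,
        n_subjects=20,
        n_runs=3,
        roi_names=("EBA",),
        seed=42,
    )
    from partwhole.simulate import generate_condition_patterns

    return generate_condition_patterns(cfg)
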