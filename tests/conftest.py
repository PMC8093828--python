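import numpy as np
import pandas as pd
import pytest

from ampdepth import AsvTable, SyntheticSpec, generate_dataset


def make_table(counts, labels, sample_ids=None, asv_ids=None) -> AsvTable:
    """Build a small AsvTable from a nested list (samples x ASVs)."""
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"S{i}" for i in range(counts.shape[0])]
    asv_ids = asv_ids or [f"A{j}" for j in range(counts.shape[1])]
    frame = pd.DataFrame(counts, index=sample_ids, columns=asv_ids)
    return AsvTable(frame, pd.Series(list(labels), index=sample_ids))


@pytest.fixture
def toy_table() -> AsvTable:
    """4 samples x 4 ASVs; ASV totals (50, 49, 100, 0); depths vary."""
    return make_table(
        [
            [20, 10, 40, 0],
            [10, 19, 20, 0],
            [15, 10, 30, 0],
            [5, 10, 10, 0],
        ],
        labels=["good", "good", "poor", "poor"],
    )


# Small generator settings reused across tests: 3 classes, clear signal,
# depths shallow enough that rarefaction and RF stay fast.
HARD_SPEC = dict(
    n_classes=3,
    samples_per_class=(10, 10, 10),
    n_background_asvs=240,
    n_specific_asvs_per_class=30,
    effect_size=30.0,
    overdispersion=60.0,
    depth_range=(2_000, 4_000),
)

SOFT_SPEC = dict(HARD_SPEC, effect_size=3.0, overdispersion=100.0)


@pytest.fixture(scope="session")
def hard_table() -> AsvTable:
    return generate_dataset(SyntheticSpec(**HARD_SPEC, seed=11))


@pytest.fixture(scope="session")
def soft_table() -> AsvTable:
    return generate_dataset(SyntheticSpec(**SOFT_SPEC, seed=11))
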