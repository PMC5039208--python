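import numpy as np
import pytest

from triplenet.bn import RoiTimeseriesTable
from triplenet.cohort import (
    CohortConfig,
    NetworkSpec,
    default_hub_model,
    simulate_cohort,
    simulate_node_timecourses,
)


def standardize(x):
    return (x - x.mean(axis=0)) / x.std(axis=0)


def make_roi_tables(model, n_subjects, n_timepoints, seed0, group):
    """Per-subject standardized node series drawn from a directed model."""
    tables = []
    for i in range(n_subjects):
        df = simulate_node_timecourses(model, n_timepoints, seed0 + i,
                                       group=group)
        tables.append(RoiTimeseriesTable(standardize(df.to_numpy()),
                                         tuple(df.columns), group,
                                         f"{group}{i:02d}"))
    return tables


@pytest.fixture(scope="session")
def tiny_specs():
    """Three disjoint small networks on a 16x16x10 grid.

    The scaled-down cohort (11 subjects) needs a proportionally stronger
    DMN loading difference to stay detectable at its reduced power.
    """
    return (
        NetworkSpec("CEN", (((4, 4, 5), 2.0, 1.0),)),
        NetworkSpec("DMN", (((11, 4, 5), 2.0, 1.0),), {"HR": 2.5, "LR": 1.0}),
        NetworkSpec("SN", (((8, 11, 5), 2.0, 1.0),)),
    )


@pytest.fixture(scope="session")
def tiny_config():
    return CohortConfig(
        n_subjects_per_group={"HR": 6, "LR": 5},
        volume_shape=(16, 16, 10),
        n_timepoints=40,
        drift_slope=0.02,
        noise_sd=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config, tiny_specs):
    return simulate_cohort(tiny_config, tiny_specs, default_hub_model())


@pytest.fixture(scope="session")
def tiny_preprocessed(tiny_cohort):
    """Tiny cohort after discard/detrend/smooth, ready for ICA."""
    from triplenet.preprocess import PreprocConfig, preprocess_subject

    subjects, truth = tiny_cohort
    cfg = PreprocConfig(n_discard=3, detrend=True, smooth_fwhm_mm=6.0)
    return [preprocess_subject(b, cfg) for b in subjects], truth


def dice(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * np.logical_and(a, b).sum() / denom if denom else 0.0
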