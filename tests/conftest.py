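import numpy as np
import pandas as pd
import pytest

from refrma import (
    ChipLayout,
    ProbeMatrix,
    SimConfig,
    build_reference,
    rma_cohort,
    simulate_two_lab_study,
)


@pytest.fixture
def toy_layout() -> ChipLayout:
    """Six probes in two probe-sets of three."""
    probes = [f"psA_p{i}" for i in range(3)] + [f"psB_p{i}" for i in range(3)]
    mapping = {p: ("psA" if p.startswith("psA") else "psB") for p in probes}
    return ChipLayout(probe_ids=probes, probe_to_probeset=mapping, chip_id="toy")


@pytest.fixture(scope="session")
def small_study():
    """A small two-laboratory simulation shared across tests.

    20 reference arrays + 20 same-lab and 20 batch-shifted held-out arrays,
    300 probe-sets of 11 probes.
    """
    cfg = SimConfig(n_probesets=300, n_samples=40, batch_shift_sd=0.8, seed=1)
    return simulate_two_lab_study(cfg, n_ref=20)


@pytest.fixture(scope="session")
def small_archive(small_study):
    return build_reference(small_study.reference, small_study.layout)


@pytest.fixture(scope="session")
def small_cohort_expr(small_study):
    """Cohort RMA of reference + same-lab held-out arrays."""
    study = small_study
    combined = ProbeMatrix(
        study.reference.probe_ids,
        study.reference.sample_ids + study.inlab.sample_ids,
        np.hstack([study.reference.intensities, study.inlab.intensities]),
    )
    return rma_cohort(combined, study.layout)


def sample_series(matrix: ProbeMatrix, sample_id: str) -> pd.Series:
    return pd.Series(matrix.column(sample_id), index=matrix.probe_ids, name=sample_id)
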