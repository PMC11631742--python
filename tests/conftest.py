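import numpy as np
import pytest

from sarcogait.cohort_labeling import CohortTable, Label, ParticipantRecord, Sex
from sarcogait.skeleton_processing import JointGraph
from sarcogait.synthetic_data import GaitParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_graph():
    """3-node path graph for brute-force model oracles."""
    return JointGraph(node_names=("a", "b", "c"), edges=((0, 1), (1, 2)), root=0)


def make_cohort(n_sarcopenia: int, n_normal: int) -> CohortTable:
    """Labeled cohort with the requested class counts, alternating sexes."""
    records = []
    for i in range(n_sarcopenia):
        sex = Sex.MALE if i % 2 else Sex.FEMALE
        records.append(ParticipantRecord(f"S{i:03d}", sex, 60 + i % 20,
                                         10.0 + i % 5, Label.SARCOPENIA))
    for i in range(n_normal):
        sex = Sex.MALE if i % 2 else Sex.FEMALE
        records.append(ParticipantRecord(f"N{i:03d}", sex, 40 + i % 30,
                                         30.0 + i % 10, Label.NORMAL))
    return CohortTable(records)


@pytest.fixture
def cohort_20_80():
    return make_cohort(20, 80)


@pytest.fixture
def clean_gait_params():
    """Noise-free, symmetric gait with exactly consistent speed."""
    return GaitParams.from_stride_cadence(
        stride_m=1.2, cadence_spm=90.0, trunk_length_m=0.5,
        noise_sd_m=0.0, asymmetry=0.0, rom_scale=1.0)
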