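import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nhejseq.joints import JointLimits, enumerate_joints
from nhejseq.locus import DsbLocus, ReadLayout

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def make_sim_locus() -> DsbLocus:
    """A 200 bp seeded locus with a CACA overhang planted at the cut."""
    seq = random_sequence(200, seed=0)
    seq = seq[:96] + "CACA" + seq[100:]
    return DsbLocus("simlocus", seq, cut_pos=100, overhang_len=4, amplicon_window=(41, 160))


@pytest.fixture(scope="session")
def sim_locus() -> DsbLocus:
    return make_sim_locus()


@pytest.fixture(scope="session")
def sim_layout() -> ReadLayout:
    return ReadLayout(index_len=6, primer_len=10, read_len=100)


@pytest.fixture(scope="session")
def sim_limits() -> JointLimits:
    return JointLimits(left_max=6, right_max=6, mh_max=4)


@pytest.fixture(scope="session")
def sim_templates(sim_locus, sim_layout, sim_limits):
    return enumerate_joints(sim_locus, sim_layout, sim_limits)


@pytest.fixture
def tiny_locus() -> DsbLocus:
    # left overhang CGTA; religation reconstructs the sequence
    return DsbLocus("toy", "AAAACGTACGTTTT", cut_pos=8, overhang_len=4, amplicon_window=(1, 14))


@pytest.fixture
def ca_locus() -> DsbLocus:
    # overhang CACA supports 2-base slipped annealing (the "+CA" fill-in joint)
    return DsbLocus("ca", "AAAACACAGTTTTT", cut_pos=8, overhang_len=4, amplicon_window=(1, 14))


@pytest.fixture
def medium_locus() -> DsbLocus:
    """60 bp locus with the CACA overhang at t=30; big enough for read templates."""
    seq = random_sequence(60, seed=42)
    seq = seq[:26] + "CACA" + seq[30:]
    return DsbLocus("medium", seq, cut_pos=30, overhang_len=4, amplicon_window=(1, 60))


@pytest.fixture
def medium_layout() -> ReadLayout:
    return ReadLayout(index_len=2, primer_len=0, read_len=42)
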