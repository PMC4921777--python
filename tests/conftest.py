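import random

import numpy as np
import pytest

from cladesig.sequence_io import GroupAssignment, SequenceRecord
from cladesig.synthetic_data import SimConfig, generate_dataset

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(AA) for _ in range(length))


@pytest.fixture(scope="session")
def small_dataset():
    """A scaled-down simulated study shared by the slower tests."""
    cfg = SimConfig(n_ingroup=6, n_outgroup=4, n_families=12, n_csi=4,
                    csi_sizes=[1, 4, 7, 20], n_csp=2, n_noise_proteins=2,
                    family_length=200, seed=11)
    return generate_dataset(cfg)


@pytest.fixture
def two_group_assignment():
    return GroupAssignment(
        groups={"in": {f"IN{i}" for i in range(6)},
                "out": {f"OUT{i}" for i in range(4)}},
        focal_group="in")


def indel_msa(base: str, interval: tuple[int, int], n_in: int = 6,
              n_out: int = 4, pattern: str = "insertion"):
    """Alignment rows where the focal side carries residues in
    ``interval`` (1-based) and the other side is gapped there."""
    lo, hi = interval
    gapped = base[:lo - 1] + "-" * (hi - lo + 1) + base[hi:]
    records = []
    for i in range(n_in):
        seq = base if pattern == "insertion" else gapped
        records.append(SequenceRecord(f"in{i}", f"IN{i}", seq))
    for i in range(n_out):
        seq = gapped if pattern == "insertion" else base
        records.append(SequenceRecord(f"out{i}", f"OUT{i}", seq))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(42)
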