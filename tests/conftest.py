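import numpy as np
import pytest

from genoconv.model import (
    Dataset,
    HardCallMatrix,
    SampleRecord,
    SnpRecord,
)
from genoconv.synthdata import SimSpec, gen_hardcalls, gen_probs


@pytest.fixture
def tiny_dataset():
    """2 SNPs x 3 samples, fully typed, hand-written."""
    snps = [
        SnpRecord("1", "rs1", 0.0, 100, "A", "G"),
        SnpRecord("2", "rs2", 0.0, 200, "C", "T"),
    ]
    samples = [
        SampleRecord("F1", "I1", "0", "0", 1, "2"),
        SampleRecord("F2", "I2", "0", "0", 2, "1"),
        SampleRecord("F3", "I3", "0", "0", 0, "-9"),
    ]
    codes = np.array([[0, 1, 2], [2, -1, 0]], dtype=np.int8)
    return Dataset(snps, samples, HardCallMatrix(codes))


@pytest.fixture
def small_dataset():
    """Seeded synthetic panel: 30 SNPs x 25 samples with some missingness."""
    return gen_hardcalls(SimSpec(seed=7, n_samples=25, n_snps=30, missing_rate=0.05))


@pytest.fixture
def small_prob_dataset(small_dataset):
    return gen_probs(small_dataset, certainty=0.9)
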