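import numpy as np
import pytest

from radqc.containers import MISSING, GenotypeMatrix

GENEPOP_FIXTURE = """two-population three-locus fixture
LocA
LocB
LocC
POP
CHA03_001 ,  0101 0102 0202
CHA03_002 ,  0102 0000 0101
POP
CHA15_001 ,  0202 0101 0102
CHA15_002 ,  0101 0202 0101
"""


@pytest.fixture
def genepop_file(tmp_path):
    path = tmp_path / "fixture.genepop"
    path.write_text(GENEPOP_FIXTURE)
    return path


@pytest.fixture
def growth_csv(tmp_path):
    path = tmp_path / "growth.csv"
    path.write_text(
        "river,year,sex,age,length\n"
        "Takwa,2002,F,11,500\n"
        "Takwa,2016,M,8,390\n"
        "Chalifour,2003,female,12,510\n"
        "Perch,2015,m,6,300\n"
        "Icon,2017,F,9,450\n"
    )
    return path


def two_pop_matrix(calls_a, calls_b, pop_a="A", pop_b="B"):
    """Build a GenotypeMatrix from per-population call arrays."""
    calls_a = np.atleast_2d(np.asarray(calls_a, dtype=np.int8))
    calls_b = np.atleast_2d(np.asarray(calls_b, dtype=np.int8))
    calls = np.vstack([calls_a, calls_b])
    n_loci = calls.shape[1]
    return GenotypeMatrix(
        individual_ids=[f"{pop_a}_{i:03d}" for i in range(len(calls_a))]
        + [f"{pop_b}_{i:03d}" for i in range(len(calls_b))],
        pop_labels=[pop_a] * len(calls_a) + [pop_b] * len(calls_b),
        locus_ids=[f"L{j}" for j in range(n_loci)],
        calls=calls,
    )


@pytest.fixture
def random_matrix():
    """A small random multi-population matrix with some missingness."""
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 3, size=(20, 15)).astype(np.int8)
    calls[rng.random(calls.shape) < 0.1] = MISSING
    return GenotypeMatrix(
        individual_ids=[f"P{k}_{i:02d}" for k in range(2) for i in range(10)],
        pop_labels=["P0"] * 10 + ["P1"] * 10,
        locus_ids=[f"L{j:02d}" for j in range(15)],
        calls=calls,
    )
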