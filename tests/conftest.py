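import numpy as np
import pandas as pd
import pytest

from xspecnorm.thermo import NNParameterTable

BASES = "ACGT"


@pytest.fixture(scope="session")
def nn_table() -> NNParameterTable:
    return NNParameterTable.unified()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20210521)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture()
def small_probes() -> pd.DataFrame:
    """Three target + three control probes with annotation."""
    return pd.DataFrame(
        {
            "probe_id": ["t1", "t2", "t3", "c1", "c2", "c3"],
            "sequence": [
                "ACGTACGTACGTACGTACGTACGTA",
                "GGGGCCCCGGGGCCCCGGGGCCCCG",
                "ATATATATATATATATATATATATA",
                "CAGTCAGTCAGTCAGTCAGTCAGTC",
                "TTGGAACCTTGGAACCTTGGAACCT",
                "GATCGATCGATCGATCGATCGATCG",
            ],
            "chromosome": ["chrI"] * 3 + ["control_set"] * 3,
            "start": [0, 35, 70, 0, 25, 50],
            "category": ["target"] * 3 + ["control"] * 3,
            "control_origin": [None] * 3 + ["plant", "bacterial", "plant"],
            "gene_id": ["gene_a", "gene_a", None, None, None, None],
            "region": ["exon", "exon", "intergenic", None, None, None],
        }
    )
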