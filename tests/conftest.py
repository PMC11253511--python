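import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def design44():
    """Full 2-stage x 3-treatment x 4-replicate design."""
    from dsbquant.proteomics_io import build_design

    return build_design(4)


MAXQUANT_FIXTURE = """\
Protein IDs\tGene names\tReverse\tPotential contaminant\tOnly identified by site\tLFQ intensity A\tLFQ intensity B\tLFQ intensity C
P1\tGEN1\t\t\t\t1000\t0\t1500
P2\tGEN2\t+\t\t\t2000\t3000\t4000
P3\tGEN3\t\t+\t\t0\t0\t512
P4\tGEN4\t\t\t+\t8\t16\t32
P5\tGEN5\t\t\t\t100\t200\t
"""


@pytest.fixture
def maxquant_file(tmp_path):
    path = tmp_path / "proteinGroups.txt"
    path.write_text(MAXQUANT_FIXTURE)
    return path
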