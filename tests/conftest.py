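import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_fasta(tmp_path):
    """Two labelled 41-nt records, one per class."""
    pos = "G" * 20 + "C" + "A" * 20
    neg = "T" * 20 + "C" + "G" * 20
    path = tmp_path / "tiny.fa"
    path.write_text(f">pos1|label=1\n{pos}\n>neg1|label=0\n{neg}\n")
    return path
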