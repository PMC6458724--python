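import numpy as np
import pytest

from rowlcs.rowpar import ExecutionPolicy


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def serial_policy():
    return ExecutionPolicy(workers=1, schedule="static", chunk="auto")


def random_pair(rng, max_len=30, alphabet="ACGT"):
    m, n = (int(v) for v in rng.integers(0, max_len + 1, size=2))
    a = "".join(rng.choice(list(alphabet), size=m)) if m else ""
    b = "".join(rng.choice(list(alphabet), size=n)) if n else ""
    return a, b


@pytest.fixture
def fasta_file(tmp_path):
    def write(content, name="seqs.fa"):
        path = tmp_path / name
        path.write_text(content)
        return path
    return write
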