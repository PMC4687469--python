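import numpy as np
import pytest

from aupdscan.io_formats import read_case_table


@pytest.fixture(scope="session")
def table1_cases():
    """The packaged case table, parsed once per session."""
    return read_case_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(20150731)
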