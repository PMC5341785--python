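import numpy as np
import pandas as pd
import pytest

from clonecall.counts import READ_COLUMNS


def make_reads(rows):
    """Build a read-record table from (sample, frag, mate, start, end, strand, bases)."""
    return pd.DataFrame(rows, columns=READ_COLUMNS)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
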