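import numpy as np
import pandas as pd
import pytest

from glandkit.expression import SAMPLES


@pytest.fixture
def small_library():
    """Hand-built six-sample library with one obvious gene per pattern."""
    rows = [
        # gene, length, s1, s2, s3, s4, s5, s6
        ("all_glands", 1000, 5, 5, 4000, 4100, 3900, 4050),
        ("s5_only", 1000, 10, 10, 8, 6, 4000, 9),
        ("uniform", 1000, 100, 100, 100, 100, 100, 100),
        ("control_high", 1000, 5000, 12, 10, 11, 9, 13),
        ("zeros", 500, 0, 0, 0, 0, 0, 0),
    ]
    return pd.DataFrame(rows, columns=["gene_id", "transcript_length",
                                       *SAMPLES])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
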