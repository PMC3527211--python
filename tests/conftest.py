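import numpy as np
import pandas as pd
import pytest

from invgen import from_sequences


@pytest.fixture
def rng():
    return np.random.default_rng(20121220)


def random_alignment(rng, n=6, L=40, alphabet="ACGTN-", ids=None):
    """Random alignment over the full 6-letter alphabet (test helper)."""
    chars = np.array(list(alphabet))
    seqs = ["".join(rng.choice(chars, size=L)) for _ in range(n)]
    return from_sequences(ids or [f"s{i}" for i in range(n)], seqs)


def meta_frame(sample_ids, arrangements, populations=None, inversion="InX"):
    pops = populations or ["RG"] * len(sample_ids)
    df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "population": pops,
            "arm": "X",
            inversion: arrangements,
        }
    )
    return df.set_index("sample_id", drop=False)
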