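import numpy as np
import pandas as pd
import pytest

from sigsegment import MutationCatalog
from sigsegment.simulate import toy_signature_matrix


@pytest.fixture(scope="session")
def toy3():
    return toy_signature_matrix(3)


@pytest.fixture(scope="session")
def toy4():
    return toy_signature_matrix(4)


def make_catalog(channels, chrom="1", sample="S", spacing=100, start=1000, **extra):
    """Catalog with the given channel sequence at fixed spacing."""
    channels = np.asarray(channels, dtype=int)
    n = len(channels)
    from sigsegment.channels import channel_label

    labels = [channel_label(c) for c in channels]
    df = pd.DataFrame(
        {
            "sample_id": sample,
            "chrom": chrom,
            "pos": start + spacing * np.arange(n),
            "ref": [l[2] for l in labels],
            "alt": [l[4] for l in labels],
            "channel": channels,
        }
    )
    for k, v in extra.items():
        df[k] = v
    return MutationCatalog(df)


@pytest.fixture
def catalog_factory():
    return make_catalog
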