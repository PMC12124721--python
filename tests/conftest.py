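import numpy as np
import pandas as pd
import pytest

from fluoroqspr import compound_library, load_library
from fluoroqspr.descriptor_engine import DescriptorTable


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def library_df(library):
    return compound_library.library_table(library)


@pytest.fixture(scope="session")
def by_id(library):
    return {c.id: c for c in library}


@pytest.fixture()
def small_table():
    """20 compounds x 5 positive descriptor columns, seeded."""
    rng = np.random.default_rng(42)
    ids = [f"c{i:02d}" for i in range(20)]
    df = pd.DataFrame(
        {f"v{j}": rng.uniform(1.0, 10.0, 20) for j in range(5)}, index=ids
    )
    df.index.name = "compound_id"
    return DescriptorTable(df, provenance={c: "dft_ingested" for c in df.columns})
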