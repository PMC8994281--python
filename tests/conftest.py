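import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from minimito import fixtures as packaged  # noqa: E402


@pytest.fixture(scope="session")
def seal_karyotypes():
    return packaged.seal_louse_karyotypes()


@pytest.fixture(scope="session")
def sucking_mrca():
    return packaged.sucking_louse_mrca()


@pytest.fixture(scope="session")
def seal_ancestor(seal_karyotypes, sucking_mrca):
    from minimito.ancestral_inference import infer_ancestral

    return infer_ancestral(
        seal_karyotypes, sucking_mrca, clade="sealice_mrca"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
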