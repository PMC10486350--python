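import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from glutenscan.epitopes import default_motif_list


@pytest.fixture(scope="session")
def motifs():
    return default_motif_list()


@pytest.fixture(scope="session")
def r5_motifs(motifs):
    return [m for m in motifs if m.epitope_class == "R5"]
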