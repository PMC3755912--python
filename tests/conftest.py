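import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/util.py

from birthsize import params, synthdata


@pytest.fixture(scope="session")
def planted_panel():
    """A mid-sized synthetic screen with 5% planted small (x0.75) and 5%
    planted large (x1.3) mutants, parameters already extracted."""
    spec = synthdata.make_planted_spec(n_mutants=200, cells_per_strain=8000)
    records, truth = synthdata.generate_panel(spec, seed=101)
    params.extract_panel(records)
    return spec, records, truth
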