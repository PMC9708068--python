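import numpy as np
import pytest

from cryptlineage import analysis, lineage, synthetic


@pytest.fixture(scope="session")
def fixture_suite():
    return synthetic.make_fixture_suite(seed=0)


@pytest.fixture(scope="session")
def seven_cell_forest(fixture_suite):
    return lineage.build_lineage_forest(fixture_suite["seven_cell"]["tracks"])


@pytest.fixture(scope="session")
def default_crypt():
    """One crypt generated with the default parameters."""
    tracks, axis, truth = synthetic.generate_crypt_tracks(rng=np.random.default_rng(42))
    return {"tracks": tracks, "axis": axis, "truth": truth}


@pytest.fixture(scope="session")
def analyzed_crypt(default_crypt):
    out = analysis.analyze_crypt(default_crypt["tracks"], default_crypt["axis"])
    out["truth"] = default_crypt["truth"]
    out["tracks"] = default_crypt["tracks"]
    out["axis"] = default_crypt["axis"]
    return out
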