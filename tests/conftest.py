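import pytest
from hypothesis import settings

from cocrysol import load_parameter_db

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def db():
    """The packaged nicotinamide/succinic-acid parameter database."""
    return load_parameter_db("packaged")


@pytest.fixture(scope="session")
def cc(db):
    """The packaged NA/SA 2:1 cocrystal definition."""
    return db.cocrystal("NA", "SA")
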