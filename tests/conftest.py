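import numpy as np
import pytest
from hypothesis import settings

from larkszip.fixtures import reference_fixtures
from larkszip.io import ProteinRecord
from larkszip.screen import ScreenConfig
from larkszip.templates import load_builtin_templates

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def templates():
    return {t.name: t for t in load_builtin_templates()}


@pytest.fixture(scope="session")
def zipper(templates):
    return templates["ZIPPER_P1"]


@pytest.fixture(scope="session")
def larks_templates(templates):
    return [templates[n] for n in ("LARKS_STGGYS", "LARKS_SYSGYS", "LARKS_GYNGFG")]


@pytest.fixture(scope="session")
def fixtures():
    return reference_fixtures()


@pytest.fixture(scope="session")
def krt8(fixtures):
    return fixtures.krt8


@pytest.fixture(scope="session")
def krt8_core(krt8):
    """The head-domain core region around the crystallised segments,
    as a standalone record (keeps scans fast)."""
    return ProteinRecord("KRT8", krt8.sequence[45 - 2:70 - 2 + 1],
                         numbering_offset=45)


@pytest.fixture(scope="session")
def config():
    return ScreenConfig.default()


@pytest.fixture(scope="session")
def ideal_beta_table():
    return np.array([[-120.0, 120.0, 180.0]] * 6)
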