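import pytest

from peptarget.itraq_quant import reporter_templates
from peptarget.synthetic_data import load_paper_tables


@pytest.fixture(scope="session")
def paper_tables():
    return load_paper_tables()


@pytest.fixture(scope="session")
def templates():
    return reporter_templates()
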