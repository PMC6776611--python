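import pytest

from odmltab import fixtures
from odmltab.fixtures import GeneratorParams, random_document

DATA_DIR = __import__("pathlib").Path(__file__).parent / "data"


@pytest.fixture
def template_doc():
    return fixtures.build_scoresheet_template()


@pytest.fixture
def subject_pre():
    return fixtures.build_subject_document("pre_enrichment")


@pytest.fixture
def subject_enriched():
    return fixtures.build_subject_document("enriched")


@pytest.fixture
def data_dir():
    return DATA_DIR


def random_docs(n, **overrides):
    """n seeded random documents (deterministic test surface)."""
    return [random_document(GeneratorParams(seed=i, **overrides))
            for i in range(n)]
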