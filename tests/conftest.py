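import pytest

from prfqe.corpus_io import build_index
from prfqe.pipeline import build_term_pool
from prfqe.retrieval import retrieve
from prfqe.synthetic import worked_example_corpus


@pytest.fixture(scope="session")
def worked_bundle():
    """The 10-document burst-illustration corpus."""
    return worked_example_corpus()


@pytest.fixture(scope="session")
def worked_index(worked_bundle):
    return build_index(worked_bundle.documents)


@pytest.fixture(scope="session")
def worked_feedback(worked_bundle, worked_index):
    """Feedback set from blind retrieval at depth 4: exactly D01..D04."""
    topic = worked_bundle.topics[0]
    ranked = retrieve(topic, worked_index, depth=4)
    return set(ranked.doc_ids())


@pytest.fixture(scope="session")
def worked_pool(worked_bundle, worked_index, worked_feedback):
    return build_term_pool(worked_feedback, worked_index, worked_bundle.topics[0])
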