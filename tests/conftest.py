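import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from evalkit import get_task_schema
from evalkit.standoff import AnnotationSet, TextBound, TextSpan


@pytest.fixture(scope="session")
def epi_schema():
    return get_task_schema("epi")


@pytest.fixture(scope="session")
def id_schema():
    return get_task_schema("id")


@pytest.fixture(scope="session")
def rel_schema():
    return get_task_schema("rel")


class DocBuilder:
    """Hand-construct tiny annotation sets word by word for matching tests."""

    def __init__(self, words: list[str], doc_id: str = "d1", id_start: int = 0):
        self.words = words
        self.text = " ".join(words)
        self.spans: list[TextSpan] = []
        offset = 0
        for w in words:
            self.spans.append(TextSpan(offset, offset + len(w)))
            offset += len(w) + 1
        self.ann = AnnotationSet(doc_id=doc_id, text=self.text)
        self._n = id_start

    def tb(self, word_index: int, tb_type: str, *, given: bool = False, n_words: int = 1) -> TextBound:
        self._n += 1
        span = TextSpan(self.spans[word_index].start, self.spans[word_index + n_words - 1].end)
        tb = TextBound(f"T{self._n}", tb_type, span, self.text[span.start : span.end])
        (self.ann.given_entities if given else self.ann.textbounds)[tb.id] = tb
        return tb


@pytest.fixture
def doc_builder():
    return DocBuilder
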