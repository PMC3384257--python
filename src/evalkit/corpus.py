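"""Reading and writing document-per-file standoff corpora.

A gold directory carries ``<docid>.txt`` (text), ``<docid>.a1`` (given
entities) and ``<docid>.a2`` (target annotations) per document; a submission
directory carries ``.a2`` files only — its text and given layer are taken
from the gold corpus it is scored against.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .standoff import AnnotationSet, parse_document, serialize_annotations

__all__ = ["read_corpus", "read_submission", "write_corpus", "write_submission"]


def _read_lines(path: Path) -> list[str]:
    if not path.exists():
        return []
    return path.read_text(encoding="utf-8").splitlines()


def read_corpus(directory, schema=None) -> dict[str, AnnotationSet]:
    """Read every ``<docid>.txt`` (+ ``.a1``/``.a2``) document in a directory."""
    directory = Path(directory)
    corpus: dict[str, AnnotationSet] = {}
    txt_files = sorted(directory.glob("*.txt"))
    if not txt_files:
        raise FileNotFoundError(f"no .txt documents found in {directory}")
    for txt in txt_files:
        doc_id = txt.stem
        text = txt.read_text(encoding="utf-8")
        corpus[doc_id] = parse_document(
            text,
            _read_lines(directory / f"{doc_id}.a1"),
            _read_lines(directory / f"{doc_id}.a2"),
            schema,
            doc_id=doc_id,
        )
    return corpus


def read_submission(directory, gold: Mapping[str, AnnotationSet], schema=None) -> dict[str, AnnotationSet]:
    """Read a submission (``.a2`` only) against a gold corpus.

    Every gold document must have a (possibly empty) ``.a2`` counterpart;
    the text and given-entity layer are shared with the gold corpus.
    """
    directory = Path(directory)
    out: dict[str, AnnotationSet] = {}
    for doc_id in sorted(gold):
        gold_ann = gold[doc_id]
        # present the shared given layer under the gold corpus's own ids so
        # submission references resolve against it
        given_lines = [
            f"{tb.id}\t{tb.type} {tb.span.start} {tb.span.end}\t{tb.text}"
            for tb in gold_ann.given_entities.values()
        ]
        ann = parse_document(
            gold_ann.text,
            given_lines,
            _read_lines(directory / f"{doc_id}.a2"),
            schema,
            doc_id=doc_id,
        )
        ann.equivs = []
        out[doc_id] = ann
    return out


def write_corpus(corpus: Mapping[str, AnnotationSet], directory, *, layers=("txt", "a1", "a2")) -> None:
    """Write a corpus as ``.txt``/``.a1``/``.a2`` files (canonical serialization)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc_id in sorted(corpus):
        ann = corpus[doc_id]
        given_lines, target_lines = serialize_annotations(ann)
        if "txt" in layers:
            (directory / f"{doc_id}.txt").write_text(ann.text, encoding="utf-8")
        if "a1" in layers:
            (directory / f"{doc_id}.a1").write_text("".join(l + "\n" for l in given_lines), encoding="utf-8")
        if "a2" in layers:
            (directory / f"{doc_id}.a2").write_text("".join(l + "\n" for l in target_lines), encoding="utf-8")


def write_submission(corpus: Mapping[str, AnnotationSet], directory) -> None:
    """Write only the ``.a2`` layer (submission format).

    Note: canonical serialization renumbers text-bounds across both layers,
    so submission files written here reference the given entities by their
    canonical ids; read them back with :func:`read_submission` against a
    gold corpus written by :func:`write_corpus`.
    """
    write_corpus(corpus, directory, layers=("a2",))
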