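"""Standoff annotation data model, parser, serializer and validator.

The format is the tab-separated standoff convention used by biomedical
information-extraction shared tasks (and by the brat annotation tool): a
plain-text document plus annotation files in which every annotation is one
line, carries a typed identifier (``T1``, ``E2``, ``M1``, ``R1``), and refers
to the text only through character offsets.

Record grammar (one record per line, fields separated by single tabs)::

    T1<TAB>Protein 0 4<TAB>PhoP              text-bound (entity or trigger)
    E1<TAB>Methylation:T2 Theme:T1 Site:T3   event (TYPE:TRIGGER then ROLE:TARGET*)
    M1<TAB>Negation E1                       event modification flag
    R1<TAB>Protein-Component Arg1:T1 Arg2:T2 binary relation
    *<TAB>Equiv T1 T2 T3                     entity equivalence statement

Offsets are 0-based, end-exclusive character offsets into the document text;
newlines count. Given (task-input) entities live in the ``.a1`` layer and are
kept separate from predicted text-bounds (triggers and ``Entity`` mentions) in
the ``.a2`` layer: the same-type-overlap constraint is enforced within each
layer only, since a predicted trigger may legitimately coincide with a given
entity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

__all__ = [
    "TextSpan",
    "TextBound",
    "EventArgument",
    "Event",
    "Modification",
    "Relation",
    "EquivStatement",
    "AnnotationSet",
    "Violation",
    "StandoffError",
    "StandoffParseError",
    "StandoffReferenceError",
    "StandoffCycleError",
    "StandoffConsistencyError",
    "MODIFICATION_KINDS",
    "normalize_role",
    "parse_document",
    "serialize_annotations",
    "validate_annotations",
]

MODIFICATION_KINDS = ("Negation", "Speculation")

_ROLE_SUFFIX_RE = re.compile(r"\d+$")


def normalize_role(role: str) -> str:
    """Strip a trailing numeric suffix from a role name (``Theme2`` -> ``Theme``).

    Numbered role names are a surface convention for repeated roles; schema
    checks and matching always operate on the normalized name.
    """
    return _ROLE_SUFFIX_RE.sub("", role)


class StandoffError(Exception):
    """Base class for standoff format errors."""


class StandoffParseError(StandoffError):
    def __init__(self, message: str, line_no: int | None = None, line: str | None = None):
        self.line_no = line_no
        self.line = line
        loc = f" (line {line_no})" if line_no is not None else ""
        super().__init__(f"{message}{loc}")


class StandoffReferenceError(StandoffError):
    """An annotation refers to an identifier that does not resolve."""


class StandoffCycleError(StandoffError):
    """The event-to-event reference graph contains a cycle."""


class StandoffConsistencyError(StandoffError):
    """A text-bound's text field disagrees with the document text at its span."""


@dataclass(frozen=True, order=True)
class TextSpan:
    """A contiguous, 0-based, end-exclusive character range."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start},{self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "TextSpan") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "TextSpan") -> bool:
        return self.start < other.end and other.start < self.end

    def crosses(self, other: "TextSpan") -> bool:
        """True if the spans overlap but neither contains the other."""
        return self.overlaps(other) and not self.contains(other) and not other.contains(self)


@dataclass(frozen=True)
class TextBound:
    """A typed text span: a given entity, a predicted entity, or an event trigger."""

    id: str
    type: str
    span: TextSpan
    text: str


@dataclass(frozen=True)
class EventArgument:
    """One event participant: a raw role label and the id of its filler."""

    role: str
    target: str

    @property
    def norm_role(self) -> str:
        return normalize_role(self.role)


@dataclass(frozen=True)
class Event:
    """A typed n-ary association anchored to a trigger text-bound."""

    id: str
    type: str
    trigger: str
    args: tuple[EventArgument, ...] = ()


@dataclass(frozen=True)
class Modification:
    """A binary Negation/Speculation flag attached to one event."""

    id: str
    kind: str
    target: str


@dataclass(frozen=True)
class Relation:
    """A typed binary association of two text-bounds."""

    id: str
    type: str
    arg1: str
    arg2: str


@dataclass(frozen=True)
class EquivStatement:
    """A symmetric, transitive equivalence over given-entity mentions."""

    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("Equiv statement needs at least two members")


@dataclass(frozen=True)
class Violation:
    """One validation finding; violations are data, not exceptions."""

    kind: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.kind}] {self.subject}: {self.message}"


@dataclass
class AnnotationSet:
    """One document's text together with all its standoff annotations.

    ``given_entities`` holds the task-input (``.a1``) layer shared between the
    gold standard and every submission; ``textbounds`` holds predicted
    text-bounds (event triggers and ``Entity`` mentions) from the ``.a2``
    layer.
    """

    doc_id: str
    text: str
    given_entities: dict[str, TextBound] = field(default_factory=dict)
    textbounds: dict[str, TextBound] = field(default_factory=dict)
    events: dict[str, Event] = field(default_factory=dict)
    modifications: list[Modification] = field(default_factory=list)
    relations: dict[str, Relation] = field(default_factory=dict)
    equivs: list[EquivStatement] = field(default_factory=list)

    # -- resolution helpers -------------------------------------------------

    def resolve_textbound(self, ann_id: str) -> TextBound | None:
        return self.given_entities.get(ann_id) or self.textbounds.get(ann_id)

    def resolve(self, ann_id: str) -> TextBound | Event | None:
        return self.resolve_textbound(ann_id) or self.events.get(ann_id)

    def is_given(self, ann_id: str) -> bool:
        return ann_id in self.given_entities

    def all_ids(self) -> Iterator[str]:
        yield from self.given_entities
        yield from self.textbounds
        yield from self.events
        for m in self.modifications:
            yield m.id
        yield from self.relations

    def copy(self) -> "AnnotationSet":
        return AnnotationSet(
            doc_id=self.doc_id,
            text=self.text,
            given_entities=dict(self.given_entities),
            textbounds=dict(self.textbounds),
            events=dict(self.events),
            modifications=list(self.modifications),
            relations=dict(self.relations),
            equivs=list(self.equivs),
        )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _parse_textbound(ann_id: str, body: str, rest: list[str], text: str, line_no: int, line: str) -> TextBound:
    parts = body.split(" ")
    if len(parts) != 3:
        raise StandoffParseError(
            f"text-bound body must be 'TYPE START END', got {body!r}", line_no, line
        )
    tb_type, start_s, end_s = parts
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise StandoffParseError(f"non-integer offsets in {body!r}", line_no, line) from None
    if not (0 <= start < end <= len(text)):
        raise StandoffParseError(
            f"span [{start},{end}) out of bounds for text of length {len(text)}", line_no, line
        )
    if len(rest) != 1:
        raise StandoffParseError("text-bound record needs exactly one text field", line_no, line)
    surface = rest[0]
    if text[start:end] != surface:
        raise StandoffConsistencyError(
            f"{ann_id}: text field {surface!r} != document text "
            f"{text[start:end]!r} at [{start},{end}) (line {line_no})"
        )
    return TextBound(ann_id, tb_type, TextSpan(start, end), surface)


def _parse_event(ann_id: str, body: str, line_no: int, line: str) -> Event:
    fields = body.split(" ")
    head = fields[0]
    if ":" not in head:
        raise StandoffParseError(f"event head must be 'TYPE:TRIGGERID', got {head!r}", line_no, line)
    ev_type, trigger = head.split(":", 1)
    if not ev_type or not trigger:
        raise StandoffParseError(f"malformed event head {head!r}", line_no, line)
    args = []
    for f in fields[1:]:
        if not f:
            continue
        if ":" not in f:
            raise StandoffParseError(f"event argument must be 'ROLE:ID', got {f!r}", line_no, line)
        role, target = f.split(":", 1)
        if not role or not target:
            raise StandoffParseError(f"malformed event argument {f!r}", line_no, line)
        args.append(EventArgument(role, target))
    return Event(ann_id, ev_type, trigger, tuple(args))


def _parse_lines(
    lines: Iterable[str],
    text: str,
    *,
    layer: str,
    line_offset_name: str,
) -> tuple[list[TextBound], list[Event], list[Modification], list[Relation], list[EquivStatement]]:
    textbounds: list[TextBound] = []
    events: list[Event] = []
    modifications: list[Modification] = []
    relations: list[Relation] = []
    equivs: list[EquivStatement] = []

    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) < 2:
            raise StandoffParseError("record needs at least two tab-separated fields", line_no, line)
        ann_id, body, rest = cols[0], cols[1], cols[2:]

        if ann_id == "*":
            parts = body.split(" ")
            if parts[0] != "Equiv":
                raise StandoffParseError(f"unknown '*' record kind {parts[0]!r}", line_no, line)
            members = [p for p in parts[1:] if p]
            if len(members) < 2:
                raise StandoffParseError("Equiv needs at least two members", line_no, line)
            equivs.append(EquivStatement(frozenset(members)))
        elif ann_id.startswith("T"):
            textbounds.append(_parse_textbound(ann_id, body, rest, text, line_no, line))
        elif ann_id.startswith("E"):
            if layer == "given":
                raise StandoffParseError("event records are not allowed in the given layer", line_no, line)
            events.append(_parse_event(ann_id, body, line_no, line))
        elif ann_id.startswith("M"):
            if layer == "given":
                raise StandoffParseError("modification records are not allowed in the given layer", line_no, line)
            parts = body.split(" ")
            if len(parts) != 2:
                raise StandoffParseError(f"modification body must be 'KIND EVENTID', got {body!r}", line_no, line)
            kind, target = parts
            if kind not in MODIFICATION_KINDS:
                raise StandoffParseError(f"unknown modification kind {kind!r}", line_no, line)
            modifications.append(Modification(ann_id, kind, target))
        elif ann_id.startswith("R"):
            if layer == "given":
                raise StandoffParseError("relation records are not allowed in the given layer", line_no, line)
            parts = body.split(" ")
            if len(parts) != 3:
                raise StandoffParseError(
                    f"relation body must be 'TYPE Arg1:ID Arg2:ID', got {body!r}", line_no, line
                )
            rel_type = parts[0]
            endpoints = {}
            for p in parts[1:]:
                if ":" not in p:
                    raise StandoffParseError(f"malformed relation argument {p!r}", line_no, line)
                name, target = p.split(":", 1)
                endpoints[name] = target
            if set(endpoints) != {"Arg1", "Arg2"}:
                raise StandoffParseError("relation arguments must be named Arg1 and Arg2", line_no, line)
            relations.append(Relation(ann_id, rel_type, endpoints["Arg1"], endpoints["Arg2"]))
        else:
            raise StandoffParseError(f"unknown record kind for id {ann_id!r}", line_no, line)

    return textbounds, events, modifications, relations, equivs


def _check_event_acyclicity(events: dict[str, Event]) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    color = {eid: WHITE for eid in events}

    def visit(eid: str) -> None:
        color[eid] = GREY
        for arg in events[eid].args:
            if arg.target in events:
                c = color[arg.target]
                if c == GREY:
                    raise StandoffCycleError(
                        f"event reference cycle through {eid} -> {arg.target}"
                    )
                if c == WHITE:
                    visit(arg.target)
        color[eid] = BLACK

    for eid in events:
        if color[eid] == WHITE:
            visit(eid)


def parse_document(
    text: str,
    given_lines: Iterable[str],
    target_lines: Iterable[str],
    schema=None,
    doc_id: str = "",
) -> AnnotationSet:
    """Parse one document's given (``.a1``) and target (``.a2``) layers.

    Performs full structural validation: offsets in bounds, text fields
    consistent with the document, identifiers unique, all cross-references
    resolved, and the event graph acyclic. Schema-level legality (roles,
    filler categories, mandatory arguments) is checked separately by
    :func:`validate_annotations`.

    Raises :class:`StandoffParseError`, :class:`StandoffReferenceError`,
    :class:`StandoffCycleError` or :class:`StandoffConsistencyError`.
    """
    g_tbs, _, _, _, g_equivs = _parse_lines(given_lines, text, layer="given", line_offset_name="a1")
    t_tbs, events_l, mods_l, rels_l, t_equivs = _parse_lines(
        target_lines, text, layer="target", line_offset_name="a2"
    )

    ann = AnnotationSet(doc_id=doc_id, text=text)
    seen: set[str] = set()
    for tb in g_tbs:
        if tb.id in seen:
            raise StandoffParseError(f"duplicate id {tb.id}")
        seen.add(tb.id)
        ann.given_entities[tb.id] = tb
    for tb in t_tbs:
        if tb.id in seen:
            raise StandoffParseError(f"duplicate id {tb.id}")
        seen.add(tb.id)
        ann.textbounds[tb.id] = tb
    for ev in events_l:
        if ev.id in seen:
            raise StandoffParseError(f"duplicate id {ev.id}")
        seen.add(ev.id)
        ann.events[ev.id] = ev
    # duplicate modification flags of one kind on one event collapse (flags
    # are binary); a repeat is tolerated rather than fatal
    mod_seen: set[tuple[str, str]] = set()
    for m in mods_l:
        if m.id in seen:
            raise StandoffParseError(f"duplicate id {m.id}")
        seen.add(m.id)
        if (m.kind, m.target) in mod_seen:
            continue
        mod_seen.add((m.kind, m.target))
        ann.modifications.append(m)
    for r in rels_l:
        if r.id in seen:
            raise StandoffParseError(f"duplicate id {r.id}")
        seen.add(r.id)
        ann.relations[r.id] = r
    ann.equivs = g_equivs + t_equivs

    # cross-reference resolution
    for ev in ann.events.values():
        if ann.resolve_textbound(ev.trigger) is None:
            raise StandoffReferenceError(f"{ev.id}: trigger {ev.trigger} does not resolve")
        for arg in ev.args:
            if ann.resolve(arg.target) is None:
                raise StandoffReferenceError(
                    f"{ev.id}: argument {arg.role}:{arg.target} does not resolve"
                )
    for m in ann.modifications:
        if m.target not in ann.events:
            raise StandoffReferenceError(f"{m.id}: target {m.target} is not an event")
    for r in ann.relations.values():
        for endpoint in (r.arg1, r.arg2):
            if ann.resolve_textbound(endpoint) is None:
                raise StandoffReferenceError(f"{r.id}: endpoint {endpoint} does not resolve")
    for eq in ann.equivs:
        for member in eq.members:
            if member not in ann.given_entities:
                raise StandoffReferenceError(
                    f"Equiv member {member} is not a given entity"
                )

    _check_event_acyclicity(ann.events)
    return ann


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _tb_sort_key(tb: TextBound) -> tuple:
    return (tb.span.start, tb.span.end, tb.type)


def serialize_annotations(ann: AnnotationSet) -> tuple[list[str], list[str]]:
    """Serialize to canonical ``(.a1 lines, .a2 lines)``.

    Identifiers are renumbered canonically: given T-records sorted by
    (start, end, type) get ``T1..Tk``, predicted T-records continue the
    numbering, then events, modifications and relations in a deterministic
    order, Equiv statements last. Refuses sets with dangling references.
    """
    for ev in ann.events.values():
        if ann.resolve_textbound(ev.trigger) is None:
            raise StandoffReferenceError(f"cannot serialize: {ev.id} trigger dangling")
        for arg in ev.args:
            if ann.resolve(arg.target) is None:
                raise StandoffReferenceError(f"cannot serialize: {ev.id} argument {arg.target} dangling")
    for m in ann.modifications:
        if m.target not in ann.events:
            raise StandoffReferenceError(f"cannot serialize: {m.id} target dangling")
    for r in ann.relations.values():
        if ann.resolve_textbound(r.arg1) is None or ann.resolve_textbound(r.arg2) is None:
            raise StandoffReferenceError(f"cannot serialize: {r.id} endpoint dangling")

    id_map: dict[str, str] = {}
    t_counter = 0
    given_sorted = sorted(ann.given_entities.values(), key=_tb_sort_key)
    pred_sorted = sorted(ann.textbounds.values(), key=_tb_sort_key)
    for tb in given_sorted + pred_sorted:
        t_counter += 1
        id_map[tb.id] = f"T{t_counter}"

    # events in a stable order: topological (arguments before the events that
    # use them), ties broken by trigger position then old id
    order: list[Event] = []
    placed: set[str] = set()

    def place(ev: Event) -> None:
        if ev.id in placed:
            return
        placed.add(ev.id)
        for arg in ev.args:
            if arg.target in ann.events:
                place(ann.events[arg.target])
        order.append(ev)

    def ev_key(ev: Event) -> tuple:
        trig = ann.resolve_textbound(ev.trigger)
        return (trig.span.start, trig.span.end, ev.type, ev.id)

    for ev in sorted(ann.events.values(), key=ev_key):
        place(ev)
    for i, ev in enumerate(order, start=1):
        id_map[ev.id] = f"E{i}"

    given_lines = [
        f"{id_map[tb.id]}\t{tb.type} {tb.span.start} {tb.span.end}\t{tb.text}"
        for tb in given_sorted
    ]
    target_lines = [
        f"{id_map[tb.id]}\t{tb.type} {tb.span.start} {tb.span.end}\t{tb.text}"
        for tb in pred_sorted
    ]
    for ev in order:
        head = f"{ev.type}:{id_map[ev.trigger]}"
        parts = [f"{arg.role}:{id_map[arg.target]}" for arg in ev.args]
        target_lines.append(f"{id_map[ev.id]}\t" + " ".join([head] + parts))
    mods_sorted = sorted(ann.modifications, key=lambda m: (id_map[m.target], m.kind))
    for i, m in enumerate(mods_sorted, start=1):
        target_lines.append(f"M{i}\t{m.kind} {id_map[m.target]}")
    rels_sorted = sorted(
        ann.relations.values(), key=lambda r: (r.type, id_map[r.arg1], id_map[r.arg2])
    )
    for i, r in enumerate(rels_sorted, start=1):
        target_lines.append(f"R{i}\t{r.type} Arg1:{id_map[r.arg1]} Arg2:{id_map[r.arg2]}")
    for eq in sorted(ann.equivs, key=lambda e: sorted(id_map[m] for m in e.members)):
        members = " ".join(sorted((id_map[m] for m in eq.members), key=lambda s: int(s[1:])))
        target_lines.append(f"*\tEquiv {members}")
    return given_lines, target_lines


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _layer_violations(layer: dict[str, TextBound], layer_name: str, text_len: int) -> list[Violation]:
    out: list[Violation] = []
    tbs = sorted(layer.values(), key=_tb_sort_key)
    for tb in tbs:
        if tb.span.end > text_len:
            out.append(Violation("offset-bounds", tb.id, f"span [{tb.span.start},{tb.span.end}) exceeds text length {text_len}"))
    for i, a in enumerate(tbs):
        for b in tbs[i + 1 :]:
            if b.span.start >= a.span.end:
                break
            if a.span.overlaps(b.span):
                if a.type == b.type:
                    out.append(
                        Violation(
                            "same-type-overlap",
                            f"{a.id}/{b.id}",
                            f"two {a.type} {layer_name} text-bounds overlap",
                        )
                    )
                if a.span.crosses(b.span):
                    out.append(
                        Violation("span-crossing", f"{a.id}/{b.id}", "overlapping spans cross")
                    )
    return out


def validate_annotations(ann: AnnotationSet, schema=None) -> list[Violation]:
    """Return every rule violation in ``ann`` (empty list means valid).

    Structural rules (same-type overlap within a layer, span crossing, offset
    bounds, reference resolution, acyclicity) are always checked; if a task
    schema is given, role legality, filler categories, mandatory-argument
    presence and repeatability are checked too.
    """
    out: list[Violation] = []
    out += _layer_violations(ann.given_entities, "given", len(ann.text))
    out += _layer_violations(ann.textbounds, "predicted", len(ann.text))

    for tb in list(ann.given_entities.values()) + list(ann.textbounds.values()):
        if ann.text[tb.span.start : tb.span.end] != tb.text:
            out.append(Violation("text-mismatch", tb.id, "text field differs from document text"))

    for ev in ann.events.values():
        if ann.resolve_textbound(ev.trigger) is None:
            out.append(Violation("dangling-reference", ev.id, f"trigger {ev.trigger} unresolved"))
        for arg in ev.args:
            if ann.resolve(arg.target) is None:
                out.append(Violation("dangling-reference", ev.id, f"argument {arg.role}:{arg.target} unresolved"))
    for m in ann.modifications:
        if m.target not in ann.events:
            out.append(Violation("dangling-reference", m.id, f"target {m.target} unresolved"))
        if m.kind not in MODIFICATION_KINDS:
            out.append(Violation("unknown-modification", m.id, f"kind {m.kind!r}"))
    for r in ann.relations.values():
        for endpoint in (r.arg1, r.arg2):
            if ann.resolve_textbound(endpoint) is None:
                out.append(Violation("dangling-reference", r.id, f"endpoint {endpoint} unresolved"))
    for eq in ann.equivs:
        for member in eq.members:
            if member not in ann.given_entities:
                out.append(Violation("dangling-reference", "*", f"Equiv member {member} is not a given entity"))

    try:
        _check_event_acyclicity(ann.events)
    except StandoffCycleError as exc:
        out.append(Violation("event-cycle", "events", str(exc)))

    if schema is not None:
        from .schemas import validate_event_schema, validate_relation_schema

        for ev in ann.events.values():
            out += validate_event_schema(schema, ev, ann)
        for r in ann.relations.values():
            out += validate_relation_schema(schema, r, ann)

    return out
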