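"""Task schemas: event/relation type inventories and argument legality.

Three built-in schemas are provided:

``epi``
    Protein and DNA modification events: 14 modification types (seven
    addition reactions and their reversals) plus ``Catalysis``, which takes a
    modification event as its ``Theme`` and the catalysing ``Protein`` as its
    ``Cause`` (both mandatory). Modification events take a mandatory
    ``Theme(Protein)`` and optional additional ``Site``/``Sidechain``/
    ``Contextgene`` arguments depending on the type.

``id``
    Infectious-disease molecular mechanisms: ten event types over five given
    core entity types (``Protein``, ``Two-component-system``,
    ``Regulon-operon``, ``Chemical``, ``Organism``), including the high-level
    ``Process`` type which has no mandatory arguments, and three regulation
    types that can take events as ``Theme``/``Cause`` (nesting).

``rel``
    Entity part-of relations: ``Protein-Component`` (a gene/protein and its
    part — domain, region, promoter, residue) and ``Subunit-Complex`` (a
    protein and the complex it is a subunit of). One endpoint is always a
    given ``Protein``; the other is a predicted ``Entity`` mention.

Argument filler categories are given-entity type names, ``Entity`` (a
predicted secondary entity), ``Event`` (an event filler), or the generic
``Core entity`` which resolves to any of the schema's given entity types.
Schemas can be exported to and loaded from YAML so the evaluation engine can
be reused for new task configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .standoff import AnnotationSet, Event, Relation, TextBound, Violation, normalize_role

__all__ = [
    "ArgumentSpec",
    "EventTypeSpec",
    "TaskSchema",
    "get_task_schema",
    "classify_argument",
    "validate_event_schema",
    "validate_relation_schema",
    "load_schema",
    "dump_schema",
    "TASKS",
]

CORE_ENTITY = "Core entity"
EVENT_FILLER = "Event"


@dataclass(frozen=True)
class ArgumentSpec:
    """Legality of one argument role for one event type."""

    role: str
    fillers: frozenset[str]
    mandatory: bool = False
    repeatable: bool = False
    core: bool = True

    def __post_init__(self) -> None:
        if self.mandatory and not self.core:
            raise ValueError(f"{self.role}: mandatory arguments must be core")


@dataclass(frozen=True)
class EventTypeSpec:
    name: str
    args: tuple[ArgumentSpec, ...]

    def __post_init__(self) -> None:
        roles = [a.role for a in self.args]
        if len(roles) != len(set(roles)):
            raise ValueError(f"{self.name}: duplicate role specs")

    def spec_for(self, role: str) -> ArgumentSpec | None:
        norm = normalize_role(role)
        for a in self.args:
            if a.role == norm:
                return a
        return None


@dataclass(frozen=True)
class TaskSchema:
    task: str
    event_types: Mapping[str, EventTypeSpec]
    relation_types: tuple[str, ...] = ()
    given_entity_types: tuple[str, ...] = ("Protein",)
    modification_kinds: tuple[str, ...] = ()
    type_groups: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def resolve_fillers(self, fillers: frozenset[str]) -> frozenset[str]:
        """Expand the generic ``Core entity`` category to concrete types."""
        if CORE_ENTITY in fillers:
            return (fillers - {CORE_ENTITY}) | frozenset(self.given_entity_types)
        return fillers


def _theme_site(*extra: ArgumentSpec) -> tuple[ArgumentSpec, ...]:
    return (
        ArgumentSpec("Theme", frozenset({"Protein"}), mandatory=True),
        ArgumentSpec("Site", frozenset({"Entity"}), core=False),
    ) + extra


_SIDECHAIN = ArgumentSpec("Sidechain", frozenset({"Entity"}), core=False)
_CONTEXTGENE = ArgumentSpec("Contextgene", frozenset({"Protein"}), core=False)

_EPI_SIMPLE = (
    "Hydroxylation",
    "Dehydroxylation",
    "Phosphorylation",
    "Dephosphorylation",
    "Ubiquitination",
    "Deubiquitination",
    "DNA_methylation",
    "DNA_demethylation",
)
_EPI_SIDECHAIN = ("Glycosylation", "Deglycosylation")
_EPI_CONTEXTGENE = ("Acetylation", "Deacetylation", "Methylation", "Demethylation")

_EPI_ADDITION = (
    "Hydroxylation",
    "Phosphorylation",
    "Ubiquitination",
    "DNA_methylation",
    "Glycosylation",
    "Acetylation",
    "Methylation",
)
_EPI_REMOVAL = (
    "Dehydroxylation",
    "Dephosphorylation",
    "Deubiquitination",
    "DNA_demethylation",
    "Deglycosylation",
    "Deacetylation",
    "Demethylation",
)


def _build_epi() -> TaskSchema:
    types: dict[str, EventTypeSpec] = {}
    for name in _EPI_SIMPLE:
        types[name] = EventTypeSpec(name, _theme_site())
    for name in _EPI_SIDECHAIN:
        types[name] = EventTypeSpec(name, _theme_site(_SIDECHAIN))
    for name in _EPI_CONTEXTGENE:
        types[name] = EventTypeSpec(name, _theme_site(_CONTEXTGENE))
    types["Catalysis"] = EventTypeSpec(
        "Catalysis",
        (
            ArgumentSpec("Theme", frozenset({EVENT_FILLER}), mandatory=True),
            ArgumentSpec("Cause", frozenset({"Protein"}), mandatory=True),
        ),
    )
    groups = {
        "simple": _EPI_SIMPLE,
        "non-simple": _EPI_SIDECHAIN + _EPI_CONTEXTGENE,
        "addition": _EPI_ADDITION,
        "removal": _EPI_REMOVAL,
        "modification": ("Negation", "Speculation"),
    }
    return TaskSchema(
        task="epi",
        event_types=types,
        given_entity_types=("Protein",),
        modification_kinds=("Negation", "Speculation"),
        type_groups=groups,
    )


_ID_SIMPLE = (
    "Gene_expression",
    "Transcription",
    "Protein_catabolism",
    "Phosphorylation",
    "Localization",
)
_ID_REGULATION = ("Regulation", "Positive_regulation", "Negative_regulation")


def _build_id() -> TaskSchema:
    expr_theme = ArgumentSpec("Theme", frozenset({"Protein", "Regulon-operon"}), mandatory=True)
    types: dict[str, EventTypeSpec] = {
        "Gene_expression": EventTypeSpec("Gene_expression", (expr_theme,)),
        "Transcription": EventTypeSpec("Transcription", (expr_theme,)),
        "Protein_catabolism": EventTypeSpec(
            "Protein_catabolism",
            (ArgumentSpec("Theme", frozenset({"Protein"}), mandatory=True),),
        ),
        "Phosphorylation": EventTypeSpec(
            "Phosphorylation",
            (
                ArgumentSpec("Theme", frozenset({"Protein"}), mandatory=True),
                ArgumentSpec("Site", frozenset({"Entity"}), core=False),
            ),
        ),
        "Localization": EventTypeSpec(
            "Localization",
            (
                ArgumentSpec("Theme", frozenset({CORE_ENTITY}), mandatory=True),
                ArgumentSpec("AtLoc", frozenset({"Entity"}), core=False),
                ArgumentSpec("ToLoc", frozenset({"Entity"}), core=False),
            ),
        ),
        "Binding": EventTypeSpec(
            "Binding",
            (
                ArgumentSpec("Theme", frozenset({CORE_ENTITY}), mandatory=True, repeatable=True),
                ArgumentSpec("Site", frozenset({"Entity"}), core=False, repeatable=True),
            ),
        ),
        "Process": EventTypeSpec(
            "Process",
            (ArgumentSpec("Participant", frozenset({CORE_ENTITY}), repeatable=True),),
        ),
    }
    for name in _ID_REGULATION:
        types[name] = EventTypeSpec(
            name,
            (
                ArgumentSpec("Theme", frozenset({CORE_ENTITY, EVENT_FILLER}), mandatory=True),
                ArgumentSpec("Cause", frozenset({CORE_ENTITY, EVENT_FILLER})),
                ArgumentSpec("Site", frozenset({"Entity"}), core=False),
                ArgumentSpec("CSite", frozenset({"Entity"}), core=False),
            ),
        )
    groups = {
        "simple": _ID_SIMPLE,
        "non-regulation": _ID_SIMPLE + ("Binding", "Process"),
        "regulation": _ID_REGULATION,
        "modification": ("Negation", "Speculation"),
    }
    return TaskSchema(
        task="id",
        event_types=types,
        given_entity_types=(
            "Protein",
            "Two-component-system",
            "Regulon-operon",
            "Chemical",
            "Organism",
        ),
        modification_kinds=("Negation", "Speculation"),
        type_groups=groups,
    )


def _build_rel() -> TaskSchema:
    return TaskSchema(
        task="rel",
        event_types={},
        relation_types=("Protein-Component", "Subunit-Complex"),
        given_entity_types=("Protein",),
        modification_kinds=(),
        type_groups={},
    )


_BUILTIN = {"epi": _build_epi, "id": _build_id, "rel": _build_rel}
TASKS = tuple(_BUILTIN)


def get_task_schema(task: str) -> TaskSchema:
    """Return the built-in schema for ``task`` (one of ``epi``/``id``/``rel``)."""
    try:
        builder = _BUILTIN[task]
    except KeyError:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(_BUILTIN)}") from None
    return builder()


def classify_argument(schema: TaskSchema, event_type: str, role: str) -> str:
    """Classify a (type, role) pair as ``"core"`` or ``"additional"``."""
    try:
        type_spec = schema.event_types[event_type]
    except KeyError:
        raise ValueError(f"unknown event type {event_type!r} for task {schema.task!r}") from None
    arg_spec = type_spec.spec_for(role)
    if arg_spec is None:
        raise ValueError(f"role {role!r} is not defined for {event_type}")
    return "core" if arg_spec.core else "additional"


def validate_event_schema(schema: TaskSchema, event: Event, ann: AnnotationSet) -> list[Violation]:
    """Check one event's schema legality; violations are returned, not raised."""
    out: list[Violation] = []
    type_spec = schema.event_types.get(event.type)
    if type_spec is None:
        out.append(Violation("unknown-event-type", event.id, f"type {event.type!r} not in {schema.task} schema"))
        return out

    counts: dict[str, int] = {}
    for arg in event.args:
        spec = type_spec.spec_for(arg.role)
        if spec is None:
            out.append(Violation("illegal-role", event.id, f"role {arg.role!r} not allowed for {event.type}"))
            continue
        counts[spec.role] = counts.get(spec.role, 0) + 1
        target = ann.resolve(arg.target)
        allowed = schema.resolve_fillers(spec.fillers)
        if isinstance(target, Event):
            if EVENT_FILLER not in spec.fillers:
                out.append(
                    Violation("illegal-filler", event.id, f"{arg.role} of {event.type} cannot take an event")
                )
        elif isinstance(target, TextBound):
            if target.type not in allowed:
                out.append(
                    Violation(
                        "illegal-filler",
                        event.id,
                        f"{arg.role} of {event.type} cannot take a {target.type}",
                    )
                )
        else:
            out.append(Violation("dangling-reference", event.id, f"{arg.role}:{arg.target} unresolved"))

    for spec in type_spec.args:
        n = counts.get(spec.role, 0)
        if spec.mandatory and n == 0:
            out.append(Violation("missing-mandatory-argument", event.id, f"{event.type} requires {spec.role}"))
        if n > 1 and not spec.repeatable:
            out.append(Violation("non-repeatable-role", event.id, f"{spec.role} repeated on {event.type}"))
    return out


def validate_relation_schema(schema: TaskSchema, rel: Relation, ann: AnnotationSet) -> list[Violation]:
    out: list[Violation] = []
    if rel.type not in schema.relation_types:
        out.append(Violation("unknown-relation-type", rel.id, f"type {rel.type!r} not in {schema.task} schema"))
        return out
    a1 = ann.resolve_textbound(rel.arg1)
    a2 = ann.resolve_textbound(rel.arg2)
    if a1 is not None and a1.type not in schema.given_entity_types:
        out.append(Violation("illegal-filler", rel.id, f"Arg1 must be a given entity, got {a1.type}"))
    if a2 is not None and a2.type != "Entity":
        out.append(Violation("illegal-filler", rel.id, f"Arg2 must be an Entity mention, got {a2.type}"))
    return out


# ---------------------------------------------------------------------------
# YAML export / import
# ---------------------------------------------------------------------------


def _schema_to_dict(schema: TaskSchema) -> dict:
    return {
        "task": schema.task,
        "given_entity_types": list(schema.given_entity_types),
        "modification_kinds": list(schema.modification_kinds),
        "relation_types": list(schema.relation_types),
        "event_types": {
            name: [
                {
                    "role": a.role,
                    "fillers": sorted(a.fillers),
                    "mandatory": a.mandatory,
                    "repeatable": a.repeatable,
                    "core": a.core,
                }
                for a in spec.args
            ]
            for name, spec in schema.event_types.items()
        },
        "type_groups": {k: list(v) for k, v in schema.type_groups.items()},
    }


def _schema_from_dict(data: dict) -> TaskSchema:
    required = {"task", "event_types"}
    missing = required - set(data)
    if missing:
        raise ValueError(f"schema config missing keys: {sorted(missing)}")
    event_types = {}
    for name, args in data["event_types"].items():
        specs = tuple(
            ArgumentSpec(
                role=a["role"],
                fillers=frozenset(a["fillers"]),
                mandatory=bool(a.get("mandatory", False)),
                repeatable=bool(a.get("repeatable", False)),
                core=bool(a.get("core", True)),
            )
            for a in args
        )
        event_types[name] = EventTypeSpec(name, specs)
    return TaskSchema(
        task=data["task"],
        event_types=event_types,
        relation_types=tuple(data.get("relation_types", ())),
        given_entity_types=tuple(data.get("given_entity_types", ("Protein",))),
        modification_kinds=tuple(data.get("modification_kinds", ())),
        type_groups={k: tuple(v) for k, v in data.get("type_groups", {}).items()},
    )


def dump_schema(schema: TaskSchema, path) -> None:
    """Write a schema as a YAML config file."""
    with open(path, "w") as fh:
        yaml.safe_dump(_schema_to_dict(schema), fh, sort_keys=False)


def load_schema(path) -> TaskSchema:
    """Load a schema from a YAML config file written by :func:`dump_schema`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("schema config must be a mapping")
    return _schema_from_dict(data)
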