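"""Synthetic gold corpora and controlled error injection.

The generator emits schema-valid annotation sets over pseudo-text: documents
are sequences of space-separated synthetic tokens, with every entity mention
and event trigger occupying its own whole token and at least one filler
token separating consecutive annotation-bearing tokens (so that the one-word
span extension of any annotation never accidentally absorbs a neighbouring
one). Realism is structural, not lexical: nested regulation/catalysis
events, multi-Theme bindings, participant-less processes, Negation and
Speculation flags, Equiv aliases and part-of relations are all generated,
but the tokens themselves carry no meaning — the evaluator never interprets
text beyond offsets and whitespace words.

Default event-type sampling weights are proportional to the type frequencies
of the reference task corpora, so a generated corpus has the same skew (many
expression/process/ubiquitination events, very few reverse reactions) as the
data the evaluation machinery is normally applied to.

The perturbation engine corrupts a gold corpus into a synthetic "submission"
with independent error operators (dropped/added events, dropped/added
arguments, whole-word trigger shifts, type swaps, modification flips) and
records every edit in a manifest, so the exact expected scores of the
corrupted submission are computable from the manifest alone.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np

from .schemas import CORE_ENTITY, EVENT_FILLER, ArgumentSpec, TaskSchema, classify_argument
from .standoff import (
    AnnotationSet,
    EquivStatement,
    Event,
    EventArgument,
    Modification,
    Relation,
    TextBound,
    TextSpan,
)

__all__ = [
    "CorpusProfile",
    "PerturbationProfile",
    "Edit",
    "generate_corpus",
    "perturb_annotations",
    "sample_event_subset",
    "DEFAULT_TYPE_WEIGHTS",
]

# Event-type sampling weights proportional to reference corpus frequencies.
DEFAULT_TYPE_WEIGHTS: dict[str, dict[str, float]] = {
    "epi": {
        "Hydroxylation": 139,
        "Dehydroxylation": 1,
        "Phosphorylation": 130,
        "Dephosphorylation": 3,
        "Ubiquitination": 340,
        "Deubiquitination": 17,
        "DNA_methylation": 416,
        "DNA_demethylation": 21,
        "Glycosylation": 347,
        "Deglycosylation": 27,
        "Acetylation": 337,
        "Deacetylation": 50,
        "Methylation": 374,
        "Demethylation": 13,
        "Catalysis": 238,
    },
    "id": {
        "Gene_expression": 512,
        "Transcription": 77,
        "Protein_catabolism": 33,
        "Phosphorylation": 69,
        "Localization": 49,
        "Binding": 156,
        "Process": 901,
        "Regulation": 267,
        "Positive_regulation": 455,
        "Negative_regulation": 260,
    },
    "rel": {
        "Protein-Component": 1950,
        "Subunit-Complex": 884,
    },
}

_MAX_NESTING_DEPTH = 3


@dataclass(frozen=True)
class CorpusProfile:
    """Generation settings for one synthetic gold corpus.

    ``events_per_doc`` is a Poisson mean (clipped to at least one event per
    document so every document contributes to scoring);
    ``relations_per_doc`` plays the same role for relation tasks.
    ``nesting_prob`` is the probability that an argument slot which may take
    an event filler actually does; mandatory event slots (catalysis themes)
    always nest. ``equiv_rate`` is the per-protein probability of an alias
    mention tied in by an Equiv statement. ``modification_rate`` is the
    per-event, per-kind probability of a Negation/Speculation flag.
    """

    documents: int = 20
    events_per_doc: float = 8.0
    relations_per_doc: float = 6.0
    type_weights: Mapping[str, float] | None = None
    nesting_prob: float = 0.35
    equiv_rate: float = 0.10
    modification_rate: float = 0.04
    optional_core_prob: float = 0.40
    additional_arg_prob: float = 0.20
    repeat_arg_prob: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "nesting_prob",
            "equiv_rate",
            "modification_rate",
            "optional_core_prob",
            "additional_arg_prob",
            "repeat_arg_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.documents < 0:
            raise ValueError("documents must be >= 0")
        if self.type_weights is not None and any(w < 0 for w in self.type_weights.values()):
            raise ValueError("type weights must be non-negative")


class _DocBuilder:
    """Accumulates a token stream and hands out text-bound annotations."""

    def __init__(self, doc_id: str, rng: np.random.Generator):
        self.doc_id = doc_id
        self.rng = rng
        self.tokens: list[str] = []
        self.offset = 0
        self.ann = AnnotationSet(doc_id=doc_id, text="")
        self._counters: dict[str, int] = {}
        self._filler = 0

    def _next_id(self, prefix: str) -> str:
        self._counters[prefix] = self._counters.get(prefix, 0) + 1
        return f"{prefix}{self._counters[prefix]}"

    def add_token(self, token: str) -> TextSpan:
        start = self.offset if not self.tokens else self.offset + 1
        self.tokens.append(token)
        self.offset = start + len(token)
        return TextSpan(start, start + len(token))

    def add_fillers(self, lo: int = 1, hi: int = 3) -> None:
        for _ in range(int(self.rng.integers(lo, hi + 1))):
            self._filler += 1
            self.add_token(f"tok{self._filler}")

    def add_textbound(self, tb_type: str, surface: str, *, given: bool) -> TextBound:
        self.add_fillers()
        span = self.add_token(surface)
        tb = TextBound(self._next_id("T"), tb_type, span, surface)
        if given:
            self.ann.given_entities[tb.id] = tb
        else:
            self.ann.textbounds[tb.id] = tb
        return tb

    def finish(self) -> AnnotationSet:
        self.add_fillers()
        self.ann.text = " ".join(self.tokens)
        return self.ann


class _EventFactory:
    def __init__(self, builder: _DocBuilder, schema: TaskSchema, profile: CorpusProfile):
        self.b = builder
        self.schema = schema
        self.profile = profile
        self.rng = builder.rng
        self._entity_seq = 0
        # types usable as nested (recursively generated) events: anything
        # that does not itself demand an event filler
        self.leaf_types = [
            name
            for name, spec in schema.event_types.items()
            if not any(a.mandatory and a.fillers == frozenset({EVENT_FILLER}) for a in spec.args)
        ]
        weights = dict(profile.type_weights or DEFAULT_TYPE_WEIGHTS.get(schema.task, {}))
        if not weights:
            weights = {name: 1.0 for name in schema.event_types}
        unknown = set(weights) - set(schema.event_types)
        if unknown:
            raise ValueError(f"type weights name unknown event types: {sorted(unknown)}")
        self.type_names = [t for t, w in weights.items() if w > 0]
        total = sum(weights[t] for t in self.type_names)
        self.type_probs = [weights[t] / total for t in self.type_names]

    def sample_type(self, leaf_only: bool = False) -> str:
        if leaf_only:
            names = [t for t in self.type_names if t in self.leaf_types]
            if not names:
                names = self.leaf_types
            probs = np.ones(len(names)) / len(names)
            return names[int(self.rng.choice(len(names), p=probs))]
        return self.type_names[int(self.rng.choice(len(self.type_names), p=self.type_probs))]

    def get_entity(self, allowed_types: frozenset[str]) -> TextBound:
        concrete = sorted(self.schema.resolve_fillers(allowed_types) - {EVENT_FILLER})
        if "Entity" in concrete and len(concrete) == 1:
            self._entity_seq += 1
            return self.b.add_textbound("Entity", f"ENT{self._entity_seq}", given=False)
        given_types = [t for t in concrete if t in self.schema.given_entity_types]
        pool = [tb for tb in self.b.ann.given_entities.values() if tb.type in given_types]
        # reuse an existing mention half the time so events share participants
        if pool and self.rng.random() < 0.5:
            return pool[int(self.rng.integers(len(pool)))]
        etype = given_types[int(self.rng.integers(len(given_types)))]
        self._entity_seq += 1
        surface = f"{etype[:4].upper()}{self._entity_seq}"
        return self.b.add_textbound(etype, surface, given=True)

    def _fill_slot(self, spec: ArgumentSpec, depth: int) -> str:
        can_event = EVENT_FILLER in spec.fillers
        must_event = spec.fillers == frozenset({EVENT_FILLER})
        if can_event and (
            must_event or (depth < _MAX_NESTING_DEPTH and self.rng.random() < self.profile.nesting_prob)
        ):
            leaf_only = depth + 1 >= _MAX_NESTING_DEPTH
            child = self.make_event(self.sample_type(leaf_only=leaf_only or must_event), depth + 1)
            return child.id
        return self.get_entity(spec.fillers).id

    def make_event(self, ev_type: str, depth: int = 0) -> Event:
        spec = self.schema.event_types[ev_type]
        trigger = self.b.add_textbound(ev_type, f"{ev_type.lower()[:6]}{self.b._next_id('trg')[3:]}", given=False)
        args: list[EventArgument] = []
        for arg_spec in spec.args:
            if arg_spec.mandatory:
                wanted = 1
            elif arg_spec.core:
                wanted = 1 if self.rng.random() < self.profile.optional_core_prob else 0
            else:
                wanted = 1 if self.rng.random() < self.profile.additional_arg_prob else 0
            if wanted and arg_spec.repeatable and self.rng.random() < self.profile.repeat_arg_prob:
                wanted += 1
            for i in range(wanted):
                role = arg_spec.role if i == 0 else f"{arg_spec.role}{i + 1}"
                args.append(EventArgument(role, self._fill_slot(arg_spec, depth)))
        event = Event(self.b._next_id("E"), ev_type, trigger.id, tuple(args))
        self.b.ann.events[event.id] = event
        return event


def _spawn_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def generate_corpus(schema: TaskSchema, profile: CorpusProfile) -> dict[str, AnnotationSet]:
    """Generate a schema-valid synthetic gold corpus.

    Returns a mapping from document id to annotation set; identical profiles
    produce byte-identical serialized corpora. Raises for infeasible
    profiles (e.g. nesting requested when no event type of the schema can
    take an event filler).
    """
    if schema.event_types and profile.nesting_prob > 0:
        if not any(
            EVENT_FILLER in a.fillers for spec in schema.event_types.values() for a in spec.args
        ):
            raise ValueError("nesting requested but no event type of this schema takes event fillers")

    corpus: dict[str, AnnotationSet] = {}
    for doc_index in range(profile.documents):
        rng = _spawn_rng(profile.seed, doc_index)
        doc_id = f"doc-{doc_index:04d}"
        builder = _DocBuilder(doc_id, rng)

        if schema.event_types:
            factory = _EventFactory(builder, schema, profile)
            n_events = max(1, int(rng.poisson(profile.events_per_doc)))
            while len(builder.ann.events) < n_events:
                factory.make_event(factory.sample_type())
            _attach_modifications(builder.ann, schema, profile, rng)
        if schema.relation_types:
            _generate_relations(builder, schema, profile, rng)
        _attach_equiv_aliases(builder, profile, rng)
        corpus[doc_id] = builder.finish()
    return corpus


def _attach_modifications(
    ann: AnnotationSet, schema: TaskSchema, profile: CorpusProfile, rng: np.random.Generator
) -> None:
    counter = 0
    for eid in sorted(ann.events):
        for kind in schema.modification_kinds:
            if rng.random() < profile.modification_rate:
                counter += 1
                ann.modifications.append(Modification(f"M{counter}", kind, eid))


def _generate_relations(
    builder: _DocBuilder, schema: TaskSchema, profile: CorpusProfile, rng: np.random.Generator
) -> None:
    weights = dict(profile.type_weights or DEFAULT_TYPE_WEIGHTS.get(schema.task, {}))
    names = [t for t in schema.relation_types if weights.get(t, 1.0) > 0]
    probs = np.array([weights.get(t, 1.0) for t in names], dtype=float)
    probs /= probs.sum()
    n_rel = max(1, int(rng.poisson(profile.relations_per_doc)))
    for i in range(1, n_rel + 1):
        rel_type = names[int(rng.choice(len(names), p=probs))]
        # one endpoint is always a gene/protein named entity
        protein = builder.add_textbound("Protein", f"PROT{i}", given=True)
        part = builder.add_textbound("Entity", f"part{i}", given=False)
        builder.ann.relations[f"R{i}"] = Relation(f"R{i}", rel_type, protein.id, part.id)


def _attach_equiv_aliases(builder: _DocBuilder, profile: CorpusProfile, rng: np.random.Generator) -> None:
    proteins = [tb for tb in builder.ann.given_entities.values() if tb.type == "Protein"]
    for tb in proteins:
        if rng.random() < profile.equiv_rate:
            alias = builder.add_textbound("Protein", f"{tb.text}alias", given=True)
            builder.ann.equivs.append(EquivStatement(frozenset({tb.id, alias.id})))


# ---------------------------------------------------------------------------
# perturbation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationProfile:
    """Rates for the independent corruption operators.

    ``trigger_shift_words`` is a whole-word shift applied to every event
    trigger (0 disables); all other operators are per-instance rates in
    [0,1]. ``add_event_rate`` is interpreted relative to the number of gold
    events in the document (rate 0.5 on 10 events injects ~5 spurious ones).
    """

    drop_event_rate: float = 0.0
    add_event_rate: float = 0.0
    drop_additional_arg_rate: float = 0.0
    add_spurious_arg_rate: float = 0.0
    trigger_shift_words: int = 0
    type_swap_rate: float = 0.0
    modification_flip_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "drop_event_rate",
            "add_event_rate",
            "drop_additional_arg_rate",
            "add_spurious_arg_rate",
            "type_swap_rate",
            "modification_flip_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.trigger_shift_words < 0:
            raise ValueError("trigger_shift_words must be >= 0")


@dataclass(frozen=True)
class Edit:
    """One manifest entry: a single applied corruption."""

    doc_id: str
    op: str
    target: str
    detail: str = ""


_WORD_RE = re.compile(r"\S+")


def _word_spans(text: str) -> list[TextSpan]:
    return [TextSpan(m.start(), m.end()) for m in _WORD_RE.finditer(text)]


def _swap_groups(schema: TaskSchema) -> dict[str, list[str]]:
    """Event types grouped by identical argument signatures (swap-compatible)."""
    by_sig: dict[tuple, list[str]] = {}
    for name, spec in schema.event_types.items():
        sig = tuple(sorted((a.role, tuple(sorted(a.fillers)), a.mandatory, a.repeatable, a.core) for a in spec.args))
        by_sig.setdefault(sig, []).append(name)
    return {name: group for group in by_sig.values() for name in group if len(group) > 1}


def perturb_annotations(
    gold: Mapping[str, AnnotationSet],
    profile: PerturbationProfile,
    schema: TaskSchema,
) -> tuple[dict[str, AnnotationSet], list[Edit]]:
    """Corrupt a gold corpus into a synthetic submission.

    Applies each operator independently at its rate and returns the corrupted
    corpus together with the manifest of every applied edit. The output is
    reference-closed: dropping an event cascades to the events and
    modification flags that depend on it, and orphaned predicted text-bounds
    are removed. Equiv statements are not carried into the submission (they
    belong to the gold side of the evaluation).
    """
    swap_groups = _swap_groups(schema)
    out: dict[str, AnnotationSet] = {}
    manifest: list[Edit] = []
    for doc_index, doc_id in enumerate(sorted(gold)):
        rng = _spawn_rng(profile.seed, doc_index, 1)
        ann = gold[doc_id].copy()
        ann.equivs = []
        edits: list[Edit] = []
        _drop_events(ann, profile, rng, edits)
        _swap_types(ann, profile, swap_groups, rng, edits)
        _shift_triggers(ann, profile, rng, edits)
        _drop_additional_args(ann, profile, schema, rng, edits)
        _add_spurious_args(ann, profile, schema, rng, edits)
        _add_spurious_events(ann, gold[doc_id], profile, schema, rng, edits)
        _flip_modifications(ann, profile, schema, rng, edits)
        _prune_orphans(ann)
        out[doc_id] = ann
        manifest.extend(edits)
    return out, manifest


def _drop_events(ann: AnnotationSet, profile: PerturbationProfile, rng, edits: list[Edit]) -> None:
    if profile.drop_event_rate <= 0:
        return
    direct = {eid for eid in sorted(ann.events) if rng.random() < profile.drop_event_rate}
    dropped = set(direct)
    # cascade: an event whose argument was dropped cannot survive
    changed = True
    while changed:
        changed = False
        for eid, ev in ann.events.items():
            if eid in dropped:
                continue
            if any(a.target in dropped for a in ev.args):
                dropped.add(eid)
                changed = True
    for eid in sorted(dropped):
        op = "drop_event" if eid in direct else "drop_event_cascade"
        edits.append(Edit(ann.doc_id, op, eid, ann.events[eid].type))
        del ann.events[eid]
    for m in ann.modifications:
        if m.target in dropped:
            edits.append(Edit(ann.doc_id, "drop_modification_cascade", m.target, m.kind))
    ann.modifications = [m for m in ann.modifications if m.target not in dropped]


def _swap_types(ann: AnnotationSet, profile: PerturbationProfile, swap_groups, rng, edits) -> None:
    if profile.type_swap_rate <= 0:
        return
    for eid in sorted(ann.events):
        ev = ann.events[eid]
        group = swap_groups.get(ev.type)
        if group and rng.random() < profile.type_swap_rate:
            others = [t for t in group if t != ev.type]
            new_type = others[int(rng.integers(len(others)))]
            ann.events[eid] = replace(ev, type=new_type)
            edits.append(Edit(ann.doc_id, "type_swap", eid, f"{ev.type}->{new_type}"))


def _shift_triggers(ann: AnnotationSet, profile: PerturbationProfile, rng, edits) -> None:
    k = profile.trigger_shift_words
    if k <= 0:
        return
    words = _word_spans(ann.text)
    starts = {w.start: i for i, w in enumerate(words)}
    shifted: dict[str, str] = {}
    for eid in sorted(ann.events):
        ev = ann.events[eid]
        if ev.trigger in shifted:
            ann.events[eid] = replace(ev, trigger=shifted[ev.trigger])
            continue
        tb = ann.textbounds.get(ev.trigger)
        if tb is None or tb.span.start not in starts:
            continue
        wi = starts[tb.span.start]
        target = wi + k if wi + k < len(words) else wi - k
        if not (0 <= target < len(words)):
            continue
        new_span = words[target]
        new_id = tb.id + "s"
        ann.textbounds[new_id] = TextBound(new_id, tb.type, new_span, ann.text[new_span.start : new_span.end])
        shifted[ev.trigger] = new_id
        ann.events[eid] = replace(ev, trigger=new_id)
        edits.append(Edit(ann.doc_id, "trigger_shift", eid, f"{k} words"))


def _drop_additional_args(ann, profile: PerturbationProfile, schema: TaskSchema, rng, edits) -> None:
    if profile.drop_additional_arg_rate <= 0:
        return
    for eid in sorted(ann.events):
        ev = ann.events[eid]
        kept, dropped_roles = [], []
        for arg in ev.args:
            is_additional = False
            try:
                is_additional = classify_argument(schema, ev.type, arg.norm_role) == "additional"
            except ValueError:
                pass
            if is_additional and rng.random() < profile.drop_additional_arg_rate:
                dropped_roles.append(arg.role)
            else:
                kept.append(arg)
        if dropped_roles:
            ann.events[eid] = replace(ev, args=tuple(kept))
            for role in dropped_roles:
                edits.append(Edit(ann.doc_id, "drop_additional_arg", eid, role))


def _filler_word_indices(ann: AnnotationSet, words: list[TextSpan]) -> list[int]:
    used = set()
    for tb in list(ann.given_entities.values()) + list(ann.textbounds.values()):
        for i, w in enumerate(words):
            if w.overlaps(tb.span):
                used.add(i)
    return [i for i in range(len(words)) if i not in used]


def _add_spurious_args(ann, profile: PerturbationProfile, schema: TaskSchema, rng, edits) -> None:
    if profile.add_spurious_arg_rate <= 0:
        return
    words = _word_spans(ann.text)
    filler = _filler_word_indices(ann, words)
    seq = 0
    for eid in sorted(ann.events):
        if rng.random() >= profile.add_spurious_arg_rate or not filler:
            continue
        ev = ann.events[eid]
        spec = schema.event_types.get(ev.type)
        if spec is None:
            continue
        present = {a.norm_role for a in ev.args}
        candidates = [a for a in spec.args if not a.core and (a.repeatable or a.role not in present)]
        candidates = [a for a in candidates if "Entity" in a.fillers]
        if not candidates:
            continue
        arg_spec = candidates[int(rng.integers(len(candidates)))]
        wi = filler.pop(int(rng.integers(len(filler))))
        span = words[wi]
        seq += 1
        tid = f"Tsp{eid}{seq}"
        ann.textbounds[tid] = TextBound(tid, "Entity", span, ann.text[span.start : span.end])
        role = arg_spec.role if arg_spec.role not in present else f"{arg_spec.role}2"
        ann.events[eid] = replace(ev, args=ev.args + (EventArgument(role, tid),))
        edits.append(Edit(ann.doc_id, "add_spurious_arg", eid, role))


def _add_spurious_events(ann, gold_ann, profile: PerturbationProfile, schema: TaskSchema, rng, edits) -> None:
    if profile.add_event_rate <= 0 or not schema.event_types:
        return
    n_add = int(rng.binomial(max(len(gold_ann.events), 1), profile.add_event_rate))
    if n_add == 0:
        return
    words = _word_spans(ann.text)
    filler = _filler_word_indices(ann, words)
    # candidate types whose mandatory slots can be filled with given entities
    usable: list[tuple[str, list[ArgumentSpec]]] = []
    for name, spec in schema.event_types.items():
        mandatory = [a for a in spec.args if a.mandatory]
        if any(a.fillers == frozenset({EVENT_FILLER}) for a in mandatory):
            continue
        ok = True
        for a in mandatory:
            types = schema.resolve_fillers(a.fillers) - {EVENT_FILLER}
            if not any(tb.type in types for tb in ann.given_entities.values()):
                ok = False
        if ok:
            usable.append((name, mandatory))
    if not usable:
        return
    # word indices whose one-word neighbourhood holds a same-type gold trigger
    gold_trigger_words: dict[str, set[int]] = {}
    for ev in gold_ann.events.values():
        tb = gold_ann.resolve_textbound(ev.trigger)
        for i, w in enumerate(words):
            if w.overlaps(tb.span):
                gold_trigger_words.setdefault(ev.type, set()).update({i - 1, i, i + 1})
    seq = 0
    for _ in range(n_add):
        if not filler:
            break
        name, mandatory = usable[int(rng.integers(len(usable)))]
        blocked = gold_trigger_words.get(name, set())
        allowed = [wi for wi in filler if wi not in blocked]
        if not allowed:
            continue
        wi = allowed[int(rng.integers(len(allowed)))]
        filler.remove(wi)
        span = words[wi]
        seq += 1
        tid, eid = f"Tadd{seq}", f"Eadd{seq}"
        ann.textbounds[tid] = TextBound(tid, name, span, ann.text[span.start : span.end])
        args = []
        for a in mandatory:
            types = schema.resolve_fillers(a.fillers) - {EVENT_FILLER}
            pool = sorted(tb.id for tb in ann.given_entities.values() if tb.type in types)
            args.append(EventArgument(a.role, pool[int(rng.integers(len(pool)))]))
        ann.events[eid] = Event(eid, name, tid, tuple(args))
        edits.append(Edit(ann.doc_id, "add_event", eid, name))


def _flip_modifications(ann, profile: PerturbationProfile, schema: TaskSchema, rng, edits) -> None:
    if profile.modification_flip_rate <= 0 or not schema.modification_kinds:
        return
    present = {(m.kind, m.target) for m in ann.modifications}
    new_mods = []
    for m in ann.modifications:
        if rng.random() < profile.modification_flip_rate:
            edits.append(Edit(ann.doc_id, "drop_modification", m.target, m.kind))
        else:
            new_mods.append(m)
    seq = 0
    for eid in sorted(ann.events):
        for kind in schema.modification_kinds:
            if (kind, eid) in present:
                continue
            if rng.random() < profile.modification_flip_rate:
                seq += 1
                new_mods.append(Modification(f"Mfl{seq}", kind, eid))
                edits.append(Edit(ann.doc_id, "add_modification", eid, kind))
    ann.modifications = new_mods


def sample_event_subset(
    gold: Mapping[str, AnnotationSet], n_events: int, seed: int = 0
) -> dict[str, AnnotationSet]:
    """Draw a uniform random, argument-closed sample of gold events.

    Returns a submission-shaped corpus (same documents, shared given layer,
    no modifications or Equiv statements) containing exactly ``n_events``
    events. Sampling an event pulls in the sub-events it references, so the
    sample is always reference-closed; candidates whose closure would
    overshoot the requested size are skipped. Raises if the corpus cannot
    supply ``n_events`` events.
    """
    rng = _spawn_rng(seed, 97)
    pool = [(doc_id, eid) for doc_id in sorted(gold) for eid in sorted(gold[doc_id].events)]
    if len(pool) < n_events:
        raise ValueError(f"corpus has only {len(pool)} events, cannot sample {n_events}")
    order = list(rng.permutation(len(pool)))
    chosen: dict[str, set[str]] = {doc_id: set() for doc_id in gold}
    total = 0

    def closure(ann: AnnotationSet, eid: str) -> set[str]:
        out = {eid}
        stack = [eid]
        while stack:
            for arg in ann.events[stack.pop()].args:
                if arg.target in ann.events and arg.target not in out:
                    out.add(arg.target)
                    stack.append(arg.target)
        return out

    for idx in order:
        if total == n_events:
            break
        doc_id, eid = pool[idx]
        ann = gold[doc_id]
        new = closure(ann, eid) - chosen[doc_id]
        if not new or total + len(new) > n_events:
            continue
        chosen[doc_id] |= new
        total += len(new)
    if total != n_events:
        raise ValueError(f"could not assemble an argument-closed sample of {n_events} events")

    sample: dict[str, AnnotationSet] = {}
    for doc_id in sorted(gold):
        ann = gold[doc_id]
        keep = chosen[doc_id]
        sub = AnnotationSet(doc_id=doc_id, text=ann.text, given_entities=dict(ann.given_entities))
        sub.events = {eid: ann.events[eid] for eid in sorted(keep)}
        referenced: set[str] = set()
        for ev in sub.events.values():
            referenced.add(ev.trigger)
            referenced.update(a.target for a in ev.args)
        sub.textbounds = {tid: tb for tid, tb in ann.textbounds.items() if tid in referenced}
        sample[doc_id] = sub
    return sample


def _prune_orphans(ann: AnnotationSet) -> None:
    referenced: set[str] = set()
    for ev in ann.events.values():
        referenced.add(ev.trigger)
        referenced.update(a.target for a in ev.args)
    for r in ann.relations.values():
        referenced.update((r.arg1, r.arg2))
    ann.textbounds = {tid: tb for tid, tb in ann.textbounds.items() if tid in referenced}
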