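"""Precision/recall/F scoring of submissions against gold annotation.

Scoring is instance-oriented: every event, relation and modification flag is
judged separately. Recall counts gold annotations matched by at least one
predicted annotation; precision counts predicted annotations matching at
least one gold annotation (many-to-many matching, no assignment step). F1 is
the harmonic mean of precision and recall.

Two evaluation criteria are supported:

* ``primary`` — approximate span and approximate recursive matching; a
  partially correct event is both a false positive (its prediction) and a
  false negative (the gold event it resembles).
* ``single_partial`` — the single-partial-penalty relaxation: a predicted
  event that matches a gold event in all of its own arguments but lacks some
  gold arguments is not counted as a false positive (the gold event still
  counts as a false negative); symmetrically, a gold event whose arguments
  are all found in some predicted event is not counted as a false negative.

Two task modes are supported: the ``full`` task scores every annotation
including additional (non-core) arguments and Negation/Speculation flags;
the ``core`` task first reduces both sides to core arguments only, drops
modifications, and merges the resulting duplicate events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .matching import EventMatcher, MatchContext, SpanMode, build_equiv_classes, contained_span_match
from .schemas import TaskSchema, classify_argument
from .standoff import AnnotationSet, Event, EventArgument, Relation, TextBound

__all__ = [
    "PRFScore",
    "EvalReport",
    "prf",
    "reduce_to_core",
    "evaluate_events",
    "evaluate_relations",
    "evaluate",
    "render_report",
]


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PRFScore:
    """Match counts with derived precision, recall and F1 (percentages).

    Scores are kept in full precision; use :meth:`rounded` for the 2-decimal
    rendering used in reports.
    """

    matched_gold: int = 0
    gold_total: int = 0
    matched_pred: int = 0
    pred_total: int = 0

    def __post_init__(self) -> None:
        for name in ("matched_gold", "gold_total", "matched_pred", "pred_total"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.matched_gold > self.gold_total or self.matched_pred > self.pred_total:
            raise ValueError("matched counts cannot exceed totals")

    @property
    def recall(self) -> float:
        return 100.0 * self.matched_gold / self.gold_total if self.gold_total else 0.0

    @property
    def precision(self) -> float:
        return 100.0 * self.matched_pred / self.pred_total if self.pred_total else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def rounded(self) -> tuple[float, float, float]:
        return _round2(self.recall), _round2(self.precision), _round2(self.f1)

    def __add__(self, other: "PRFScore") -> "PRFScore":
        return PRFScore(
            self.matched_gold + other.matched_gold,
            self.gold_total + other.gold_total,
            self.matched_pred + other.matched_pred,
            self.pred_total + other.pred_total,
        )


def prf(matched_gold: int, gold_total: int, matched_pred: int, pred_total: int) -> PRFScore:
    """Build a :class:`PRFScore`, validating the counts."""
    return PRFScore(matched_gold, gold_total, matched_pred, pred_total)


@dataclass
class EvalReport:
    """Per-type, per-group and aggregate scores under one named criterion."""

    criterion: str
    mode: str
    per_type: dict[str, PRFScore] = field(default_factory=dict)
    groups: dict[str, PRFScore] = field(default_factory=dict)
    total: PRFScore = field(default_factory=PRFScore)

    def to_dict(self) -> dict:
        def enc(s: PRFScore) -> dict:
            r, p, f = s.rounded()
            return {
                "matched_gold": s.matched_gold,
                "gold_total": s.gold_total,
                "matched_pred": s.matched_pred,
                "pred_total": s.pred_total,
                "recall": r,
                "precision": p,
                "f1": f,
            }

        return {
            "criterion": self.criterion,
            "mode": self.mode,
            "per_type": {k: enc(v) for k, v in self.per_type.items()},
            "groups": {k: enc(v) for k, v in self.groups.items()},
            "total": enc(self.total),
        }


# ---------------------------------------------------------------------------
# core-task reduction
# ---------------------------------------------------------------------------


def _is_core_arg(schema: TaskSchema, event_type: str, role: str) -> bool:
    try:
        return classify_argument(schema, event_type, role) == "core"
    except ValueError:
        # unknown type or role: keep the argument; the event scores as a
        # false positive of its stated type either way
        return True


def reduce_to_core(ann: AnnotationSet, schema: TaskSchema) -> AnnotationSet:
    """Reduce an annotation set to core extraction targets.

    Every event keeps only its core arguments, modifications are dropped,
    events that become identical under a recursive normal form — (type,
    trigger span, multiset of (normalized role, normalized target)) — are
    merged with references remapped, and predicted text-bounds left
    unreferenced are dropped.
    """
    out = ann.copy()
    out.modifications = []
    out.events = {
        eid: Event(
            ev.id,
            ev.type,
            ev.trigger,
            tuple(a for a in ev.args if _is_core_arg(schema, ev.type, a.norm_role)),
        )
        for eid, ev in ann.events.items()
    }

    equiv = build_equiv_classes(out.equivs, set(out.given_entities))
    nf_memo: dict[str, tuple] = {}

    def target_nf(target: str):
        if target in out.events:
            return event_nf(target)
        if target in out.given_entities:
            cls = equiv.get(target)
            return ("ent", min(cls) if cls else target)
        tb = out.textbounds[target]
        return ("tb", tb.type, tb.span.start, tb.span.end)

    def event_nf(eid: str) -> tuple:
        cached = nf_memo.get(eid)
        if cached is not None:
            return cached
        ev = out.events[eid]
        trig = out.resolve_textbound(ev.trigger)
        items = sorted((a.norm_role, target_nf(a.target)) for a in ev.args)
        nf = ("event", ev.type, trig.span.start, trig.span.end, tuple(items))
        nf_memo[eid] = nf
        return nf

    by_nf: dict[tuple, str] = {}
    remap: dict[str, str] = {}
    for eid in sorted(out.events):
        nf = event_nf(eid)
        rep = by_nf.setdefault(nf, eid)
        remap[eid] = rep

    merged: dict[str, Event] = {}
    for eid, ev in out.events.items():
        rep = remap[eid]
        if rep != eid:
            continue
        merged[eid] = Event(
            ev.id,
            ev.type,
            ev.trigger,
            tuple(EventArgument(a.role, remap.get(a.target, a.target)) for a in ev.args),
        )
    out.events = merged

    referenced: set[str] = set()
    for ev in out.events.values():
        referenced.add(ev.trigger)
        referenced.update(a.target for a in ev.args)
    for r in out.relations.values():
        referenced.update((r.arg1, r.arg2))
    out.textbounds = {tid: tb for tid, tb in out.textbounds.items() if tid in referenced}
    return out


# ---------------------------------------------------------------------------
# event scoring
# ---------------------------------------------------------------------------


class _CountAccumulator:
    def __init__(self) -> None:
        self.matched_gold: dict[str, int] = {}
        self.gold_total: dict[str, int] = {}
        self.matched_pred: dict[str, int] = {}
        self.pred_total: dict[str, int] = {}

    def _bump(self, table: dict[str, int], key: str, by: int = 1) -> None:
        table[key] = table.get(key, 0) + by

    def score_for(self, types: Iterable[str]) -> PRFScore:
        mg = sum(self.matched_gold.get(t, 0) for t in types)
        gt = sum(self.gold_total.get(t, 0) for t in types)
        mp = sum(self.matched_pred.get(t, 0) for t in types)
        pt = sum(self.pred_total.get(t, 0) for t in types)
        return PRFScore(mg, gt, mp, pt)

    def all_types(self) -> list[str]:
        seen = set(self.gold_total) | set(self.pred_total)
        return sorted(seen)


def _as_corpus(x) -> dict[str, AnnotationSet]:
    if isinstance(x, AnnotationSet):
        return {x.doc_id: x}
    return dict(x)


def _check_same_documents(pred: Mapping[str, AnnotationSet], gold: Mapping[str, AnnotationSet]) -> None:
    if set(pred) != set(gold):
        missing = sorted(set(gold) - set(pred))
        extra = sorted(set(pred) - set(gold))
        raise ValueError(
            f"prediction and gold cover different documents (missing: {missing[:5]}, extra: {extra[:5]})"
        )


def _score_document_events(
    acc: _CountAccumulator,
    pred: AnnotationSet,
    gold: AnnotationSet,
    schema: TaskSchema,
    criterion: str,
    span_mode: SpanMode,
) -> None:
    ctx = MatchContext.from_gold(gold, span_mode=span_mode)
    matcher = EventMatcher(pred, gold, ctx)
    pred_events = list(pred.events.values())
    gold_events = list(gold.events.values())

    gold_matched = {
        g.id: any(matcher.match_event(p, g) for p in pred_events) for g in gold_events
    }
    pred_matched = {
        p.id: any(matcher.match_event(p, g) for g in gold_events) for p in pred_events
    }

    for g in gold_events:
        exempt = False
        if criterion == "single_partial" and not gold_matched[g.id]:
            # a gold event partially found inside some richer prediction is
            # not counted as a false negative
            exempt = any(matcher.match_args_superset(p, g) for p in pred_events)
        if not exempt:
            acc._bump(acc.gold_total, g.type)
            if gold_matched[g.id]:
                acc._bump(acc.matched_gold, g.type)
    for p in pred_events:
        exempt = False
        if criterion == "single_partial" and not pred_matched[p.id]:
            # a prediction correct in all of its own arguments but missing
            # some gold arguments is not counted as a false positive
            exempt = any(matcher.match_args_subset(p, g) for g in gold_events)
        if not exempt:
            acc._bump(acc.pred_total, p.type)
            if pred_matched[p.id]:
                acc._bump(acc.matched_pred, p.type)

    # modification flags: a predicted flag is correct iff a gold flag of the
    # same kind targets a gold event matched (primary criteria) by the
    # predicted flag's target event
    if schema.modification_kinds:
        for kind in schema.modification_kinds:
            p_mods = [m for m in pred.modifications if m.kind == kind]
            g_mods = [m for m in gold.modifications if m.kind == kind]
            for gm in g_mods:
                acc._bump(acc.gold_total, kind)
                ge = gold.events[gm.target]
                if any(matcher.match_event(pred.events[pm.target], ge) for pm in p_mods):
                    acc._bump(acc.matched_gold, kind)
            for pm in p_mods:
                acc._bump(acc.pred_total, kind)
                pe = pred.events[pm.target]
                if any(matcher.match_event(pe, gold.events[gm.target]) for gm in g_mods):
                    acc._bump(acc.matched_pred, kind)


def _build_report(
    acc: _CountAccumulator, schema: TaskSchema, criterion: str, mode: str, scored_types: list[str]
) -> EvalReport:
    report = EvalReport(criterion=criterion, mode=mode)
    for t in scored_types:
        report.per_type[t] = acc.score_for([t])
    for group, members in schema.type_groups.items():
        members = [m for m in members if m in report.per_type]
        if mode == "core" and any(m in schema.modification_kinds for m in members):
            continue
        if members:
            report.groups[group] = acc.score_for(members)
    report.total = acc.score_for(scored_types)
    return report


def evaluate_events(
    pred,
    gold,
    schema: TaskSchema,
    criterion: str = "primary",
    mode: str = "full",
    span_mode: SpanMode = "approx",
) -> EvalReport:
    """Score predicted events (and modifications) against gold.

    ``pred`` and ``gold`` are single :class:`AnnotationSet`\\ s or mappings
    from document id to annotation set covering the same documents. In
    ``core`` mode both sides are reduced with :func:`reduce_to_core` first;
    in ``full`` mode Negation/Speculation flags are scored alongside events.
    """
    if criterion not in ("primary", "single_partial"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if mode not in ("full", "core"):
        raise ValueError(f"unknown mode {mode!r}")
    pred_c, gold_c = _as_corpus(pred), _as_corpus(gold)
    _check_same_documents(pred_c, gold_c)

    acc = _CountAccumulator()
    scoring_schema = schema
    if mode == "core":
        scoring_schema = TaskSchema(
            task=schema.task,
            event_types=schema.event_types,
            relation_types=schema.relation_types,
            given_entity_types=schema.given_entity_types,
            modification_kinds=(),
            type_groups=schema.type_groups,
        )
    for doc_id in sorted(gold_c):
        p, g = pred_c[doc_id], gold_c[doc_id]
        if mode == "core":
            p, g = reduce_to_core(p, schema), reduce_to_core(g, schema)
        _score_document_events(acc, p, g, scoring_schema, criterion, span_mode)

    scored_types = sorted(set(schema.event_types) | set(acc.all_types()))
    if mode == "full":
        scored_types = sorted(set(scored_types) | set(schema.modification_kinds))
    return _build_report(acc, scoring_schema, criterion, mode, scored_types)


# ---------------------------------------------------------------------------
# relation scoring
# ---------------------------------------------------------------------------


def _relation_endpoint_match(
    pred_id: str, gold_id: str, pred: AnnotationSet, gold: AnnotationSet, ctx: MatchContext
) -> bool:
    p = pred.resolve_textbound(pred_id)
    g = gold.resolve_textbound(gold_id)
    if p is None or g is None:
        return False
    if gold.is_given(gold_id):
        return pred.is_given(pred_id) and ctx.same_entity(pred_id, gold_id)
    # predicted secondary entity: equal type, span entirely contained within
    # the gold span (stricter than the event criterion: no extension)
    return (
        not pred.is_given(pred_id)
        and p.type == g.type
        and contained_span_match(p.span, g.span)
    )


def _relations_match(
    p: Relation, g: Relation, pred: AnnotationSet, gold: AnnotationSet, ctx: MatchContext
) -> bool:
    return (
        p.type == g.type
        and _relation_endpoint_match(p.arg1, g.arg1, pred, gold, ctx)
        and _relation_endpoint_match(p.arg2, g.arg2, pred, gold, ctx)
    )


def evaluate_relations(pred, gold, schema: TaskSchema) -> EvalReport:
    """Score predicted binary relations against gold.

    A relation matches iff its type matches and both endpoints match: given
    entities by equivalence class, predicted ``Entity`` endpoints by equal
    type and containment within the gold span.
    """
    pred_c, gold_c = _as_corpus(pred), _as_corpus(gold)
    _check_same_documents(pred_c, gold_c)
    acc = _CountAccumulator()
    for doc_id in sorted(gold_c):
        p_ann, g_ann = pred_c[doc_id], gold_c[doc_id]
        ctx = MatchContext.from_gold(g_ann)
        for g in g_ann.relations.values():
            acc._bump(acc.gold_total, g.type)
            if any(_relations_match(p, g, p_ann, g_ann, ctx) for p in p_ann.relations.values()):
                acc._bump(acc.matched_gold, g.type)
        for p in p_ann.relations.values():
            acc._bump(acc.pred_total, p.type)
            if any(_relations_match(p, g, p_ann, g_ann, ctx) for g in g_ann.relations.values()):
                acc._bump(acc.matched_pred, p.type)
    scored_types = sorted(set(schema.relation_types) | set(acc.all_types()))
    return _build_report(acc, schema, "primary", "full", scored_types)


def evaluate(
    pred,
    gold,
    schema: TaskSchema,
    criterion: str = "primary",
    mode: str = "full",
    span_mode: SpanMode = "approx",
) -> EvalReport:
    """Task-aware entry point: relation scoring for relation tasks, event scoring otherwise."""
    if schema.relation_types and not schema.event_types:
        return evaluate_relations(pred, gold, schema)
    return evaluate_events(pred, gold, schema, criterion=criterion, mode=mode, span_mode=span_mode)


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------


def render_report(report: EvalReport, fmt: str = "text") -> str:
    """Render a report as ``text`` (aligned table), ``tsv`` or ``json``."""
    if fmt == "json":
        import json

        return json.dumps(report.to_dict(), indent=2)

    rows: list[tuple[str, PRFScore]] = list(report.per_type.items())
    rows += [(f"[{name} total]", s) for name, s in report.groups.items()]
    rows.append(("TOTAL", report.total))

    header = ("type", "gold", "match", "answer", "match", "recall", "prec.", "F")
    table = [header]
    for name, s in rows:
        r, p, f = s.rounded()
        table.append(
            (
                name,
                str(s.gold_total),
                str(s.matched_gold),
                str(s.pred_total),
                str(s.matched_pred),
                f"{r:.2f}",
                f"{p:.2f}",
                f"{f:.2f}",
            )
        )
    if fmt == "tsv":
        return "\n".join("\t".join(row) for row in table)
    widths = [max(len(row[i]) for row in table) for i in range(len(header))]
    lines = [
        "  ".join(
            cell.ljust(widths[i]) if i == 0 else cell.rjust(widths[i])
            for i, cell in enumerate(row)
        )
        for row in table
    ]
    title = f"criterion={report.criterion} mode={report.mode}"
    sep = "-" * max(len(line) for line in lines)
    return "\n".join([title, sep] + lines)
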