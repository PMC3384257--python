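"""Equality criteria for events, text-bounds and entity references.

Three relaxations of exact matching are implemented:

* **approximate span matching** — a predicted text-bound (trigger or
  ``Entity`` mention) matches a gold one if its span is contained within the
  gold span extended by one whole word to the left and to the right. A word
  is a maximal run of non-whitespace characters; the relation is asymmetric
  (the extension is applied to the gold side only).
* **entity equivalence** — references to any member of an equivalence class
  of given entities (local aliases such as a name and its abbreviation) are
  treated identically.
* **approximate recursive matching** — when an event is referred to as the
  argument of another event, only its ``Theme`` arguments are compared;
  non-Theme arguments of recursively referred events are ignored.

Argument matching between two events requires an injective, role-respecting
correspondence between argument multisets: role names are compared after
stripping numeric suffixes, repeated roles (multiple ``Theme``\\ s of a
binding) are matched as an unordered set, and a gold argument can license at
most one predicted argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .standoff import AnnotationSet, Event, EquivStatement, TextBound, TextSpan

__all__ = [
    "SpanMode",
    "MatchContext",
    "word_extended_span",
    "approx_span_match",
    "contained_span_match",
    "build_equiv_classes",
    "match_textbound",
    "EventMatcher",
    "match_event",
    "match_args_subset",
]

SpanMode = Literal["approx", "exact", "containment"]


def word_extended_span(doc_text: str, span: TextSpan) -> TextSpan:
    """Extend ``span`` by one whole adjacent word on each side.

    Returns the smallest span containing ``span`` plus the word immediately
    to its left and to its right, where words are maximal runs of
    non-whitespace characters. Extension stops at the text boundaries. If the
    span starts or ends mid-word, the remainder of that word counts as the
    adjacent word.
    """
    if not (0 <= span.start < span.end <= len(doc_text)):
        raise ValueError(f"span [{span.start},{span.end}) out of bounds for text of length {len(doc_text)}")
    start = span.start
    while start > 0 and doc_text[start - 1].isspace():
        start -= 1
    while start > 0 and not doc_text[start - 1].isspace():
        start -= 1
    end = span.end
    n = len(doc_text)
    while end < n and doc_text[end].isspace():
        end += 1
    while end < n and not doc_text[end].isspace():
        end += 1
    return TextSpan(start, end)


def contained_span_match(pred: TextSpan, gold: TextSpan) -> bool:
    """True iff the predicted span lies entirely within the gold span."""
    return gold.start <= pred.start and pred.end <= gold.end


def approx_span_match(pred: TextSpan, gold: TextSpan, doc_text: str) -> bool:
    """True iff ``pred`` is contained in the one-word extension of ``gold``."""
    return contained_span_match(pred, word_extended_span(doc_text, gold))


def build_equiv_classes(
    statements: list[EquivStatement], universe: set[str] | None = None
) -> dict[str, frozenset[str]]:
    """Union-find closure of equivalence statements.

    Returns a mapping from every mentioned id (plus every id in ``universe``)
    to its equivalence class as a frozenset; ids in no statement map to
    singleton classes.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for stmt in statements:
        members = sorted(stmt.members)
        for m in members[1:]:
            union(members[0], m)
    for uid in universe or ():
        find(uid)

    groups: dict[str, set[str]] = {}
    for x in parent:
        groups.setdefault(find(x), set()).add(x)
    out: dict[str, frozenset[str]] = {}
    for members in groups.values():
        cls = frozenset(members)
        for m in members:
            out[m] = cls
    return out


@dataclass
class MatchContext:
    """Shared state for one prediction-vs-gold document comparison.

    ``equiv`` maps given-entity ids to their equivalence class; it should be
    built from the gold annotation's Equiv statements (the given layer is
    shared between gold and submissions, so ids are comparable directly).
    """

    doc_text: str
    equiv: dict[str, frozenset[str]] = field(default_factory=dict)
    span_mode: SpanMode = "approx"

    @classmethod
    def from_gold(cls, gold: AnnotationSet, span_mode: SpanMode = "approx") -> "MatchContext":
        return cls(
            doc_text=gold.text,
            equiv=build_equiv_classes(gold.equivs, set(gold.given_entities)),
            span_mode=span_mode,
        )

    def same_entity(self, pred_id: str, gold_id: str) -> bool:
        if pred_id == gold_id:
            return True
        cls = self.equiv.get(gold_id)
        return cls is not None and pred_id in cls

    def span_match(self, pred: TextSpan, gold: TextSpan) -> bool:
        if self.span_mode == "approx":
            return approx_span_match(pred, gold, self.doc_text)
        if self.span_mode == "containment":
            return contained_span_match(pred, gold)
        return pred == gold


def match_textbound(
    pred: TextBound,
    gold: TextBound,
    ctx: MatchContext,
    *,
    pred_given: bool,
    gold_given: bool,
) -> bool:
    """Match two text-bound references.

    Given entities are identified by id / equivalence class only (the given
    layer is shared, so spans never disagree for the same entity); predicted
    text-bounds match on equal type and span agreement under the context's
    span mode.
    """
    if gold_given != pred_given:
        return False
    if gold_given:
        return ctx.same_entity(pred.id, gold.id)
    return pred.type == gold.type and ctx.span_match(pred.span, gold.span)


class EventMatcher:
    """Memoized event matching between one predicted and one gold annotation set.

    All decisions are cached on ``(pred_event_id, gold_event_id, mode)``;
    event graphs are acyclic (validated at parse time), so the recursion
    terminates.
    """

    def __init__(self, pred: AnnotationSet, gold: AnnotationSet, ctx: MatchContext | None = None):
        self.pred = pred
        self.gold = gold
        self.ctx = ctx if ctx is not None else MatchContext.from_gold(gold)
        self._memo: dict[tuple[str, str, str], bool] = {}

    # -- target-level matching ---------------------------------------------

    def _match_target(self, pred_id: str, gold_id: str) -> bool:
        p = self.pred.resolve(pred_id)
        g = self.gold.resolve(gold_id)
        if isinstance(p, Event) and isinstance(g, Event):
            return self.match_event(p, g, recursive_position=True)
        if isinstance(p, TextBound) and isinstance(g, TextBound):
            return match_textbound(
                p,
                g,
                self.ctx,
                pred_given=self.pred.is_given(pred_id),
                gold_given=self.gold.is_given(gold_id),
            )
        return False

    def _triggers_match(self, pred: Event, gold: Event) -> bool:
        pt = self.pred.resolve_textbound(pred.trigger)
        gt = self.gold.resolve_textbound(gold.trigger)
        if pt is None or gt is None:
            raise ValueError("unresolvable trigger reference")
        return self.ctx.span_match(pt.span, gt.span)

    # -- argument multiset matching ----------------------------------------

    @staticmethod
    def _by_role(args) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a in args:
            out.setdefault(a.norm_role, []).append(a.target)
        return out

    def _injective_matching(self, pred_targets: list[str], gold_targets: list[str]) -> bool:
        """Can every pred target be matched to a distinct gold target?"""
        assignment: dict[int, int] = {}  # gold index -> pred index

        def try_assign(pi: int, seen: set[int]) -> bool:
            for gi, gt in enumerate(gold_targets):
                if gi in seen or not self._match_target(pred_targets[pi], gt):
                    continue
                seen.add(gi)
                if gi not in assignment or try_assign(assignment[gi], seen):
                    assignment[gi] = pi
                    return True
            return False

        for pi in range(len(pred_targets)):
            if not try_assign(pi, set()):
                return False
        return True

    def _args_map_into(self, pred_args, gold_args, *, exact: bool) -> bool:
        """Injective role-respecting mapping of pred args into gold args.

        With ``exact=True`` the mapping must be a bijection (equal role
        multiplicities); otherwise pred's multiset must embed into gold's.
        """
        pred_roles = self._by_role(pred_args)
        gold_roles = self._by_role(gold_args)
        if exact and set(pred_roles) != set(gold_roles):
            return False
        for role, pred_targets in pred_roles.items():
            gold_targets = gold_roles.get(role, [])
            if exact and len(pred_targets) != len(gold_targets):
                return False
            if len(pred_targets) > len(gold_targets):
                return False
            if not self._injective_matching(pred_targets, gold_targets):
                return False
        return True

    # -- event-level matching ----------------------------------------------

    def match_event(self, pred: Event, gold: Event, recursive_position: bool = False) -> bool:
        """Primary-criteria event equality.

        At the top level the full argument multisets must correspond
        bijectively; in recursive position (the event is referred to as an
        argument of another event) only ``Theme`` arguments are compared.
        """
        key = (pred.id, gold.id, "rec" if recursive_position else "top")
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        result = self._match_event_uncached(pred, gold, recursive_position)
        self._memo[key] = result
        return result

    def _match_event_uncached(self, pred: Event, gold: Event, recursive_position: bool) -> bool:
        if pred.type != gold.type:
            return False
        if not self._triggers_match(pred, gold):
            return False
        if recursive_position:
            pred_args = [a for a in pred.args if a.norm_role == "Theme"]
            gold_args = [a for a in gold.args if a.norm_role == "Theme"]
        else:
            pred_args, gold_args = list(pred.args), list(gold.args)
        return self._args_map_into(pred_args, gold_args, exact=True)

    def match_args_subset(self, pred: Event, gold: Event) -> bool:
        """True iff pred's full argument multiset embeds into gold's.

        Types and triggers must match; equality is included (a full match is
        a subset match).
        """
        key = (pred.id, gold.id, "sub")
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        result = (
            pred.type == gold.type
            and self._triggers_match(pred, gold)
            and self._args_map_into(list(pred.args), list(gold.args), exact=False)
        )
        self._memo[key] = result
        return result

    def match_args_superset(self, pred: Event, gold: Event) -> bool:
        """True iff gold's argument multiset embeds into pred's.

        This is the gold-side partial-match test (the predicted event carries
        extra arguments); target comparisons still run in the usual
        prediction-vs-gold direction.
        """
        key = (pred.id, gold.id, "sup")
        cached = self._memo.get(key)
        if cached is not None:
            return cached
        pred_roles = self._by_role(pred.args)
        gold_roles = self._by_role(gold.args)
        ok = pred.type == gold.type and self._triggers_match(pred, gold)
        if ok:
            for role, gold_targets in gold_roles.items():
                pred_targets = pred_roles.get(role, [])
                if len(gold_targets) > len(pred_targets):
                    ok = False
                    break
                # embed gold targets injectively into pred targets, matching
                # each candidate pair in the pred-vs-gold direction
                assignment: dict[int, int] = {}

                def try_assign(gi: int, seen: set[int]) -> bool:
                    for pi, pt in enumerate(pred_targets):
                        if pi in seen or not self._match_target(pt, gold_targets[gi]):
                            continue
                        seen.add(pi)
                        if pi not in assignment or try_assign(assignment[pi], seen):
                            assignment[pi] = gi
                            return True
                    return False

                if not all(try_assign(gi, set()) for gi in range(len(gold_targets))):
                    ok = False
                    break
        self._memo[key] = ok
        return ok


def match_event(
    pred_event: Event,
    gold_event: Event,
    pred: AnnotationSet,
    gold: AnnotationSet,
    ctx: MatchContext | None = None,
    recursive_position: bool = False,
) -> bool:
    """Convenience wrapper around :class:`EventMatcher` for one decision."""
    return EventMatcher(pred, gold, ctx).match_event(pred_event, gold_event, recursive_position)


def match_args_subset(
    pred_event: Event,
    gold_event: Event,
    pred: AnnotationSet,
    gold: AnnotationSet,
    ctx: MatchContext | None = None,
) -> bool:
    return EventMatcher(pred, gold, ctx).match_args_subset(pred_event, gold_event)
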