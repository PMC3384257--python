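"""n-vote system combination of event extraction outputs.

The combination emits an event iff it is found in the output of at least
``n`` of the combined systems, where inter-system event equality uses the
primary evaluation criteria (approximate span and approximate recursive
matching). Because approximate span matching is directional and therefore
not transitive, "found in" is realized as connected components of the match
graph: nodes are all systems' events for a document, with an edge wherever
the primary match holds in either direction. A cluster's support is the
number of distinct systems contributing at least one member.

For every cluster with sufficient support, the representative event (from
the lowest-indexed system, ties broken by trigger offset) is emitted
together with its argument closure: sub-events it references transitively,
their triggers and any predicted text-bound arguments — even when a
sub-event's own cluster fell below the support threshold, since the emitted
event would otherwise dangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .matching import EventMatcher, MatchContext, SpanMode
from .standoff import AnnotationSet, Event, EventArgument

__all__ = ["EnsembleConfig", "EventCluster", "cluster_events", "combine_outputs"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Support threshold and matching settings for a combination run."""

    n: int
    span_mode: SpanMode = "approx"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("support threshold n must be >= 1")


@dataclass
class EventCluster:
    """A connected component of the inter-system event match graph."""

    members: list[tuple[int, Event]]
    support: int
    representative: tuple[int, Event]


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def cluster_events(
    outputs: Sequence[AnnotationSet], ctx: MatchContext | None = None
) -> list[EventCluster]:
    """Cluster all systems' events for one document.

    All outputs must share the document text and given-entity layer.
    """
    if not outputs:
        return []
    base = outputs[0]
    for other in outputs[1:]:
        if other.text != base.text:
            raise ValueError("combined outputs must share the document text")
    if ctx is None:
        ctx = MatchContext.from_gold(base)

    matchers: dict[tuple[int, int], EventMatcher] = {}

    def matcher(i: int, j: int) -> EventMatcher:
        key = (i, j)
        if key not in matchers:
            matchers[key] = EventMatcher(outputs[i], outputs[j], ctx)
        return matchers[key]

    uf = _UnionFind()
    nodes: list[tuple[int, str]] = []
    for i, out in enumerate(outputs):
        for eid in out.events:
            nodes.append((i, eid))
            uf.find((i, eid))

    for a_idx in range(len(nodes)):
        i, eid = nodes[a_idx]
        for b_idx in range(a_idx + 1, len(nodes)):
            j, fid = nodes[b_idx]
            ev_a, ev_b = outputs[i].events[eid], outputs[j].events[fid]
            if matcher(i, j).match_event(ev_a, ev_b) or matcher(j, i).match_event(ev_b, ev_a):
                uf.union((i, eid), (j, fid))

    components: dict = {}
    for node in nodes:
        components.setdefault(uf.find(node), []).append(node)

    def rep_key(node: tuple[int, str]):
        i, eid = node
        ev = outputs[i].events[eid]
        trig = outputs[i].resolve_textbound(ev.trigger)
        return (i, trig.span.start, trig.span.end, eid)

    clusters = []
    for members in components.values():
        members = sorted(members, key=rep_key)
        ri, rid = members[0]
        clusters.append(
            EventCluster(
                members=[(i, outputs[i].events[eid]) for i, eid in members],
                support=len({i for i, _ in members}),
                representative=(ri, outputs[ri].events[rid]),
            )
        )
    clusters.sort(key=lambda c: rep_key((c.representative[0], c.representative[1].id)))
    return clusters


def _emit_with_closure(
    out: AnnotationSet,
    source: AnnotationSet,
    sys_index: int,
    event: Event,
    id_map: dict[tuple[int, str], str],
    counters: dict[str, int],
) -> str:
    """Copy an event and everything it transitively requires into ``out``."""
    key = (sys_index, event.id)
    if key in id_map:
        return id_map[key]

    def new_id(prefix: str) -> str:
        # fresh ids must not collide with the retained given-entity ids
        counters[prefix] = counters.get(prefix, 0) + 1
        return f"C{prefix}{counters[prefix]}"

    def copy_textbound(tb_id: str) -> str:
        if tb_id in out.given_entities:
            return tb_id
        tkey = (sys_index, tb_id)
        if tkey in id_map:
            return id_map[tkey]
        tb = source.textbounds[tb_id]
        # identical text-bounds contributed by different systems collapse to
        # one annotation (same-type overlap is illegal within a layer)
        skey = ("span", tb.type, tb.span.start, tb.span.end)
        if skey in id_map:
            id_map[tkey] = id_map[skey]
            return id_map[skey]
        nid = new_id("T")
        id_map[tkey] = nid
        id_map[skey] = nid
        out.textbounds[nid] = type(tb)(nid, tb.type, tb.span, tb.text)
        return nid

    eid = new_id("E")
    id_map[key] = eid
    trigger_id = copy_textbound(event.trigger)
    new_args = []
    for arg in event.args:
        if arg.target in source.events:
            target = _emit_with_closure(out, source, sys_index, source.events[arg.target], id_map, counters)
        elif source.is_given(arg.target):
            target = arg.target
        else:
            target = copy_textbound(arg.target)
        new_args.append(EventArgument(arg.role, target))
    out.events[eid] = Event(eid, event.type, trigger_id, tuple(new_args))
    return eid


def combine_outputs(
    outputs: Sequence[Mapping[str, AnnotationSet]], config: EnsembleConfig
) -> dict[str, AnnotationSet]:
    """Combine per-system corpora into one n-vote corpus.

    ``outputs`` is one corpus (doc id -> annotation set) per system, all over
    the same documents and shared given layer. ``config.n = 1`` yields the
    union of all submissions up to clustering.
    """
    if not outputs:
        raise ValueError("need at least one system output")
    if config.n > len(outputs):
        raise ValueError(f"support threshold n={config.n} exceeds the {len(outputs)} systems")
    doc_ids = set(outputs[0])
    for corpus in outputs[1:]:
        if set(corpus) != doc_ids:
            raise ValueError("all systems must cover the same documents")

    combined: dict[str, AnnotationSet] = {}
    for doc_id in sorted(doc_ids):
        per_system = [corpus[doc_id] for corpus in outputs]
        base = per_system[0]
        out = AnnotationSet(
            doc_id=doc_id,
            text=base.text,
            given_entities=dict(base.given_entities),
            equivs=list(base.equivs),
        )
        id_map: dict[tuple[int, str], str] = {}
        counters: dict[str, int] = {}
        for cluster in cluster_events(per_system):
            if cluster.support >= config.n:
                sys_index, event = cluster.representative
                _emit_with_closure(out, per_system[sys_index], sys_index, event, id_map, counters)
        combined[doc_id] = out
    return combined
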