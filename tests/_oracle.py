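"""Independent brute-force oracles used to cross-check the matching engine.

Everything here is deliberately written on a different algorithmic route
from the package: span extension works on a token list instead of character
scanning, equivalence closure by repeated passes instead of union-find, and
event matching enumerates every argument permutation and every recursive
expansion explicitly instead of per-role bipartite matching with
memoization.
"""

from __future__ import annotations

import itertools
import re

from evalkit.standoff import AnnotationSet, Event, TextBound, TextSpan, normalize_role


def token_extended_span(text: str, span: TextSpan) -> TextSpan:
    """One-word extension computed over an explicit token list."""
    words = [(m.start(), m.end()) for m in re.finditer(r"\S+", text)]
    start, end = span.start, span.end
    overlapping = [w for w in words if w[0] < end and w[1] > start]
    if overlapping:
        # a span starting/ending mid-word absorbs the remainder of that word
        first, last = overlapping[0], overlapping[-1]
        left_extra = first[0] < start
        right_extra = last[1] > end
        start, end = min(start, first[0]), max(end, last[1])
    else:
        left_extra = right_extra = False
    if not left_extra:
        before = [w for w in words if w[1] <= start]
        if before:
            start = before[-1][0]
    if not right_extra:
        after = [w for w in words if w[0] >= end]
        if after:
            end = after[0][1]
    return TextSpan(start, end)


def brute_equiv_classes(equivs) -> dict[str, set[str]]:
    classes: list[set[str]] = [set(e.members) for e in equivs]
    changed = True
    while changed:
        changed = False
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                if classes[i] & classes[j]:
                    classes[i] |= classes[j]
                    classes[j] = set()
                    changed = True
        classes = [c for c in classes if c]
    out: dict[str, set[str]] = {}
    for c in classes:
        for m in c:
            out[m] = c
    return out


def _span_ok(pred_span: TextSpan, gold_span: TextSpan, gold_text: str) -> bool:
    ext = token_extended_span(gold_text, gold_span)
    return ext.start <= pred_span.start and pred_span.end <= ext.end


def oracle_match_event(
    pred_ev: Event,
    gold_ev: Event,
    pred_ann: AnnotationSet,
    gold_ann: AnnotationSet,
    equiv: dict[str, set[str]],
    recursive: bool = False,
) -> bool:
    """Exhaustive-enumeration event matching (no memoization, no pruning)."""
    if pred_ev.type != gold_ev.type:
        return False
    pt = pred_ann.resolve_textbound(pred_ev.trigger)
    gt = gold_ann.resolve_textbound(gold_ev.trigger)
    if not _span_ok(pt.span, gt.span, gold_ann.text):
        return False

    if recursive:
        pargs = [a for a in pred_ev.args if normalize_role(a.role) == "Theme"]
        gargs = [a for a in gold_ev.args if normalize_role(a.role) == "Theme"]
    else:
        pargs, gargs = list(pred_ev.args), list(gold_ev.args)
    if len(pargs) != len(gargs):
        return False
    if not gargs:
        return True

    def pair_ok(pa, ga) -> bool:
        if normalize_role(pa.role) != normalize_role(ga.role):
            return False
        p_t, g_t = pred_ann.resolve(pa.target), gold_ann.resolve(ga.target)
        if isinstance(p_t, Event) and isinstance(g_t, Event):
            return oracle_match_event(p_t, g_t, pred_ann, gold_ann, equiv, recursive=True)
        if isinstance(p_t, TextBound) and isinstance(g_t, TextBound):
            p_given, g_given = pred_ann.is_given(pa.target), gold_ann.is_given(ga.target)
            if p_given != g_given:
                return False
            if g_given:
                return pa.target == ga.target or pa.target in equiv.get(ga.target, set())
            return p_t.type == g_t.type and _span_ok(p_t.span, g_t.span, gold_ann.text)
        return False

    for perm in itertools.permutations(range(len(gargs))):
        if all(pair_ok(pargs[i], gargs[perm[i]]) for i in range(len(pargs))):
            return True
    return False
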