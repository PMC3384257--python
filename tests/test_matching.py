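"""Approximate span matching, equivalence handling and recursive event matching."""

import pytest

from evalkit import (
    CorpusProfile,
    EventMatcher,
    MatchContext,
    PerturbationProfile,
    approx_span_match,
    build_equiv_classes,
    contained_span_match,
    generate_corpus,
    perturb_annotations,
    word_extended_span,
)
from evalkit.standoff import EquivStatement, Event, EventArgument, TextSpan

from _oracle import brute_equiv_classes, oracle_match_event, token_extended_span

from hypothesis import given, settings, strategies as st

TEXT = "histone H3 is methylated"
# word offsets: histone [0,7) H3 [8,10) is [11,13) methylated [14,24)


@pytest.mark.parametrize(
    "span,expected",
    [
        (TextSpan(14, 24), TextSpan(11, 24)),  # "methylated" absorbs "is"
        (TextSpan(8, 10), TextSpan(0, 13)),  # "H3" absorbs "histone" and "is"
        (TextSpan(0, 24), TextSpan(0, 24)),  # whole text unchanged
        (TextSpan(0, 7), TextSpan(0, 10)),  # leftmost word extends right only
    ],
)
def test_word_extended_span_hand_tokenization(span, expected):
    assert word_extended_span(TEXT, span) == expected
    assert token_extended_span(TEXT, span) == expected  # independent oracle agrees


@settings(max_examples=200, derandomize=True)
@given(
    words=st.lists(st.text(alphabet="abxy.,", min_size=1, max_size=5), min_size=1, max_size=8),
    data=st.data(),
)
def test_word_extension_properties_on_random_text(words, data):
    """Extension contains its input, stays in bounds, agrees with the token
    oracle, and containment in it is reflexive for the gold span itself."""
    text = " ".join(words)
    start = data.draw(st.integers(0, len(text) - 1))
    end = data.draw(st.integers(start + 1, len(text)))
    span = TextSpan(start, end)
    ext = word_extended_span(text, span)
    assert 0 <= ext.start <= span.start and span.end <= ext.end <= len(text)
    assert ext == token_extended_span(text, span)
    assert approx_span_match(span, span, text)


def test_word_extended_span_out_of_bounds_rejected():
    with pytest.raises(ValueError):
        word_extended_span(TEXT, TextSpan(10, 99))


def test_approx_span_match_one_word_tolerance():
    gold = TextSpan(14, 24)  # "methylated"
    assert approx_span_match(gold, gold, TEXT)  # reflexive
    assert approx_span_match(TextSpan(11, 24), gold, TEXT)  # plus "is"
    assert not approx_span_match(TextSpan(8, 24), gold, TEXT)  # plus "H3 is": two words
    assert not approx_span_match(TextSpan(0, 24), gold, TEXT)


def test_approx_span_match_is_asymmetric():
    gold, wide = TextSpan(14, 24), TextSpan(11, 24)
    assert approx_span_match(wide, gold, TEXT)
    assert approx_span_match(gold, wide, TEXT)  # containment also holds here
    # two words of extension: only one direction survives
    wider = TextSpan(8, 24)
    assert approx_span_match(gold, wider, TEXT)
    assert not approx_span_match(wider, gold, TEXT)


def test_contained_span_match_no_extension():
    gold = TextSpan(8, 13)
    assert contained_span_match(TextSpan(8, 13), gold)
    assert contained_span_match(TextSpan(9, 12), gold)
    assert not contained_span_match(TextSpan(7, 13), gold)  # one character wider


def test_equiv_classes_transitive_closure():
    stmts = [EquivStatement(frozenset({"T1", "T2"})), EquivStatement(frozenset({"T2", "T3"}))]
    classes = build_equiv_classes(stmts, {"T1", "T2", "T3", "T4"})
    assert classes["T1"] == frozenset({"T1", "T2", "T3"})
    assert classes["T4"] == frozenset({"T4"})
    oracle = brute_equiv_classes(stmts)
    assert set(oracle["T1"]) == set(classes["T1"])


def test_equiv_classes_disjoint_statements_stay_separate():
    stmts = [EquivStatement(frozenset({"T1", "T2"})), EquivStatement(frozenset({"T4", "T5"}))]
    classes = build_equiv_classes(stmts)
    assert classes["T1"] != classes["T4"]


def test_no_statements_gives_singletons():
    classes = build_equiv_classes([], {"T1", "T2"})
    assert classes == {"T1": frozenset({"T1"}), "T2": frozenset({"T2"})}


# ---------------------------------------------------------------------------
# event matching on hand-built structures
# ---------------------------------------------------------------------------


def _simple_pair(doc_builder, *, pred_site=False, gold_site=False, pred_type="Methylation", shift=0):
    """Build (pred, gold) sets over the same text with one modification event."""
    words = ["aa", "trig", "bb", "PROT1", "cc", "site1", "dd"]
    gold_b = doc_builder(words, "d1")
    g_prot = gold_b.tb(3, "Protein", given=True)
    g_trig = gold_b.tb(1, "Methylation")
    g_args = [EventArgument("Theme", g_prot.id)]
    if gold_site:
        g_site = gold_b.tb(5, "Entity")
        g_args.append(EventArgument("Site", g_site.id))
    gold_b.ann.events["E1"] = Event("E1", "Methylation", g_trig.id, tuple(g_args))

    pred_b = doc_builder(words, "d1", id_start=50)
    pred_b.ann.given_entities = dict(gold_b.ann.given_entities)
    p_trig = pred_b.tb(1 + shift, pred_type)
    p_args = [EventArgument("Theme", g_prot.id)]
    if pred_site:
        p_site = pred_b.tb(5, "Entity")
        p_args.append(EventArgument("Site", p_site.id))
    pred_b.ann.events["E9"] = Event("E9", pred_type, p_trig.id, tuple(p_args))
    return pred_b.ann, gold_b.ann


def test_identical_events_match(doc_builder):
    pred, gold = _simple_pair(doc_builder, pred_site=True, gold_site=True)
    m = EventMatcher(pred, gold)
    assert m.match_event(pred.events["E9"], gold.events["E1"])


def test_missing_site_blocks_top_level_match(doc_builder):
    pred, gold = _simple_pair(doc_builder, pred_site=False, gold_site=True)
    m = EventMatcher(pred, gold)
    assert not m.match_event(pred.events["E9"], gold.events["E1"])
    # ... but it is an argument-subset match (the single-penalty exemption)
    assert m.match_args_subset(pred.events["E9"], gold.events["E1"])


def test_extra_argument_blocks_subset_but_not_superset(doc_builder):
    pred, gold = _simple_pair(doc_builder, pred_site=True, gold_site=False)
    m = EventMatcher(pred, gold)
    assert not m.match_event(pred.events["E9"], gold.events["E1"])
    assert not m.match_args_subset(pred.events["E9"], gold.events["E1"])
    assert m.match_args_superset(pred.events["E9"], gold.events["E1"])


def test_full_match_is_also_a_subset_match(doc_builder):
    pred, gold = _simple_pair(doc_builder, pred_site=True, gold_site=True)
    m = EventMatcher(pred, gold)
    assert m.match_args_subset(pred.events["E9"], gold.events["E1"])


def test_type_mismatch_blocks_match(doc_builder):
    pred, gold = _simple_pair(doc_builder, pred_type="Demethylation")
    m = EventMatcher(pred, gold)
    assert not m.match_event(pred.events["E9"], gold.events["E1"])


def test_one_word_trigger_shift_matches_two_words_does_not(doc_builder):
    pred1, gold = _simple_pair(doc_builder, shift=1)
    assert EventMatcher(pred1, gold).match_event(pred1.events["E9"], gold.events["E1"])
    pred2, gold = _simple_pair(doc_builder, shift=2)
    assert not EventMatcher(pred2, gold).match_event(pred2.events["E9"], gold.events["E1"])


def _nested_pair(doc_builder, *, extra_site_on_referred: bool):
    """Regulation(Theme -> Gene_expression(Theme -> protein [, Site]))."""
    words = ["x", "regtrig", "y", "exprtrig", "z", "PROT1", "sitew", "q"]
    def build(with_site):
        b = doc_builder(words, "d1")
        prot = b.tb(5, "Protein", given=True)
        etrig = b.tb(3, "Gene_expression")
        args = [EventArgument("Theme", prot.id)]
        if with_site:
            site = b.tb(6, "Entity")
            args.append(EventArgument("Site", site.id))
        b.ann.events["E1"] = Event("E1", "Gene_expression", etrig.id, tuple(args))
        rtrig = b.tb(1, "Regulation")
        b.ann.events["E2"] = Event("E2", "Regulation", rtrig.id, (EventArgument("Theme", "E1"),))
        return b.ann

    gold = build(False)
    pred = build(extra_site_on_referred)
    pred.given_entities = dict(gold.given_entities)
    return pred, gold


def test_non_theme_arguments_ignored_for_recursively_referred_events(doc_builder):
    pred, gold = _nested_pair(doc_builder, extra_site_on_referred=True)
    m = EventMatcher(pred, gold)
    # the referred expression event differs in a Site argument, so it does
    # not match at the top level ...
    assert not m.match_event(pred.events["E1"], gold.events["E1"])
    # ... but in recursive position only Themes count, so the regulations match
    assert m.match_event(pred.events["E2"], gold.events["E2"])


def test_equiv_alias_reference_matches(doc_builder):
    words = ["aa", "trig", "bb", "PROT1", "cc", "PROT1alias", "dd"]
    gold_b = doc_builder(words, "d1")
    prot = gold_b.tb(3, "Protein", given=True)
    alias = gold_b.tb(5, "Protein", given=True)
    gold_b.ann.equivs.append(EquivStatement(frozenset({prot.id, alias.id})))
    gtrig = gold_b.tb(1, "Methylation")
    gold_b.ann.events["E1"] = Event("E1", "Methylation", gtrig.id, (EventArgument("Theme", prot.id),))

    pred_b = doc_builder(words, "d1", id_start=50)
    pred_b.ann.given_entities = dict(gold_b.ann.given_entities)
    ptrig = pred_b.tb(1, "Methylation")
    pred_b.ann.events["E9"] = Event("E9", "Methylation", ptrig.id, (EventArgument("Theme", alias.id),))

    m = EventMatcher(pred_b.ann, gold_b.ann)
    assert m.match_event(pred_b.ann.events["E9"], gold_b.ann.events["E1"])


# ---------------------------------------------------------------------------
# properties on generated data
# ---------------------------------------------------------------------------


def _random_pairs(task, n_docs, seed):
    schema = None
    from evalkit import get_task_schema

    schema = get_task_schema(task)
    gold = generate_corpus(
        schema,
        CorpusProfile(documents=n_docs, events_per_doc=3.0, nesting_prob=0.5, equiv_rate=0.3, seed=seed),
    )
    pred, _ = perturb_annotations(
        gold,
        PerturbationProfile(
            drop_event_rate=0.15,
            add_event_rate=0.2,
            drop_additional_arg_rate=0.3,
            add_spurious_arg_rate=0.3,
            type_swap_rate=0.2,
            seed=seed + 1,
        ),
        schema,
    )
    return gold, pred


@pytest.mark.parametrize("task,seed", [("epi", 101), ("id", 202)])
def test_match_event_agrees_with_brute_force_oracle(task, seed):
    gold, pred = _random_pairs(task, 40, seed)
    checked = 0
    for doc_id in gold:
        g_ann, p_ann = gold[doc_id], pred[doc_id]
        if len(g_ann.events) > 6 or len(p_ann.events) > 6:
            continue
        equiv = brute_equiv_classes(g_ann.equivs)
        matcher = EventMatcher(p_ann, g_ann)
        for p in p_ann.events.values():
            for g in g_ann.events.values():
                expected = oracle_match_event(p, g, p_ann, g_ann, equiv)
                assert matcher.match_event(p, g) == expected, (doc_id, p.id, g.id)
                checked += 1
    assert checked > 100


def test_equiv_substitution_never_changes_decisions(id_schema):
    gold = generate_corpus(
        id_schema, CorpusProfile(documents=15, events_per_doc=4, equiv_rate=1.0, seed=33)
    )
    for ann in gold.values():
        classes = build_equiv_classes(ann.equivs, set(ann.given_entities))
        swapped = ann.copy()
        new_events = {}
        for eid, ev in swapped.events.items():
            args = []
            for a in ev.args:
                cls = classes.get(a.target)
                target = a.target
                if cls and len(cls) > 1:
                    target = sorted(cls - {a.target})[0]  # substitute a co-class alias
                args.append(EventArgument(a.role, target))
            new_events[eid] = Event(ev.id, ev.type, ev.trigger, tuple(args))
        swapped.events = new_events
        matcher = EventMatcher(swapped, ann)
        for p in swapped.events.values():
            for g in ann.events.values():
                base = EventMatcher(ann, ann).match_event(ann.events[p.id], g)
                assert matcher.match_event(p, g) == base


def test_memoization_is_transparent(id_schema):
    gold, pred = _random_pairs("id", 10, 77)
    for doc_id in gold:
        memo_matcher = EventMatcher(pred[doc_id], gold[doc_id])
        decisions_with_memo = {
            (p.id, g.id): memo_matcher.match_event(p, g)
            for p in pred[doc_id].events.values()
            for g in gold[doc_id].events.values()
        }
        for (pid, gid), expected in decisions_with_memo.items():
            fresh = EventMatcher(pred[doc_id], gold[doc_id])  # empty cache each decision
            assert fresh.match_event(pred[doc_id].events[pid], gold[doc_id].events[gid]) == expected


def test_gold_vs_gold_matching_is_symmetric(epi_schema):
    """With identical span sets the match relation is symmetric."""
    gold = generate_corpus(epi_schema, CorpusProfile(documents=15, events_per_doc=5, seed=55))
    for ann in gold.values():
        matcher = EventMatcher(ann, ann)
        events = list(ann.events.values())
        for a in events:
            for b in events:
                assert matcher.match_event(a, b) == matcher.match_event(b, a)
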