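"""Scoring: PRF arithmetic, core reduction, partial-penalty and relation evaluation."""

import pytest

from evalkit import (
    CorpusProfile,
    PerturbationProfile,
    evaluate,
    evaluate_events,
    evaluate_relations,
    generate_corpus,
    get_task_schema,
    perturb_annotations,
    prf,
    reduce_to_core,
)
from evalkit.standoff import Event, EventArgument, Modification, Relation


@pytest.mark.parametrize(
    "counts,expected",
    [
        ((100, 100, 100, 100), (100.0, 100.0, 100.0)),
        ((0, 10, 0, 0), (0.0, 0.0, 0.0)),
        ((2, 5, 2, 3), (40.0, 66.67, 50.0)),  # harmonic mean of 66.67 and 40
    ],
)
def test_prf_arithmetic(counts, expected):
    score = prf(*counts)
    assert score.rounded() == expected


def test_prf_rejects_impossible_counts():
    with pytest.raises(ValueError):
        prf(-1, 5, 0, 0)
    with pytest.raises(ValueError):
        prf(6, 5, 0, 0)


# ---------------------------------------------------------------------------
# core-task reduction
# ---------------------------------------------------------------------------


def _glyco_doc(doc_builder):
    b = doc_builder(["x", "glytrig", "y", "PROT1", "z", "sitew", "q", "chainw", "r"])
    prot = b.tb(3, "Protein", given=True)
    trig = b.tb(1, "Glycosylation")
    site = b.tb(5, "Entity")
    chain = b.tb(7, "Entity")
    b.ann.events["E1"] = Event(
        "E1",
        "Glycosylation",
        trig.id,
        (
            EventArgument("Theme", prot.id),
            EventArgument("Site", site.id),
            EventArgument("Sidechain", chain.id),
        ),
    )
    return b


def test_reduction_strips_additional_arguments(doc_builder, epi_schema):
    b = _glyco_doc(doc_builder)
    reduced = reduce_to_core(b.ann, epi_schema)
    ev = reduced.events["E1"]
    assert [a.norm_role for a in ev.args] == ["Theme"]
    # orphaned secondary-entity mentions are dropped with their arguments
    assert all(tb.type != "Entity" for tb in reduced.textbounds.values())


def test_reduction_merges_events_differing_only_in_site(doc_builder, epi_schema):
    b = doc_builder(["x", "methtrig", "y", "PROT1", "z", "siteA", "siteB", "q"])
    prot = b.tb(3, "Protein", given=True)
    trig = b.tb(1, "Methylation")
    s1, s2 = b.tb(5, "Entity"), b.tb(6, "Entity")
    b.ann.events["E1"] = Event(
        "E1", "Methylation", trig.id, (EventArgument("Theme", prot.id), EventArgument("Site", s1.id))
    )
    b.ann.events["E2"] = Event(
        "E2", "Methylation", trig.id, (EventArgument("Theme", prot.id), EventArgument("Site", s2.id))
    )
    reduced = reduce_to_core(b.ann, epi_schema)
    assert len(reduced.events) == 1


def test_reduction_remaps_references_to_merged_events(doc_builder, epi_schema):
    b = doc_builder(["x", "methtrig", "y", "PROT1", "cattrig", "PROT2", "siteA", "z"])
    prot = b.tb(3, "Protein", given=True)
    cause = b.tb(5, "Protein", given=True)
    mtrig = b.tb(1, "Methylation")
    ctrig = b.tb(4, "Catalysis")
    site = b.tb(6, "Entity")
    b.ann.events["E1"] = Event(
        "E1", "Methylation", mtrig.id, (EventArgument("Theme", prot.id), EventArgument("Site", site.id))
    )
    b.ann.events["E2"] = Event("E2", "Methylation", mtrig.id, (EventArgument("Theme", prot.id),))
    b.ann.events["E3"] = Event(
        "E3", "Catalysis", ctrig.id, (EventArgument("Theme", "E2"), EventArgument("Cause", cause.id))
    )
    reduced = reduce_to_core(b.ann, epi_schema)
    assert len(reduced.events) == 2  # the two methylations merged
    catalysis = next(e for e in reduced.events.values() if e.type == "Catalysis")
    theme = next(a for a in catalysis.args if a.norm_role == "Theme")
    assert theme.target in reduced.events


def test_reduction_drops_modifications(doc_builder, epi_schema):
    b = _glyco_doc(doc_builder)
    b.ann.modifications.append(Modification("M1", "Negation", "E1"))
    assert reduce_to_core(b.ann, epi_schema).modifications == []


def test_theme_only_event_unchanged_by_reduction(doc_builder, epi_schema):
    b = doc_builder(["x", "trig", "PROT1", "y"])
    prot = b.tb(2, "Protein", given=True)
    trig = b.tb(1, "Ubiquitination")
    b.ann.events["E1"] = Event("E1", "Ubiquitination", trig.id, (EventArgument("Theme", prot.id),))
    reduced = reduce_to_core(b.ann, epi_schema)
    assert reduced.events["E1"].args == b.ann.events["E1"].args


# ---------------------------------------------------------------------------
# event evaluation
# ---------------------------------------------------------------------------


def _five_event_doc(doc_builder, keep=5, spurious=0):
    """Gold with five phosphorylations; prediction reproducing `keep` of them."""
    words = []
    for i in range(5):
        words += [f"f{i}", f"ptrig{i}", f"PROT{i}"]
    words += ["pad1", "pad2", "pad3", "pad4", "pad5", "pad6", "pad7", "pad8", "pad9"]
    gold_b = doc_builder(words, "d1")
    pred_b = doc_builder(words, "d1", id_start=60)
    for i in range(5):
        prot = gold_b.tb(3 * i + 2, "Protein", given=True)
        trig = gold_b.tb(3 * i + 1, "Phosphorylation")
        gold_b.ann.events[f"E{i}"] = Event(
            f"E{i}", "Phosphorylation", trig.id, (EventArgument("Theme", prot.id),)
        )
        if i < keep:
            ptrig = pred_b.tb(3 * i + 1, "Phosphorylation")
            pred_b.ann.events[f"P{i}"] = Event(
                f"P{i}", "Phosphorylation", ptrig.id, (EventArgument("Theme", prot.id),)
            )
    pred_b.ann.given_entities = dict(gold_b.ann.given_entities)
    for j in range(spurious):
        strig = pred_b.tb(16 + j, "Phosphorylation")  # far from any gold trigger
        prot_id = next(iter(gold_b.ann.given_entities))
        pred_b.ann.events[f"S{j}"] = Event(
            f"S{j}", "Phosphorylation", strig.id, (EventArgument("Theme", prot_id),)
        )
    return pred_b.ann, gold_b.ann


def test_exact_reproduction_scores_hundred(doc_builder, epi_schema):
    pred, gold = _five_event_doc(doc_builder)
    for criterion in ("primary", "single_partial"):
        for mode in ("full", "core"):
            rep = evaluate_events(pred, gold, epi_schema, criterion=criterion, mode=mode)
            assert rep.total.rounded() == (100.0, 100.0, 100.0)


def test_partial_reproduction_with_spurious_prediction(doc_builder, epi_schema):
    pred, gold = _five_event_doc(doc_builder, keep=2, spurious=1)
    rep = evaluate_events(pred, gold, epi_schema)
    assert rep.total.rounded() == (40.0, 66.67, 50.0)


def test_empty_prediction_scores_zero(doc_builder, epi_schema):
    pred, gold = _five_event_doc(doc_builder, keep=0)
    rep = evaluate_events(pred, gold, epi_schema)
    assert rep.total.rounded() == (0.0, 0.0, 0.0)


def test_document_set_mismatch_rejected(doc_builder, epi_schema):
    pred, gold = _five_event_doc(doc_builder)
    with pytest.raises(ValueError):
        evaluate_events({"other": pred}, {"d1": gold}, epi_schema)


def _partial_pair(doc_builder, *, pred_has_extra: bool):
    words = ["x", "methtrig", "y", "PROT1", "z", "sitew", "q"]
    gold_b = doc_builder(words, "d1")
    prot = gold_b.tb(3, "Protein", given=True)
    gtrig = gold_b.tb(1, "Methylation")
    gold_args = [EventArgument("Theme", prot.id)]
    pred_args = [EventArgument("Theme", prot.id)]
    if pred_has_extra:
        pass  # gold stays Theme-only
    else:
        gsite = gold_b.tb(5, "Entity")
        gold_args.append(EventArgument("Site", gsite.id))
    gold_b.ann.events["E1"] = Event("E1", "Methylation", gtrig.id, tuple(gold_args))

    pred_b = doc_builder(words, "d1", id_start=50)
    pred_b.ann.given_entities = dict(gold_b.ann.given_entities)
    ptrig = pred_b.tb(1, "Methylation")
    if pred_has_extra:
        psite = pred_b.tb(5, "Entity")
        pred_args.append(EventArgument("Site", psite.id))
    pred_b.ann.events["P1"] = Event("P1", "Methylation", ptrig.id, tuple(pred_args))
    return pred_b.ann, gold_b.ann


def test_single_penalty_drops_fp_for_missing_argument(doc_builder, epi_schema):
    pred, gold = _partial_pair(doc_builder, pred_has_extra=False)
    primary = evaluate_events(pred, gold, epi_schema, criterion="primary").total
    assert (primary.pred_total, primary.gold_total) == (1, 1)
    assert primary.matched_pred == primary.matched_gold == 0
    spp = evaluate_events(pred, gold, epi_schema, criterion="single_partial").total
    # no FP (prediction exempt), but the gold event still counts as FN
    assert (spp.pred_total, spp.gold_total) == (0, 1)


def test_single_penalty_drops_fn_for_extra_argument(doc_builder, epi_schema):
    pred, gold = _partial_pair(doc_builder, pred_has_extra=True)
    spp = evaluate_events(pred, gold, epi_schema, criterion="single_partial").total
    # the over-specified prediction keeps its FP; the gold event is exempt
    assert (spp.pred_total, spp.gold_total) == (1, 0)


def test_single_penalty_leaves_exact_matches_untouched(doc_builder, epi_schema):
    pred, gold = _five_event_doc(doc_builder)
    primary = evaluate_events(pred, gold, epi_schema, criterion="primary").total
    spp = evaluate_events(pred, gold, epi_schema, criterion="single_partial").total
    assert primary == spp


# ---------------------------------------------------------------------------
# modification scoring
# ---------------------------------------------------------------------------


def test_modification_scoring(doc_builder, epi_schema):
    pred, gold = _five_event_doc(doc_builder, keep=2, spurious=1)
    gold.modifications.append(Modification("M1", "Negation", "E0"))  # matched by P0
    gold.modifications.append(Modification("M2", "Negation", "E4"))  # never predicted
    pred.modifications.append(Modification("M1", "Negation", "P0"))  # TP
    pred.modifications.append(Modification("M2", "Speculation", "S0"))  # FP: no gold counterpart
    rep = evaluate_events(pred, gold, epi_schema, mode="full")
    neg = rep.per_type["Negation"]
    assert (neg.matched_gold, neg.gold_total, neg.matched_pred, neg.pred_total) == (1, 2, 1, 1)
    spec = rep.per_type["Speculation"]
    assert (spec.matched_pred, spec.pred_total) == (0, 1)
    assert rep.groups["modification"].gold_total == 2
    # core mode ignores modifications entirely
    core = evaluate_events(pred, gold, epi_schema, mode="core")
    assert "Negation" not in core.per_type


# ---------------------------------------------------------------------------
# relation evaluation
# ---------------------------------------------------------------------------


def _relation_pair(doc_builder, *, pred_type="Protein-Component", narrow=True):
    words = ["aa", "histoneH3", "bb", "lysine", "nine", "cc"]
    gold_b = doc_builder(words, "d1")
    prot = gold_b.tb(1, "Protein", given=True)
    part = gold_b.tb(3, "Entity", n_words=2)  # "lysine nine"
    gold_b.ann.relations["R1"] = Relation("R1", "Protein-Component", prot.id, part.id)

    pred_b = doc_builder(words, "d1", id_start=50)
    pred_b.ann.given_entities = dict(gold_b.ann.given_entities)
    p_part = pred_b.tb(3, "Entity", n_words=1 if narrow else 2)
    pred_b.ann.relations["R9"] = Relation("R9", pred_type, prot.id, p_part.id)
    return pred_b.ann, gold_b.ann


def test_relation_entity_containment_match(doc_builder, rel_schema):
    pred, gold = _relation_pair(doc_builder, narrow=True)
    rep = evaluate_relations(pred, gold, rel_schema)
    assert rep.total.rounded() == (100.0, 100.0, 100.0)


def test_relation_type_mismatch_is_fp_and_fn(doc_builder, rel_schema):
    pred, gold = _relation_pair(doc_builder, pred_type="Subunit-Complex")
    rep = evaluate_relations(pred, gold, rel_schema)
    assert rep.total.matched_gold == 0 and rep.total.matched_pred == 0
    assert rep.per_type["Subunit-Complex"].pred_total == 1
    assert rep.per_type["Protein-Component"].gold_total == 1


def test_relation_entity_wider_than_gold_does_not_match(doc_builder, rel_schema):
    words = ["aa", "histoneH3", "bb", "lysine", "nine", "cc"]
    gold_b = doc_builder(words, "d1")
    prot = gold_b.tb(1, "Protein", given=True)
    part = gold_b.tb(3, "Entity")  # just "lysine"
    gold_b.ann.relations["R1"] = Relation("R1", "Protein-Component", prot.id, part.id)
    pred_b = doc_builder(words, "d1", id_start=50)
    pred_b.ann.given_entities = dict(gold_b.ann.given_entities)
    wide = pred_b.tb(3, "Entity", n_words=2)
    pred_b.ann.relations["R9"] = Relation("R9", "Protein-Component", prot.id, wide.id)
    rep = evaluate_relations(pred_b.ann, gold_b.ann, rel_schema)
    assert rep.total.matched_pred == 0


# ---------------------------------------------------------------------------
# aggregate properties on generated corpora
# ---------------------------------------------------------------------------


def test_group_counts_equal_sum_of_member_types(id_schema):
    gold = generate_corpus(id_schema, CorpusProfile(documents=20, events_per_doc=6, seed=90))
    pred, _ = perturb_annotations(
        gold, PerturbationProfile(drop_event_rate=0.2, add_event_rate=0.2, seed=91), id_schema
    )
    rep = evaluate_events(pred, gold, id_schema, mode="full")
    for group, members in id_schema.type_groups.items():
        expected = sum(
            (rep.per_type[m] for m in members if m in rep.per_type),
            start=prf(0, 0, 0, 0),
        )
        assert rep.groups[group] == expected
    total_expected = sum(rep.per_type.values(), start=prf(0, 0, 0, 0))
    assert rep.total == total_expected


def test_self_evaluation_identity_on_generated_corpora():
    for task in ("epi", "id"):
        schema = get_task_schema(task)
        gold = generate_corpus(schema, CorpusProfile(documents=8, events_per_doc=5, seed=17))
        for criterion in ("primary", "single_partial"):
            for mode in ("full", "core"):
                rep = evaluate_events(gold, gold, schema, criterion=criterion, mode=mode)
                assert rep.total.rounded() == (100.0, 100.0, 100.0), (task, criterion, mode)


def test_evaluate_dispatches_relations_for_rel_task(rel_schema):
    gold = generate_corpus(rel_schema, CorpusProfile(documents=4, seed=21))
    rep = evaluate(gold, gold, rel_schema)
    assert rep.total.rounded() == (100.0, 100.0, 100.0)
    assert set(rep.per_type) == {"Protein-Component", "Subunit-Complex"}
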