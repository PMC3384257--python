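# Methods

This note records the exact semantics the toolkit implements, the decisions
taken where the conventions of this evaluation family leave room, and what
the synthetic test bed does and does not establish.

## Data model

A document is plain text plus standoff annotations addressed by 0-based,
end-exclusive character offsets (newlines count). Text-bound annotations are
contiguous spans; within one layer no two spans of the same type may
overlap, and overlapping spans of different types must nest rather than
cross. The *given* layer (`.a1`) holds the task-input entity mentions shared
between gold and every submission; the *target* layer (`.a2`) holds
predicted text-bounds (event triggers and generic `Entity` mentions),
events, `Negation`/`Speculation` flags, relations and `Equiv` statements.
Because the layers are distinct namespaces of annotations, the same-type
overlap constraint is enforced within each layer only: a predicted trigger
may legitimately coincide with a given entity. Event graphs must be acyclic;
this is validated at parse time, which is what lets the matcher recurse
without cycle checks.

Role names may carry numeric suffixes (`Theme2`, `Site3`) to distinguish
repeated roles on one event. They are stored raw but normalized (suffix
digits stripped) for all schema checks and matching, so repeated roles
behave as an unordered multiset.

Serialization is canonical: text-bounds sorted by (start, end, type) and
renumbered with the given layer first, events in topological order
(arguments before the events that use them), then flags, relations, and
`Equiv` statements. `serialize ∘ parse` is therefore the identity on
canonical files, and `parse ∘ serialize` is the identity up to renumbering —
a property the suite checks on 1,000 generated annotation sets.

## Matching semantics

**Word extension.** A *word* is a maximal run of non-whitespace characters;
punctuation attaches to its adjacent run. The one-word extension of a gold
span absorbs, on each side, any remainder of a word the span starts or ends
inside, plus one whole adjacent word, stopping at the text boundaries. This
definition is reproducible and dialect-free (no tokenizer involved); whether
the historical tools extended by one token or one whitespace word is not
recorded anywhere we know of, so the whitespace convention is fixed here
explicitly and the exact-span mode is available for comparisons that must
not depend on it.

**Text-bound matching.** Predicted triggers and `Entity` mentions match a
gold counterpart iff the types are equal and the predicted span lies within
the extension of the gold span — an asymmetric relation by construction.
Given entities never match by span: the given layer is shared, so references
are compared by id, up to the transitive closure of the gold `Equiv`
statements (a name and its abbreviation are interchangeable everywhere).

**Event matching (primary criteria).** Types equal, triggers match, and the
full argument multisets correspond injectively in both directions (a
bijection) with equal normalized roles and matching fillers; a gold argument
can license at most one predicted argument. Per role the correspondence is
found by augmenting-path bipartite matching — argument lists are short, so
worst-case cost is irrelevant, but correctness under repeated roles
(multi-`Theme` bindings) is not. When an event is reached *as the argument
of another event*, only its `Theme` arguments are compared; all other
arguments of recursively referred events are ignored. Decisions are memoized
per (predicted event, gold event, position) within one document comparison;
the suite verifies memoization changes no decision, and checks the whole
relation against a brute-force oracle that enumerates every role-respecting
argument permutation and recursive expansion explicitly.

`Site` arguments of multi-`Theme` bindings are treated as an unordered set,
not paired with specific themes — the representation does not record such
pairings. Argument-less `Process` events match on type and trigger span
alone, which is forced by the type having no mandatory arguments.

## Scoring

Counting is instance-oriented and many-to-many: recall counts gold events
matched by at least one prediction, precision counts predictions matching at
least one gold event, with no bipartite assignment step between events. This
keeps scoring order-independent and means a duplicate correct prediction is
not punished. Predictions whose type lies outside the active schema are
counted as false positives under their stated type rather than rejected.
Duplicate identical events in a full-task submission are counted as separate
predictions (deduplication happens only in core reduction, where it is part
of the definition).

**Core reduction** keeps only core-flagged arguments, removes modification
flags, merges events identical under a recursive normal form — (type,
trigger span, multiset of (normalized role, normalized target), with given
entities normalized to an `Equiv`-class representative and sub-events to
their own normal form) — remapping references to merged events, and drops
predicted text-bounds left unreferenced.

**Single partial penalty.** After primary matching, an unmatched prediction
is removed from the false-positive side iff its arguments embed injectively
into some gold event's arguments (same type, matching trigger); an unmatched
gold event is removed from the false-negative side iff its arguments embed
into some prediction's. The two exemptions are applied independently per
event, with target comparisons always in the prediction-vs-gold direction.
It follows directly that P, R and F under the single penalty are each at
least their primary-criterion values; the suite checks this on 100 random
corrupted corpora, with strictness when argument drops are the only error.

**Modifications** are scored in full mode only: a predicted flag is correct
iff a gold flag of the same kind targets a gold event matched (primary
criteria) by the flagged prediction. Flag counts are never adjusted by the
single-penalty exemptions, which are defined on events.

**Relations** match on equal type and both endpoints: the named-entity
endpoint by `Equiv` class, the `Entity` endpoint by equal type and strict
containment of the predicted span within the gold span (no extension).

Scores are computed in full precision and rendered to two decimals,
half-up.

## Significance testing

The statistic is the absolute difference of the two systems' pooled
(micro-averaged) total F1. The swap unit is the document: each repetition
independently exchanges the two systems' per-document outputs with
probability ½ and recomputes both pooled scores; 9,999 repetitions by
default, p estimated as `(b+1)/(R+1)` so it is never zero. The cited
method's standard use for corpus-level scores swaps at the document level;
nothing in the evaluation family fixes a different unit. On corpora of up to
20 documents an exhaustive mode enumerates all `2^D` patterns and returns
the exact permutation p; the suite confirms the sampled estimate converges
to it within Monte-Carlo error.

## System combination

An n-vote combination emits an event iff it is found in at least *n* of the
combined outputs, with "the same event" decided by the primary criteria.
Because approximate span matching is directional, pairwise event equality is
not transitive; clusters are therefore connected components of the match
graph (edges wherever the match holds in either direction), the weakest
closure consistent with "found in *n* outputs". Support counts distinct
systems, not member events. The representative is the member from the
lowest-indexed system (ties by trigger offset), emitted with its full
argument closure — sub-events are re-included even when their own cluster
fell below the threshold, since the emitted event would otherwise dangle.
Combination operates on events only (the experiment it implements is defined
on core extraction targets); modification flags and relations are not
carried into combined output. Recall is non-increasing in *n* and the
*n* = 1 union dominates every standalone system's recall, both verified in
the suite.

## Synthetic corpus generator

Documents are streams of synthetic space-separated tokens; every entity
mention and trigger occupies one whole token, with at least one filler token
between consecutive annotation-bearing tokens so that one-word extensions
never accidentally bridge two annotations. Realism is structural, not
lexical: the generator produces nested regulation and catalysis structures
(catalysis themes always nest; optional event slots nest with probability
`nesting_prob` = 0.35, depth-capped at 3), multi-`Theme` bindings,
participant-less processes, `Equiv` aliases (`equiv_rate` = 0.10 per
protein), `Negation`/`Speculation` flags (`modification_rate` = 0.04 per
kind per event, matching the few-percent incidence of flags in the reference
corpora), and part-of relations with one protein endpoint each. Default
event-type sampling weights are proportional to the type frequencies of the
reference task corpora, so generated data reproduces their skew (many
expression/process events, single-digit reverse reactions). Default corpus
size is 20 documents × Poisson(8) events (at least one event per document,
so every document contributes to document-level swaps). Optional core
arguments appear with probability 0.40 and additional arguments with 0.20 —
deliberately denser than the ~3% incidence of additional arguments in the
infectious-disease reference data, because the full/core and partial-penalty
machinery is exactly what the additional arguments exercise.

The perturbation engine applies independent operators — event drops (with
cascading removal of dependent events and flags), spurious event injection
(triggers placed on filler words at least two words from any same-type gold
trigger, so injected events never accidentally match), additional-argument
drops, spurious-argument additions, whole-word trigger shifts (shift 1 stays
within the one-word extension, shift 2 leaves it — probing the span rule at
its boundary), argument-signature-preserving type swaps, and modification
flips — and records every edit in a manifest. For each operator in isolation
the scores the evaluator produces equal the scores predicted from the
manifest, which is what turns the generator into an oracle for the whole
stack.

What passing these tests does **not** show: behaviour on real text
(discontinuous or sub-token triggers, annotation ambiguity, tokenizer
edge cases), scorer agreement with any historical evaluation service to the
digit, or performance characteristics of real extraction systems. The
synthetic conditions establish the algebraic properties of the criteria, not
empirical system rankings.

## Numerical and degenerate-input conventions

Precision (resp. recall) is defined as 0 when there are no predictions
(resp. no gold annotations), and F as 0 when both are 0. Duplicate
modification flags of one kind on one event collapse on parsing (flags are
binary). The randomization test compares pseudo-statistics to the observed
value with a `1e-12` tie tolerance so floating-point noise cannot flip a
`≥` decision. All randomness (generator, perturbation, sampling,
significance) flows through seeded NumPy generators; identical profiles give
byte-identical serialized corpora.

## Problem sizes used in the test suite

The acceptance-style checks run at sizes chosen to make their statistics
meaningful while keeping the suite fast: the gold self-evaluation sample
uses 100 events from a ~320-event corpus; oracle equivalence compares every
event pair on 500+ documents of at most 6 events; criterion-dominance runs
100 independent 4-document corpora; error recovery uses ~2,000 flat events
(3 binomial standard errors ≈ 2–3 percentage points); significance exactness
enumerates all 1,024 swap patterns of a 10-document corpus; round-tripping
covers 1,000 annotation sets across all three tasks. The whole suite
completes in a few seconds.
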