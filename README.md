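# evalkit

A library and command-line toolkit for **evaluating biomedical event and
relation extraction systems** against gold-standard standoff annotation. It
is aimed at shared-task organizers, system developers who want exact,
reproducible scores during development, and anyone who needs to compare
extraction systems with proper significance testing or combine their outputs.

Extraction targets are *events*: typed, n-ary associations of participants in
roles, anchored to a trigger expression in text, possibly taking other events
as arguments (e.g. a `Regulation` whose `Theme` is a `Gene_expression`).
Three built-in task schemas cover protein/DNA modification events (`epi`,
15 event types including `Catalysis`), infectious-disease molecular
mechanisms (`id`, 10 event types over five core entity classes), and entity
part-of relations (`rel`, `Protein-Component` and `Subunit-Complex`); custom
schemas load from YAML.

## What it computes

Scoring is instance-oriented. For a submission scored against gold,

- recall `R = 100 · |matched gold| / |gold|`,
- precision `P = 100 · |matched predicted| / |predicted|`,
- `F1 = 2PR / (P + R)`, the harmonic mean, is the ranking criterion.

A predicted event matches a gold event under the **primary criteria** iff
their types are equal, their triggers agree under *approximate span
matching* (the predicted span lies within the gold span extended by one
whole word on each side), and their argument multisets correspond one-to-one
with equal roles and matching fillers — given entities by identity up to
`Equiv` alias classes, secondary entities by type and approximate span,
sub-events by *approximate recursive matching* (only `Theme` arguments of
recursively referred events are compared). Relation endpoints use the
stricter containment criterion with no extension.

On top of the match relation the toolkit provides:

- **full vs core task** — core scoring strips additional (non-`Theme`/`Cause`)
  arguments and `Negation`/`Speculation` flags from both sides and merges the
  resulting duplicate events;
- **single partial penalty** — a relaxed criterion in which an event that is
  a strict argument-subset (or superset) of a gold event incurs only one of
  the usual two penalties instead of counting as both FP and FN;
- **approximate randomization** significance tests of F-score differences
  (9,999 repetitions by default, exact enumeration on small corpora);
- **n-vote system combination** — emit an event iff at least *n* systems
  produced it, with event identity decided by the primary criteria;
- a **synthetic corpus generator** and **error-injection engine** that
  produce schema-valid gold corpora and controlled corrupted "submissions"
  with an exact edit manifest, so every part of the stack is testable
  without access to real task data.

## Worked example

```python
from evalkit import (CorpusProfile, PerturbationProfile, evaluate_events,
                     generate_corpus, get_task_schema, perturb_annotations,
                     render_report)

schema = get_task_schema("epi")
gold = generate_corpus(schema, CorpusProfile(documents=20, events_per_doc=8, seed=7))
noise = PerturbationProfile(drop_event_rate=0.2, add_event_rate=0.1,
                            drop_additional_arg_rate=0.5, seed=8)
submission, manifest = perturb_annotations(gold, noise, schema)
print(f"{sum(len(a.events) for a in gold.values())} gold events, {len(manifest)} injected errors")
report = evaluate_events(submission, gold, schema, criterion="primary", mode="full")
print(render_report(report))
```

prints (abridged):

```
145 gold events, 63 injected errors
criterion=primary mode=full
------------------------------------------------------------------------
type                  gold  match  answer  match  recall   prec.       F
Acetylation             22     16      24     16   72.73   66.67   69.57
Catalysis                9      8       8      8   88.89  100.00   94.12
...
[simple total]          73     55      68     55   75.34   80.88   78.01
[modification total]    12      8       9      8   66.67   88.89   76.19
TOTAL                  157    107     144    107   68.15   74.31   71.10
```

Each row shows how many gold annotations of that type exist (`gold`), how
many were found (`match`), how many the submission predicted (`answer`), and
the resulting percentages; groups like `[simple total]` aggregate their
member types, and `TOTAL` pools every scored type (here including the
`Negation`/`Speculation` flag rows). The 20% event-drop rate shows up as
recall in the low 70s; argument drops depress full-task precision but
disappear under core scoring (`mode="core"` gives F1 87.14 on the same
submission) and are forgiven one penalty under
`criterion="single_partial"` (F1 76.98).

The same operations are available from the shell:

```bash
evalkit synth --task epi --out gold/ --seed 7
evalkit perturb --task epi --gold gold/ --out pred/ --manifest edits.json
evalkit evaluate --task epi --gold gold/ --pred pred/ --criterion primary --mode full
evalkit significance --task epi --gold gold/ --pred-a predA/ --pred-b predB/ --reps 9999 --seed 1
evalkit combine --task epi --gold gold/ --pred predA/ --pred predB/ --n 2 --out combined/
```

## Standoff format

Per document: `<docid>.txt` (text), `<docid>.a1` (given entities,
`ID<TAB>TYPE START END<TAB>TEXT`), `<docid>.a2` (targets: text-bounds as in
`.a1`, events `ID<TAB>TYPE:TRIGGERID ROLE:TARGETID ...`, modifications
`ID<TAB>Negation|Speculation EVENTID`, relations
`ID<TAB>TYPE Arg1:ID Arg2:ID`, equivalences `*<TAB>Equiv ID ID ...`).
Offsets are 0-based, end-exclusive character positions. Gold directories
carry `.txt` + `.a1` + `.a2`; submissions carry `.a2` only.

See `docs/methods.md` for the precise matching semantics, the design
decisions behind them, and known limitations.
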