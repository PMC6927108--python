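# Methods

This note records what the package models, the parameters that matter,
the choices made where the design was genuinely open, and what the test
suite does and does not establish.

## The ontology schema

The T-Box is an application ontology for patient counseling dialogue:
classes describe *what can be said and why*, and the engine treats the
instance graph as its dialogue-state machine. The hierarchy has four
level roots — Discussion, Goal, Task (with Speech Task beneath it), and
Utterance — plus Vaccine Counseling under Discussion, the seven
Communication Goals under Goal, the speech-task taxonomy under Speech
Task, and 18 participant / 29 system utterance classes under Utterance.
That is 72 named classes in total. Published descriptions of this kind
of ontology count more classes (86) and one further object property than
they enumerate; the builder deliberately constructs only the enumerable
inventory and does not pad to a headline count, so the totals here are
72 classes, 8 object properties, 5 data properties.

Speech-act annotation follows Searle's classification, kept exactly as
tabulated: both *assertive* and *representative* appear as distinct
values even though Searle treats them as one category (a comment
annotation records this on the affected classes). Three reconstruction
choices were needed where the tabulated inventory is silent:

- Grouping classes whose rows print no act (Negative Utterance, Positive
  Utterance, Personal Status, Compassionate Utterance, Option) take the
  act of their children; System Declaration is annotated *declaration*,
  Searle's own category for world-changing pronouncements.
- Negative Personal Status is listed under two parents with two
  different acts; it is encoded once with both parents (multi-parent
  subsumption) and the act *expressive*, matching its sibling Positive
  Personal Status.
- Health Information — the utterance delivering one piece of health
  content — is placed under System Utterance with act *representative*;
  it appears only in the topic-delivery flow, not in the utterance
  tables.

IRIs are `<base>#CamelCaseLabel` with the verbatim label in
`rdfs:label`, which makes serialization deterministic and round-trip
exact (parse ∘ serialize is the identity on classes, properties and
annotations, property-tested over random sub-schemas in both Turtle and
RDF/XML).

## Session graphs and task templates

A counseling script (YAML/JSON, schema in
`schemas/dialogue_script.schema.json`) lists goals in order, each with
speech tasks and content slots. Compilation instantiates a fixed
utterance template per task kind and chains tasks with `speechSegue`
edges. The templates are the normative reconstruction of the task
flows and are frozen as golden fixtures in the test suite; two details
deserve explanation:

- **Valediction** mirrors salutation's repeat loop (Request Repeat leads
  back to the expected replies), since the two pleasantry tasks are
  described as sequence-identical up to utterance classes.
- **Question Options** (the "any more questions?" prompt) gives the
  proceed branch (Disconfirmation) priority 0 and the question loop
  priority 1. Template candidates otherwise take priorities in listing
  order; this one site is reordered because a participant who is out of
  questions must have a default that exits the loop — otherwise no
  session containing a question-answering excursion could terminate.

Off-path flows use `speechSegue` edges from task-terminal participant
utterances: a Question during topic delivery segues to the
question-answering task, and a Disconfirmation segues to the
pursuit-before-exit goal's task (a presumptive nudge); a second
refusal there passes through Capitulate and segues to the valediction.
Both excursions carry a return address (a single-depth stack pushed at
the segue, popped when the excursion's proceed branch fires), so the
conversation resumes exactly where it was interrupted. `follows` is
never stored: it is derived by querying `precedes` backwards, and the
inverse closure is checked exhaustively on compiled graphs.

Instance-level RDF serialization writes one triple per
`hasUtteranceExamples` entry; RDF assigns no order to triples, so loaded
example lists are sorted and graph equality treats example lists as
multisets. Engine semantics are unaffected (classification takes the
maximum over examples).

## The dialogue engine

The engine implements the focus-transition loop: exactly one instance
carries `hasFocus` while the session is live. On a system utterance it
emits the `hasUtteranceString`, marks `hasBeenSaid`, and advances; when
the followers are participant classes it waits for input, placing focus
on the highest-priority expected slot. Input is classified by token-set
Jaccard similarity (lower-cased, punctuation-stripped) against each
candidate's examples, taking the best example per candidate.

Parameters:

- `threshold` (τ, default **0.5**, unitless in [0,1]): minimum Jaccard
  similarity for a match; below it the input is Unintelligible.
  Jaccard was chosen over learned matchers because it is deterministic,
  dependency-free and auditable; 0.5 means "at least half the combined
  vocabulary is shared".
- `retry_budget` (default **2** per request-repeat site): repeated
  misunderstanding is described as ending the session without a printed
  count; two re-asks before giving up is the conventional choice in
  deployed voice interfaces. The third consecutive failure at a site
  ends the session.
- Priorities: lower integer = higher priority; ties break on instance id
  for determinism.

A matched participant utterance is marked `hasBeenSaid` ("heard") and
focus passes *through* it to its follower within the same step; pausing
focus on the participant node would deadlock the loop. `hasBeenSaid` is
monotone and the single-focus invariant is property-tested across
randomized persona runs.

## Semiotic metrics

All six sub-scores map an ontology document to [0,1]:

- **lawfulness** = 1 − violating/total statements. Violations are
  structural OWL2-profile breaches: undeclared predicates, typing or
  subclassing against undeclared terms, and punning (one IRI as both
  class and property, or both object and data property).
- **richness** = |axiom types used ∩ inventory| / |inventory|. The
  shipped inventory lists 16 OWL2 axiom/feature types
  (`phido.metrics.DEFAULT_AXIOM_INVENTORY`). The inventory is
  configuration: published richness figures for comparable ontologies
  are not reproducible without the original feature list, so no
  particular constant is privileged.
- **interpretability**: fraction of distinct label words (camel-case and
  space split) with ≥1 sense in the lexical provider.
- **consistency**: fraction of classes satisfiable under structural
  reasoning — a class is unsatisfiable if its superclass closure
  contains an asserted-disjoint pair. No DL reasoner is used; this is
  exact for schemas without complex class expressions, which is the
  intended input class.
- **clarity**: mean over label words of 1/max(1, senses); unknown words
  clamp to one sense so they cannot be charged as ambiguous.
- **comprehensiveness** = min(1, classes/reference size). The reference
  (default 10,000 classes) stands for the average size of an ontology
  library and is configuration, not a measured constant.

Branches: syntactic = mean(lawfulness, richness); semantic = unweighted
mean(interpretability, consistency, clarity); pragmatic =
comprehensiveness (its other sub-scores, relevance and accuracy, need
domain experts and are out of scope). Overall = Σ wᵢ·branchᵢ with
default weights 1/3 — read as exactly one third rather than 0.33 so a
perfect ontology scores 1.00; both readings agree to two decimals on the
composites checked in the tests. Note that an unweighted semantic mean
of (0.94, 1.00, 0.92) is 0.95, while comparable published reports give
0.94 for those inputs; the weighting that yields 0.94 is unknown, so no
test pins the semantic composite to it. Benchmark z-scores require a
user-supplied per-score mean and standard deviation; none is built in
because no benchmark distribution is published.

The lexical provider is a plain `word -> sense count` callable. The
bundled toy lexicon (`phido.lexicon`) covers the vocabulary of the
schema labels with hand-set counts reflecting ordinary English polysemy;
it keeps the suite deterministic and offline. Scores produced with it
are internally consistent but not comparable to scores computed against
a full word-sense database.

## Simulator

Personas stand in for counseling participants. The cooperative persona
replies with the first example of the highest-priority expected
utterance (always a certain match); confused emits gibberish with
probability `p_gibberish`; refuser disconfirms with `p_disconfirm` where
a Disconfirmation is expected; questioner spends a question budget
(default 2) asking at question sites; repeater requests re-delivery with
`p_repeat` (an additional knob beyond the three shared probabilities).
Gibberish tokens are consonant clusters from an alphabet disjoint from
every example text, so a zero Jaccard score — and hence the
Unintelligible classification — is guaranteed rather than probable.
Each session uses one named RNG stream seeded from the run seed; no
global RNG state is touched.

The script generator emits 1–7 goals (opening with acclimation/
salutation, closing with conclusion/valediction, topic goals in between,
the pursuit goal only at the full 7) with health items drawn from a
configurable vocabulary. What the synthetic setup does **not** model:
real patient language (paraphrase, disfluency, topic drift), speech
recognition noise with structure (gibberish here is adversarially
unmatchable, real ASR errors are near-misses), and mixed-initiative
behavior beyond the single question/refusal excursions. Passing tests
therefore demonstrate the control flow and the contracts, not
robustness of the similarity matcher on natural input.

## Problem sizes and determinism

The test suite runs entirely on generated data: compiled sessions of
roughly 20–130 utterance instances, property tests over 15–50 examples
(hypothesis, derandomized), and a 1,000-turn randomized persona sweep
for the focus invariant. `scripts/acceptance.py` rebuilds the 72-class
schema (350 triples serialized), scores it, and drives one full
cooperative session; everything completes in seconds. All randomness is
seeded; transcripts and generated scripts are byte-reproducible for a
fixed seed.

## Known limitations

- The engine covers the described task flows; utterance classes that
  appear in the taxonomy but in no flow (Divergent Question, Satisfaction
  Prompt, Inquire Personal, Prattle, Agenda, Apology, Condolence, Happy
  For, Inform, Request, Clarification Options, Acceptance, Participant
  Introduction/Farewell) are schema-only: they can be instantiated and
  serialized but no template routes through them.
- Lawfulness and consistency are structural checks, not a complete OWL2
  DL profile validator or reasoner; they are exact on the class of
  documents this package emits.
- Interview replies accept Positive/Negative Personal Status only; the
  set of participant classes a real interview should accept is an open
  modelling question.
- Topic options are rendered as a single utterance listing the options,
  not as sibling option utterances.
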