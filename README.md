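# phido — ontology-driven dialogue management for patient health counseling

`phido` rebuilds a patient health-information dialogue ontology as a
working system. Health-care providers rarely have time to counsel every
patient on, say, the HPV vaccine, and conversational agents can standardize
that counseling — if the dialogue flow itself is encoded in a form a
machine can reason over. This package targets researchers in health
informatics and conversational-agent engineering who want the whole loop
runnable on a desk: ontology schema, counseling content, dialogue engine,
and quality metrics, with simulated participants instead of human subjects.

It provides:

- **Schema builder** (`phido.builder`): programmatic construction of the
  dialogue ontology T-Box — four class levels (*Discussion*, *Goal*,
  *Task*/*Speech Task*, *Utterance*), 18 participant-utterance and 29
  system-utterance classes annotated with Searle speech-act types, seven
  communication goals grounded in the Health Belief Model, eight object
  properties (`follows`/`precedes` as mutual inverses, `speechSegue`,
  `belongsToSpeechTask`, ...) and the five utterance data properties
  (`hasUtterancePriority`, `hasUtteranceString`, `hasBeenSaid`,
  `hasUtteranceExamples`, `hasFocus`). Serialized to OWL2 Turtle or
  RDF/XML with lossless round-trip.
- **Script compiler** (`phido.script`, `phido.session`): declarative
  YAML/JSON counseling scripts (goals → speech tasks → content slots)
  compiled into an instance-level session graph via fixed utterance
  templates for the seven speech-task kinds (salutation, valediction,
  initiate discussion, transition to topic, interview participant,
  discuss health topic, question answering).
- **Dialogue engine** (`phido.engine`): the focus-transition mechanism —
  query what `follows` the focused utterance, speak system utterances,
  classify participant input by token-set Jaccard similarity against
  `hasUtteranceExamples`, move the single `hasFocus` marker, and request
  repeats with a bounded retry budget.
- **Semiotic metrics** (`phido.metrics`): lawfulness, richness,
  interpretability, consistency, clarity and comprehensiveness for any
  OWL2 ontology, composed into syntactic/semantic/pragmatic branch scores
  and an overall score `(1/3)·syntactic + (1/3)·semantic + (1/3)·pragmatic`,
  with optional z-scores against a user-supplied benchmark.
- **Simulator** (`phido.simulator`): deterministic script generation and
  five participant personas (cooperative, confused, refuser, questioner,
  repeater) so every path runs offline and reproducibly.

## Worked example

Build the ontology and score it:

```sh
$ phido build-schema -o phido.ttl
$ phido evaluate --ontology phido.ttl
{
  "clarity": 0.63,
  "comprehensiveness": 0.01,
  "consistency": 1.0,
  "interpretability": 1.0,
  "lawfulness": 1.0,
  "overall": 0.53,
  "pragmatic": 0.01,
  "richness": 0.44,
  "semantic": 0.88,
  "syntactic": 0.72
}
```

`lawfulness` 1.0 means no statement in the emitted document breaks the
OWL2 profile, and `consistency` 1.0 means every class is satisfiable.
`richness` and `comprehensiveness` depend on configuration (the axiom
inventory and the reference library size; see `docs/methods.md`), and
`clarity` penalizes polysemous label words under the bundled lexicon.

Simulate a counseling session on the bundled HPV script with a
question-asking persona:

```sh
$ phido simulate --persona questioner --seed 7 | head -3
{"class": "System Greet", "kind": "system_say", "text": "Hello! I am a virtual assistant here to talk with you about the HPV vaccine.", "turn": 1, "utterance_id": "g0.t0.greet"}
{"class": "Reciprocal Greet", "kind": "await_input", "text": "", "turn": 1, "utterance_id": "g0.t0.reciprocal_greet"}
{"class": "Reciprocal Greet", "kind": "classified_as", "score": 1.0, "text": "hello there", "turn": 2, "utterance_id": "g0.t0.reciprocal_greet"}
```

Each line is one engine event: the agent speaks (`system_say`), waits for
input (`await_input`), and classifies the reply against the expected
utterance classes (`classified_as`, with its Jaccard score). The same
persona and seed always reproduce the transcript byte for byte. An
interactive session runs with `phido compile --script ... -o session.ttl`
followed by `phido run --session session.ttl`.

## Layout

```
src/phido/        library (schema, builder, script, session, engine,
                  metrics, lexicon, simulator, cli)
examples/         bundled HPV counseling script + a generated sample
schemas/          JSON-Schema for the dialogue-script format
docs/methods.md   models, parameters, design choices, limitations
tests/            pytest suite (unit, property-based, acceptance)
```
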