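"""Programmatic construction of the dialogue-ontology schema.

The T-Box is rebuilt from its published inventory: four class levels
(Discussion, Goal, Task with Speech Task, Utterance), the participant and
system utterance taxonomies with their Searle speech-act types, the seven
communication goals, and the fourteen-minus-one properties that can be
named from that inventory (eight object properties and the five utterance
data properties).

Notes on the reconstruction:

* The participant taxonomy keeps both "assertive" and "representative" as
  annotation values, exactly as the published tables print them, even
  though Searle's taxonomy treats them as one category (recorded on the
  relevant classes as a comment).
* Grouping classes whose table rows print no speech act (Negative
  Utterance, Positive Utterance, Personal Status, Compassionate Utterance,
  Option, System Declaration) are annotated from their children's acts;
  System Declaration is annotated "declaration", Searle's own category.
* Negative Personal Status is listed in the tables under both Negative
  Utterance and Personal Status with differing acts; it is encoded once,
  with both parents, as "expressive" (matching Positive Personal Status).
* Health Information is placed under System Utterance: it is the utterance
  the agent speaks when presenting one piece of health content in the
  Discuss Health Topic task.
"""

from __future__ import annotations

from .schema import (
    COMMUNICATION_GOALS,
    DATA_PROPERTY_RANGES,
    ClassDescriptor,
    OntologySchema,
    PropertyDescriptor,
)

__all__ = [
    "build_schema",
    "PARTICIPANT_UTTERANCES",
    "SYSTEM_UTTERANCES",
]

# name -> (speech act, parents within the participant subtree; empty means
# directly under Participant Utterance)
PARTICIPANT_UTTERANCES: dict[str, tuple[str, tuple[str, ...]]] = {
    "Acceptance": ("expressive", ()),
    "Negative Utterance": ("expressive", ()),
    "Disconfirmation": ("expressive", ("Negative Utterance",)),
    "Negative Personal Status": ("expressive", ("Negative Utterance", "Personal Status")),
    "Participant Farewell": ("expressive", ()),
    "Participant Introduction": ("assertive", ()),
    "Personal Status": ("expressive", ()),
    "Positive Personal Status": ("expressive", ("Positive Utterance", "Personal Status")),
    "Positive Utterance": ("representative", ()),
    "Confirmation": ("representative", ("Positive Utterance",)),
    "Prattle": ("none", ()),
    "Question": ("directive", ()),
    "Divergent Question": ("directive", ("Question",)),
    "Reciprocal Farewell": ("expressive", ()),
    "Reciprocal Greet": ("expressive", ()),
    "Request System": ("directive", ()),
    "Request System Repeat": ("directive", ("Request System",)),
    "Unintelligible": ("none", ()),
}

SYSTEM_UTTERANCES: dict[str, tuple[str, tuple[str, ...]]] = {
    "Acknowledgment": ("expressive", ()),
    "Agenda": ("commissive", ()),
    "Answer": ("representative", ()),
    "No Answer": ("representative", ("Answer",)),
    "Apology": ("expressive", ()),
    "Capitulate": ("expressive", ()),
    "Compassionate Utterance": ("expressive", ()),
    "Condolence": ("expressive", ("Compassionate Utterance",)),
    "Happy For": ("expressive", ("Compassionate Utterance",)),
    "Confirm Health Information": ("directive", ()),
    "System Declaration": ("declaration", ()),
    "Disclaimer": ("representative", ("System Declaration",)),
    "Topic Transition": ("commissive", ("System Declaration",)),
    "System Farewell": ("expressive", ()),
    "Concluding Farewell": ("expressive", ("System Farewell",)),
    "System Greet": ("expressive", ()),
    "Inform": ("representative", ()),
    "Inquire Personal": ("directive", ()),
    "Interview Question": ("directive", ()),
    "Option": ("directive", ()),
    "Clarification Options": ("directive", ("Option",)),
    "Question Options": ("directive", ("Option",)),
    "Topic Options": ("directive", ("Option",)),
    "Overview": ("commissive", ()),
    "Request": ("directive", ()),
    "Request Repeat": ("directive", ()),
    "Satisfaction Prompt": ("directive", ()),
    "System Introduction": ("representative", ()),
    # Spoken by the agent when delivering one piece of health content.
    "Health Information": ("representative", ()),
}

_ASSERTIVE_NOTE = (
    "Annotated exactly as tabulated; note that Searle's taxonomy treats "
    "'assertive' and 'representative' as a single category."
)


def build_schema(iri_base: str = "https://w3id.org/phido") -> OntologySchema:
    """Construct the full dialogue-ontology T-Box.

    Returns a schema that passes :func:`phido.schema.validate_schema` with
    an empty report.  The inventory is the fully named one: 72 classes,
    8 object properties and the 5 utterance data properties.
    """
    classes: list[ClassDescriptor] = []

    def add(name, parents=(), act="none", note=""):
        classes.append(ClassDescriptor(name, frozenset(parents), act, note))

    # level roots
    add("Discussion", note="Encapsulates one whole counseling conversation.")
    add("Goal", note="An objective the conversation works toward.")
    add("Task", note="A generic activity concept.")
    add("Utterance", note="Any piece of speech by the agent or the participant.")

    add("Vaccine Counseling", ["Discussion"],
        note="A counseling discussion about vaccination.")

    add("Communication Goal", ["Goal"],
        note="A high-level objective for communicating health information.")
    goal_notes = {
        "Acclimate": "Help the participant adapt to talking with an automated agent.",
        "Conclude": "End the discussion.",
        "Communicate Benefit": "Health-belief-model construct: perceived benefits.",
        "Communicate Effectiveness": "Health-belief-model construct: effectiveness.",
        "Communicate Harms": "Health-belief-model construct: perceived harms.",
        "Communicate Uncertainty": "Health-belief-model construct: uncertainty.",
        "Pursuit Before Exit": "Presumptive nudge for a hesitant participant before exiting.",
    }
    for goal in COMMUNICATION_GOALS:
        add(goal, ["Communication Goal"], note=goal_notes[goal])

    add("Speech Task", ["Task"],
        note="An atomic conversational objective realized as a small utterance graph.")
    add("Pleasantry Task", ["Speech Task"],
        note="Exchange of pleasantries opening or closing the session.")
    add("Salutation", ["Pleasantry Task"])
    add("Valediction", ["Pleasantry Task"])
    add("Proposition Task", ["Speech Task"],
        note="Communicating a piece of information with participant feedback.")
    add("Initiate Discussion", ["Proposition Task"])
    add("Transition to Topic", ["Proposition Task"])
    add("Interview Participant", ["Proposition Task"])
    add("Discuss Health Topic", ["Proposition Task"])
    add("Question and Answering Task", ["Speech Task"],
        note="Answering participant questions during the session.")

    add("Participant Utterance", ["Utterance"],
        note="Utterances expected and spoken by the participant user.")
    add("System Utterance", ["Utterance"],
        note="Utterances vocalized by the agent.")

    for name, (act, parents) in PARTICIPANT_UTTERANCES.items():
        note = _ASSERTIVE_NOTE if act in ("assertive", "representative") else ""
        add(name, parents or ["Participant Utterance"], act, note)
    for name, (act, parents) in SYSTEM_UTTERANCES.items():
        note = _ASSERTIVE_NOTE if act == "representative" else ""
        add(name, parents or ["System Utterance"], act, note)

    properties = [
        PropertyDescriptor("utteranceLink", "object", "Utterance", "Utterance",
                           symmetric=True),
        PropertyDescriptor("follows", "object", "Utterance", "Utterance",
                           inverse_of="precedes", sub_property_of="utteranceLink"),
        PropertyDescriptor("precedes", "object", "Utterance", "Utterance",
                           inverse_of="follows", sub_property_of="utteranceLink"),
        PropertyDescriptor("speechSegue", "object", "Utterance", "Utterance",
                           sub_property_of="utteranceLink"),
        PropertyDescriptor("belongsToSpeechTask", "object", "Utterance", "Speech Task",
                           inverse_of="hasUtterance"),
        PropertyDescriptor("hasUtterance", "object", "Speech Task", "Utterance",
                           inverse_of="belongsToSpeechTask"),
        PropertyDescriptor("hasGoal", "object", "Discussion", "Goal"),
        PropertyDescriptor("hasSpeechTask", "object", "Communication Goal", "Speech Task"),
    ]
    for name, rng in DATA_PROPERTY_RANGES.items():
        properties.append(PropertyDescriptor(name, "data", "Utterance", rng))

    return OntologySchema(tuple(classes), tuple(properties), iri_base=iri_base)
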