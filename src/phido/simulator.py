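"""Synthetic counseling scripts and participant personas.

Nobody sits at the other end of the wire during testing, so personas
stand in for counseling participants: a cooperative one that always
answers as expected, a confused one that produces gibberish, a refuser,
a repeater, and a questioner with a bounded question budget.  Gibberish
is drawn from a consonant-cluster alphabet disjoint from every example
text, so it is guaranteed (not merely likely) to classify as
unintelligible.

The script generator emits valid dialogue scripts of configurable size,
and :func:`example_script` is the bundled HPV-vaccine counseling script
covering all seven communication goals.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .script import DialogueScript, GOAL_KINDS

__all__ = [
    "ParticipantPolicy",
    "ScriptGenParams",
    "make_policy",
    "generate_script",
    "example_script",
    "PERSONAS",
]

PERSONAS = ("cooperative", "repeater", "confused", "questioner", "refuser")

#: Tokens built from consonant clusters absent from every example text, so
#: token-set overlap with any example is exactly zero.
_GIBBERISH_TOKENS = ("zzqx", "qqvz", "xkcq", "vvzk", "qzzv", "kxqz")


@dataclass
class ParticipantPolicy:
    """A simulated participant.

    Perturbation probabilities are applied where the corresponding
    utterance class is among the expected candidates; otherwise the
    policy answers cooperatively (first example of the highest-priority
    expected utterance).  One private RNG stream per session, seeded via
    :meth:`bind`.
    """

    persona: str = "cooperative"
    p_question: float = 0.0
    p_disconfirm: float = 0.0
    p_gibberish: float = 0.0
    p_repeat: float = 0.0
    question_budget: int = 0
    seed: int = 0
    _rng: random.Random = field(default=None, repr=False)  # type: ignore[assignment]
    _questions_left: int = field(default=0, repr=False)

    def __post_init__(self) -> None:
        if self.persona not in PERSONAS:
            raise ValueError(f"unknown persona {self.persona!r}; expected one of {PERSONAS}")
        for name in ("p_question", "p_disconfirm", "p_gibberish", "p_repeat"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.question_budget < 0:
            raise ValueError("question_budget must be non-negative")
        if self.persona == "cooperative" and any(
            getattr(self, n) > 0 for n in ("p_question", "p_disconfirm", "p_gibberish", "p_repeat")
        ):
            raise ValueError("cooperative persona must have all perturbation probabilities 0")
        if self._rng is None:
            self._rng = random.Random(self.seed)
        self._questions_left = self.question_budget

    def bind(self, seed: int) -> "ParticipantPolicy":
        """Fresh copy with its own RNG stream for one session."""
        return ParticipantPolicy(
            persona=self.persona, p_question=self.p_question,
            p_disconfirm=self.p_disconfirm, p_gibberish=self.p_gibberish,
            p_repeat=self.p_repeat, question_budget=self.question_budget,
            seed=seed,
        )

    # -- responding -----------------------------------------------------
    def _gibberish(self) -> str:
        return " ".join(self._rng.choice(_GIBBERISH_TOKENS) for _ in range(3))

    def respond(self, candidates) -> str:
        """Produce input text for one expected-utterance slot."""
        if not candidates:
            raise ValueError("cannot respond to an empty candidate list")
        by_class = {}
        for c in candidates:
            by_class.setdefault(c.class_name, c)

        if self.persona == "confused" and self._rng.random() < self.p_gibberish:
            return self._gibberish()
        if (self.persona == "questioner" and "Question" in by_class
                and self._questions_left > 0):
            # p_question = 0 means "always, while the budget lasts"
            if self.p_question == 0 or self._rng.random() < self.p_question:
                self._questions_left -= 1
                return by_class["Question"].examples[0]
        if (self.persona == "refuser" and "Disconfirmation" in by_class
                and self._rng.random() < self.p_disconfirm):
            return by_class["Disconfirmation"].examples[0]
        if (self.persona == "repeater" and "Request System Repeat" in by_class
                and self._rng.random() < self.p_repeat):
            return by_class["Request System Repeat"].examples[0]

        # cooperative default: first example of the highest-priority
        # matchable candidate
        for cand in candidates:
            if cand.class_name != "Unintelligible" and cand.examples:
                return cand.examples[0]
        raise ValueError("no matchable candidate to respond to")


_PERSONA_DEFAULTS = {
    "cooperative": {},
    "confused": {"p_gibberish": 1.0},
    "refuser": {"p_disconfirm": 1.0},
    "repeater": {"p_repeat": 0.5},
    "questioner": {"question_budget": 2},
}


def make_policy(persona: str, seed: int = 0, **overrides) -> ParticipantPolicy:
    """Policy with the standard parameterization for a persona."""
    params = dict(_PERSONA_DEFAULTS.get(persona, {}))
    params.update(overrides)
    return ParticipantPolicy(persona=persona, seed=seed, **params)


@dataclass(frozen=True)
class ScriptGenParams:
    """Knobs for the random script generator."""

    n_goals: int = 4
    items_per_topic: int = 2
    vocabulary: tuple[str, ...] = (
        "the vaccine protects against several cancers",
        "the vaccine is highly effective against infection",
        "side effects are usually mild and short lived",
        "two doses are recommended before age fifteen",
        "protection lasts for many years after the doses",
        "the vaccine works best when given early",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_goals < 1:
            raise ValueError("n_goals must be at least 1")
        if self.n_goals > len(GOAL_KINDS):
            raise ValueError(
                f"n_goals must not exceed the {len(GOAL_KINDS)} defined communication goals"
            )
        if self.items_per_topic < 1:
            raise ValueError("items_per_topic must be at least 1")
        if not self.vocabulary:
            raise ValueError("vocabulary must be non-empty")


_MIDDLE_GOALS = (
    "communicate_benefit",
    "communicate_effectiveness",
    "communicate_harms",
    "communicate_uncertainty",
    "pursuit_before_exit",
)


def generate_script(params: ScriptGenParams) -> DialogueScript:
    """Deterministically generate a valid counseling script.

    Always opens with a salutation and closes with a valediction; health
    items are drawn from the vocabulary with a seeded RNG, so the same
    params yield byte-identical scripts.
    """
    rng = random.Random(params.seed)
    goals: list[dict] = []

    first_tasks = [{"task_kind": "salutation", "content": {}}]
    if params.n_goals >= 2:
        first_tasks.append({"task_kind": "initiate_discussion",
                            "content": {"topic_options": ["vaccine facts"]}})
    goals.append({"goal_kind": "acclimate", "tasks": first_tasks})

    middle = list(_MIDDLE_GOALS[: max(0, params.n_goals - 2)])
    for kind in middle:
        if kind == "pursuit_before_exit":
            goals.append({
                "goal_kind": kind,
                "tasks": [{"task_kind": "transition_to_topic",
                           "content": {"transition": "Before you go, may I share "
                                                     "one more important point?"}}],
            })
        else:
            items = [rng.choice(params.vocabulary) for _ in range(params.items_per_topic)]
            goals.append({
                "goal_kind": kind,
                "tasks": [{"task_kind": "discuss_health_topic",
                           "content": {"health_items": items}}],
            })

    if params.n_goals >= 2:
        goals.append({"goal_kind": "conclude",
                      "tasks": [{"task_kind": "valediction", "content": {}}]})
    else:
        goals[0]["tasks"].append({"task_kind": "valediction", "content": {}})

    return DialogueScript.model_validate({
        "title": f"Generated counseling script (seed {params.seed})",
        "goals": goals,
    })


def example_script() -> DialogueScript:
    """The bundled HPV-vaccine counseling script.

    Covers all seven communication goals: acclimation (greeting,
    disclaimer, a short interview, and the question-answering task),
    the four health-belief-model topic goals with talking points, the
    pursuit-before-exit nudge for hesitant participants, and the
    concluding valediction.
    """
    return DialogueScript.model_validate({
        "title": "HPV vaccine counseling",
        "goals": [
            {"goal_kind": "acclimate", "tasks": [
                {"task_kind": "salutation", "content": {
                    "greeting": "Hello! I am a virtual assistant here to talk "
                                "with you about the HPV vaccine.",
                    "introduction": "I can share what is known about the vaccine "
                                    "and answer questions along the way.",
                }},
                {"task_kind": "initiate_discussion", "content": {
                    "disclaimer": "A quick note before we start: I may not cover "
                                  "every concern, so please also raise your "
                                  "questions with your health care provider.",
                    "overview": "We will talk about the benefits of the HPV "
                                "vaccine, how well it works, possible side "
                                "effects, and what is still being studied.",
                    "topic_options": ["benefits", "effectiveness", "side effects",
                                      "open questions"],
                }},
                {"task_kind": "interview_participant", "content": {
                    "interview_questions": ["Before we begin, how are you doing today?"],
                }},
                {"task_kind": "question_answering", "content": {
                    "answers": {
                        "schedule": "The vaccine is usually given as two doses, "
                                    "six to twelve months apart, starting at age "
                                    "eleven or twelve.",
                    },
                }},
            ]},
            {"goal_kind": "communicate_benefit", "tasks": [
                {"task_kind": "discuss_health_topic", "content": {"health_items": [
                    "The HPV vaccine protects against the virus strains that "
                    "cause most cervical and several other cancers.",
                    "Vaccinating early protects both men and women before any "
                    "exposure to the virus.",
                ]}},
            ]},
            {"goal_kind": "communicate_effectiveness", "tasks": [
                {"task_kind": "discuss_health_topic", "content": {"health_items": [
                    "In clinical studies the vaccine prevented nearly all "
                    "infections from the targeted HPV strains.",
                ]}},
            ]},
            {"goal_kind": "communicate_harms", "tasks": [
                {"task_kind": "discuss_health_topic", "content": {"health_items": [
                    "Most side effects are mild: brief soreness, redness, or "
                    "swelling where the shot was given.",
                ]}},
            ]},
            {"goal_kind": "communicate_uncertainty", "tasks": [
                {"task_kind": "discuss_health_topic", "content": {"health_items": [
                    "Researchers are still studying exactly how long protection "
                    "lasts, though current data show it lasting many years.",
                ]}},
            ]},
            {"goal_kind": "pursuit_before_exit", "tasks": [
                {"task_kind": "transition_to_topic", "content": {
                    "transition": "I hear your hesitation. May I share one more "
                                  "point before you decide?",
                }},
            ]},
            {"goal_kind": "conclude", "tasks": [
                {"task_kind": "valediction", "content": {
                    "farewell": "That is everything I wanted to share about the "
                                "HPV vaccine today. Goodbye for now!",
                    "concluding_farewell": "Thank you for talking with me about "
                                           "the HPV vaccine. Take care!",
                }},
            ]},
        ],
    })
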