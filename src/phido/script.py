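"""Declarative counseling scripts.

A dialogue script lists communication goals in order; each goal carries an
ordered list of speech tasks with their content slots (greeting text,
disclaimer, health talking points, interview questions, answer bank, ...).
Scripts are authored in YAML or JSON and validated with pydantic before
compilation into a session graph.
"""

from __future__ import annotations

import json
from typing import Any, Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

__all__ = [
    "TaskSpec",
    "GoalSpec",
    "DialogueScript",
    "ScriptValidationError",
    "load_script",
    "dump_script",
    "script_json_schema",
    "TASK_KINDS",
    "GOAL_KINDS",
]

TASK_KINDS = (
    "salutation",
    "valediction",
    "initiate_discussion",
    "transition_to_topic",
    "interview_participant",
    "discuss_health_topic",
    "question_answering",
)

GOAL_KINDS = (
    "acclimate",
    "conclude",
    "communicate_benefit",
    "communicate_effectiveness",
    "communicate_harms",
    "communicate_uncertainty",
    "pursuit_before_exit",
)

#: snake-case goal kind -> ontology class label
GOAL_CLASS = {
    "acclimate": "Acclimate",
    "conclude": "Conclude",
    "communicate_benefit": "Communicate Benefit",
    "communicate_effectiveness": "Communicate Effectiveness",
    "communicate_harms": "Communicate Harms",
    "communicate_uncertainty": "Communicate Uncertainty",
    "pursuit_before_exit": "Pursuit Before Exit",
}

#: task kind -> speech-task ontology class label
TASK_CLASS = {
    "salutation": "Salutation",
    "valediction": "Valediction",
    "initiate_discussion": "Initiate Discussion",
    "transition_to_topic": "Transition to Topic",
    "interview_participant": "Interview Participant",
    "discuss_health_topic": "Discuss Health Topic",
    "question_answering": "Question and Answering Task",
}


class ScriptValidationError(ValueError):
    """Invalid dialogue script; message lists the offending field path."""


class TaskSpec(BaseModel):
    """One speech task: its kind plus the content slots it consumes."""

    task_kind: Literal[TASK_KINDS]  # type: ignore[valid-type]
    content: dict[str, Any] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_slots(self) -> "TaskSpec":
        if self.task_kind == "discuss_health_topic":
            items = self.content.get("health_items") or []
            if not items:
                raise ValueError(
                    "discuss_health_topic requires at least one entry in "
                    "content.health_items"
                )
        if self.task_kind == "interview_participant":
            qs = self.content.get("interview_questions") or []
            if not qs:
                raise ValueError(
                    "interview_participant requires at least one entry in "
                    "content.interview_questions"
                )
        return self


class GoalSpec(BaseModel):
    """A communication goal and its ordered speech tasks."""

    goal_kind: Literal[GOAL_KINDS]  # type: ignore[valid-type]
    tasks: list[TaskSpec] = Field(min_length=1)


class DialogueScript(BaseModel):
    """A complete counseling script: ordered goals, each with tasks."""

    title: str = "Counseling session"
    goals: list[GoalSpec] = Field(min_length=1)

    @field_validator("goals")
    @classmethod
    def _bookends(cls, goals: list[GoalSpec]) -> list[GoalSpec]:
        kinds = [t.task_kind for g in goals for t in g.tasks]
        for bookend, where in (("salutation", 0), ("valediction", len(kinds) - 1)):
            count = kinds.count(bookend)
            if count > 1:
                raise ValueError(f"{bookend} may appear at most once")
            if count == 1 and kinds.index(bookend) != where:
                place = "first" if bookend == "salutation" else "last"
                raise ValueError(f"{bookend} must be the {place} task when present")
        return goals

    def all_tasks(self) -> list[tuple[int, int, "TaskSpec"]]:
        """(goal index, task index, task) triples in script order."""
        return [(i, j, t) for i, g in enumerate(self.goals) for j, t in enumerate(g.tasks)]


def load_script(document: str, format: str = "yaml") -> DialogueScript:
    """Parse and validate a YAML or JSON script document."""
    if format not in ("yaml", "json"):
        raise ScriptValidationError(f"unknown format {format!r}; expected 'yaml' or 'json'")
    try:
        data = json.loads(document) if format == "json" else yaml.safe_load(document)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ScriptValidationError(f"unparseable {format} document: {exc}") from exc
    if not isinstance(data, dict):
        raise ScriptValidationError("script document must be a mapping at top level")
    try:
        return DialogueScript.model_validate(data)
    except ValidationError as exc:
        paths = "; ".join(
            ".".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in exc.errors()
        )
        raise ScriptValidationError(f"invalid script: {paths}") from exc


def dump_script(script: DialogueScript, format: str = "yaml") -> str:
    """Serialize a script back to YAML or JSON text."""
    data = script.model_dump()
    if format == "json":
        return json.dumps(data, indent=2, sort_keys=True) + "\n"
    return yaml.safe_dump(data, sort_keys=False)


def script_json_schema() -> dict[str, Any]:
    """JSON-Schema document describing the script format."""
    return DialogueScript.model_json_schema()
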