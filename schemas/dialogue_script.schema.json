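{
  "$defs": {
    "GoalSpec": {
      "description": "A communication goal and its ordered speech tasks.",
      "properties": {
        "goal_kind": {
          "enum": [
            "acclimate",
            "conclude",
            "communicate_benefit",
            "communicate_effectiveness",
            "communicate_harms",
            "communicate_uncertainty",
            "pursuit_before_exit"
          ],
          "title": "Goal Kind",
          "type": "string"
        },
        "tasks": {
          "items": {
            "$ref": "#/$defs/TaskSpec"
          },
          "minItems": 1,
          "title": "Tasks",
          "type": "array"
        }
      },
      "required": [
        "goal_kind",
        "tasks"
      ],
      "title": "GoalSpec",
      "type": "object"
    },
    "TaskSpec": {
      "description": "One speech task: its kind plus the content slots it consumes.",
      "properties": {
        "content": {
          "additionalProperties": true,
          "title": "Content",
          "type": "object"
        },
        "task_kind": {
          "enum": [
            "salutation",
            "valediction",
            "initiate_discussion",
            "transition_to_topic",
            "interview_participant",
            "discuss_health_topic",
            "question_answering"
          ],
          "title": "Task Kind",
          "type": "string"
        }
      },
      "required": [
        "task_kind"
      ],
      "title": "TaskSpec",
      "type": "object"
    }
  },
  "description": "A complete counseling script: ordered goals, each with tasks.",
  "properties": {
    "goals": {
      "items": {
        "$ref": "#/$defs/GoalSpec"
      },
      "minItems": 1,
      "title": "Goals",
      "type": "array"
    },
    "title": {
      "default": "Counseling session",
      "title": "Title",
      "type": "string"
    }
  },
  "required": [
    "goals"
  ],
  "title": "DialogueScript",
  "type": "object"
}
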