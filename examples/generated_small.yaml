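title: Generated counseling script (seed 42)
goals:
- goal_kind: acclimate
  tasks:
  - task_kind: salutation
    content: {}
  - task_kind: initiate_discussion
    content:
      topic_options:
      - vaccine facts
- goal_kind: communicate_benefit
  tasks:
  - task_kind: discuss_health_topic
    content:
      health_items:
      - the vaccine works best when given early
      - the vaccine protects against several cancers
- goal_kind: communicate_effectiveness
  tasks:
  - task_kind: discuss_health_topic
    content:
      health_items:
      - the vaccine protects against several cancers
      - the vaccine works best when given early
- goal_kind: conclude
  tasks:
  - task_kind: valediction
    content: {}
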