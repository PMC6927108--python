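title: HPV vaccine counseling
goals:
- goal_kind: acclimate
  tasks:
  - task_kind: salutation
    content:
      greeting: Hello! I am a virtual assistant here to talk with you about the HPV
        vaccine.
      introduction: I can share what is known about the vaccine and answer questions
        along the way.
  - task_kind: initiate_discussion
    content:
      disclaimer: 'A quick note before we start: I may not cover every concern, so
        please also raise your questions with your health care provider.'
      overview: We will talk about the benefits of the HPV vaccine, how well it works,
        possible side effects, and what is still being studied.
      topic_options:
      - benefits
      - effectiveness
      - side effects
      - open questions
  - task_kind: interview_participant
    content:
      interview_questions:
      - Before we begin, how are you doing today?
  - task_kind: question_answering
    content:
      answers:
        schedule: The vaccine is usually given as two doses, six to twelve months
          apart, starting at age eleven or twelve.
- goal_kind: communicate_benefit
  tasks:
  - task_kind: discuss_health_topic
    content:
      health_items:
      - The HPV vaccine protects against the virus strains that cause most cervical
        and several other cancers.
      - Vaccinating early protects both men and women before any exposure to the virus.
- goal_kind: communicate_effectiveness
  tasks:
  - task_kind: discuss_health_topic
    content:
      health_items:
      - In clinical studies the vaccine prevented nearly all infections from the targeted
        HPV strains.
- goal_kind: communicate_harms
  tasks:
  - task_kind: discuss_health_topic
    content:
      health_items:
      - 'Most side effects are mild: brief soreness, redness, or swelling where the
        shot was given.'
- goal_kind: communicate_uncertainty
  tasks:
  - task_kind: discuss_health_topic
    content:
      health_items:
      - Researchers are still studying exactly how long protection lasts, though current
        data show it lasting many years.
- goal_kind: pursuit_before_exit
  tasks:
  - task_kind: transition_to_topic
    content:
      transition: I hear your hesitation. May I share one more point before you decide?
- goal_kind: conclude
  tasks:
  - task_kind: valediction
    content:
      farewell: That is everything I wanted to share about the HPV vaccine today.
        Goodbye for now!
      concluding_farewell: Thank you for talking with me about the HPV vaccine. Take
        care!
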