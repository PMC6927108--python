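"""Task templates, task linking, and A-Box serialization."""

from collections import Counter

import pytest

from phido.script import load_script
from phido.session import (
    PRECEDES,
    SEGUE,
    SessionError,
    compile_script,
    instantiate_task,
    link_tasks,
    load_session,
    serialize_session,
)


def class_edges(frag):
    """Edge set lifted from instance ids to class labels."""
    cls = {i.id: i.class_name for i in frag.instances}
    return {(cls[s], k, cls[d]) for (s, k, d) in frag.edges}


# Frozen golden templates: node-class multiset and class-level edge set
# for each speech-task kind.
GOLDEN = {
    "salutation": (
        {"System Greet": 1, "Reciprocal Greet": 1, "Unintelligible": 1,
         "Request Repeat": 1, "System Introduction": 1},
        {("System Greet", PRECEDES, "Reciprocal Greet"),
         ("System Greet", PRECEDES, "Unintelligible"),
         ("Unintelligible", PRECEDES, "Request Repeat"),
         ("Request Repeat", PRECEDES, "Reciprocal Greet"),
         ("Request Repeat", PRECEDES, "Unintelligible"),
         ("Reciprocal Greet", PRECEDES, "System Introduction")},
    ),
    "valediction": (
        {"System Farewell": 1, "Reciprocal Farewell": 1, "Unintelligible": 1,
         "Request Repeat": 1, "Concluding Farewell": 1},
        {("System Farewell", PRECEDES, "Reciprocal Farewell"),
         ("System Farewell", PRECEDES, "Unintelligible"),
         ("Unintelligible", PRECEDES, "Request Repeat"),
         ("Request Repeat", PRECEDES, "Reciprocal Farewell"),
         ("Request Repeat", PRECEDES, "Unintelligible"),
         ("Reciprocal Farewell", PRECEDES, "Concluding Farewell")},
    ),
    "initiate_discussion": (
        {"Disclaimer": 1, "Confirmation": 1, "Unintelligible": 1,
         "Request Repeat": 1, "Overview": 1, "Topic Options": 1},
        {("Disclaimer", PRECEDES, "Confirmation"),
         ("Disclaimer", PRECEDES, "Unintelligible"),
         ("Unintelligible", PRECEDES, "Request Repeat"),
         ("Request Repeat", PRECEDES, "Confirmation"),
         ("Request Repeat", PRECEDES, "Unintelligible"),
         ("Confirmation", PRECEDES, "Overview"),
         ("Overview", PRECEDES, "Topic Options")},
    ),
    "transition_to_topic": (
        {"Topic Transition": 1, "Confirmation": 1, "Unintelligible": 1,
         "Disconfirmation": 1, "Request Repeat": 1},
        {("Topic Transition", PRECEDES, "Confirmation"),
         ("Topic Transition", PRECEDES, "Unintelligible"),
         ("Topic Transition", PRECEDES, "Disconfirmation"),
         ("Unintelligible", PRECEDES, "Request Repeat"),
         ("Request Repeat", PRECEDES, "Confirmation"),
         ("Request Repeat", PRECEDES, "Unintelligible"),
         ("Request Repeat", PRECEDES, "Disconfirmation")},
    ),
    "interview_participant": (
        {"Interview Question": 1, "Positive Personal Status": 1,
         "Negative Personal Status": 1, "Acknowledgment": 1},
        {("Interview Question", PRECEDES, "Positive Personal Status"),
         ("Interview Question", PRECEDES, "Negative Personal Status"),
         ("Positive Personal Status", PRECEDES, "Acknowledgment"),
         ("Negative Personal Status", PRECEDES, "Acknowledgment")},
    ),
    "discuss_health_topic": (
        {"Health Information": 1, "Confirm Health Information": 1,
         "Confirmation": 1, "Request System Repeat": 1, "Question": 1,
         "Disconfirmation": 1, "Unintelligible": 1, "Request Repeat": 1},
        {("Health Information", PRECEDES, "Confirm Health Information"),
         ("Confirm Health Information", PRECEDES, "Confirmation"),
         ("Confirm Health Information", PRECEDES, "Request System Repeat"),
         ("Confirm Health Information", PRECEDES, "Question"),
         ("Confirm Health Information", PRECEDES, "Disconfirmation"),
         ("Confirm Health Information", PRECEDES, "Unintelligible"),
         ("Request System Repeat", PRECEDES, "Health Information"),
         ("Unintelligible", PRECEDES, "Request Repeat"),
         ("Request Repeat", PRECEDES, "Confirmation"),
         ("Request Repeat", PRECEDES, "Request System Repeat"),
         ("Request Repeat", PRECEDES, "Question"),
         ("Request Repeat", PRECEDES, "Disconfirmation"),
         ("Request Repeat", PRECEDES, "Unintelligible")},
    ),
    "question_answering": (
        {"Question": 1, "Answer": 1, "No Answer": 1, "Question Options": 1,
         "Disconfirmation": 1},
        {("Question", PRECEDES, "Answer"),
         ("Question", PRECEDES, "No Answer"),
         ("Answer", PRECEDES, "Question Options"),
         ("No Answer", PRECEDES, "Question Options"),
         ("Question Options", PRECEDES, "Disconfirmation"),
         ("Question Options", PRECEDES, "Question")},
    ),
}

CONTENT = {
    "salutation": {},
    "valediction": {},
    "initiate_discussion": {"topic_options": ["benefits"]},
    "transition_to_topic": {},
    "interview_participant": {"interview_questions": ["How are you?"]},
    "discuss_health_topic": {"health_items": ["vaccines work"]},
    "question_answering": {"answers": {"why": "because it protects you"}},
}


class TestTemplates:
    @pytest.mark.parametrize("kind", sorted(GOLDEN))
    def test_template_conformance(self, kind):
        frag = instantiate_task(kind, CONTENT[kind], "t")
        nodes, edges = GOLDEN[kind]
        assert Counter(i.class_name for i in frag.instances) == Counter(nodes)
        assert class_edges(frag) == edges

    def test_salutation_candidates_after_greet(self, schema):
        frag = instantiate_task("salutation", {}, "t")
        cls = {i.id: i.class_name for i in frag.instances}
        after = sorted(cls[d] for (s, k, d) in frag.edges
                       if cls[s] == "System Greet" and k == PRECEDES)
        assert after == ["Reciprocal Greet", "Unintelligible"]

    def test_discuss_with_three_items_chains_three_deliveries(self):
        frag = instantiate_task(
            "discuss_health_topic", {"health_items": ["a b", "c d", "e f"]}, "t")
        his = [i for i in frag.instances if i.class_name == "Health Information"]
        assert len(his) == 3
        # each confirmation but the last chains into the next delivery
        cls = {i.id: i.class_name for i in frag.instances}
        chain = [(s, d) for (s, k, d) in frag.edges
                 if k == PRECEDES and cls[s] == "Confirmation"
                 and cls[d] == "Health Information"]
        assert len(chain) == 2

    def test_question_answering_empty_answers_routes_to_no_answer(self):
        frag = instantiate_task("question_answering", {}, "t")
        cls = {i.id: i.class_name for i in frag.instances}
        assert "Answer" not in cls.values()
        after_q = {cls[d] for (s, k, d) in frag.edges
                   if cls[s] == "Question" and k == PRECEDES}
        assert after_q == {"No Answer"}

    def test_missing_slot_names_slot_and_kind(self):
        with pytest.raises(SessionError, match="health_items"):
            instantiate_task("discuss_health_topic", {}, "t")

    def test_unknown_kind_names_allowed_kinds(self):
        with pytest.raises(SessionError, match="salutation"):
            instantiate_task("chitchat", {}, "t")


TWO_TASKS = """
goals:
  - goal_kind: acclimate
    tasks:
      - task_kind: salutation
  - goal_kind: conclude
    tasks:
      - task_kind: valediction
"""


class TestLinking:
    def test_two_task_script_has_one_happy_path_segue(self, schema):
        graph = link_tasks(load_script(TWO_TASKS), schema)
        segues = [e for e in graph.edges if e[1] == SEGUE]
        assert len(segues) == 1
        src, _, dst = segues[0]
        assert graph.instances[src].class_name == "System Introduction"
        assert graph.instances[dst].class_name == "System Farewell"

    def test_exactly_one_initial_focus_and_nothing_said(self, hpv_graph):
        assert len(hpv_graph.focus_instances()) == 1
        assert hpv_graph.focus_instances()[0].class_name == "System Greet"
        assert not any(i.been_said for i in hpv_graph.instances.values())

    def test_every_instance_belongs_to_exactly_one_task(self, hpv_graph):
        assert set(hpv_graph.task_membership) == set(hpv_graph.instances)
        assert set(hpv_graph.task_membership.values()) <= set(hpv_graph.tasks)

    def test_disconfirmations_segue_to_pursuit_goal_entry(self, hpv_graph):
        pursuit_goals = [g for g, cls in hpv_graph.goals.items()
                         if cls == "Pursuit Before Exit"]
        assert len(pursuit_goals) == 1
        pursuit_tasks = {t for t, g in hpv_graph.task_goal.items()
                         if g == pursuit_goals[0]}
        for inst in hpv_graph.by_class("Disconfirmation"):
            task = hpv_graph.task_membership[inst.id]
            if task in pursuit_tasks or hpv_graph.tasks[task] == "Question and Answering Task":
                continue
            targets = hpv_graph.segue_targets(inst.id)
            assert len(targets) == 1
            assert hpv_graph.task_membership[targets[0].id] in pursuit_tasks

    def test_questions_segue_to_question_answering_task(self, hpv_graph):
        qa_tasks = {t for t, cls in hpv_graph.tasks.items()
                    if cls == "Question and Answering Task"}
        assert len(qa_tasks) == 1
        for inst in hpv_graph.by_class("Question"):
            if hpv_graph.task_membership[inst.id] in qa_tasks:
                continue
            targets = hpv_graph.segue_targets(inst.id)
            assert [hpv_graph.task_membership[t.id] for t in targets] == list(qa_tasks)

    def test_segues_leave_terminal_nodes_only(self, hpv_graph):
        assert hpv_graph.validate() == []

    def test_inverse_closure_follows_iff_precedes(self, hpv_graph):
        graph = hpv_graph
        assert len(graph.instances) <= 200
        for a in graph.instances:
            for b in graph.instances:
                stored = (a, PRECEDES, b) in graph.edges
                derived = any(i.id == a for i in graph.follows(b))
                assert stored == derived


class TestSerialization:
    @pytest.mark.parametrize("dialect", ["turtle", "rdfxml"])
    def test_round_trip_identity(self, hpv_graph, dialect):
        text = serialize_session(hpv_graph, dialect)
        assert load_session(text, dialect, hpv_graph.schema) == hpv_graph

    def test_triple_count_matches_hand_computation(self, hpv_graph):
        from rdflib import Graph
        g = Graph()
        g.parse(data=serialize_session(hpv_graph, "turtle"), format="turtle")
        expected = 0
        for inst in hpv_graph.instances.values():
            expected += 6  # type, label, priority, been_said, focus, task link
            expected += 1 if inst.utterance_string else 0
            expected += len(inst.examples)
        expected += len(hpv_graph.edges)
        expected += len(hpv_graph.tasks) + len(hpv_graph.goals) + 1  # rdf:type
        expected += len(hpv_graph.task_goal) + len(hpv_graph.goal_discussion)
        expected += len(hpv_graph.resume_map)
        assert len(g) == expected

    def test_dangling_edge_target_rejected(self, hpv_graph):
        text = serialize_session(hpv_graph, "turtle")
        broken = text + "\nsession:ghost phido:precedes session:ghost2 .\n"
        with pytest.raises(SessionError, match="dangling"):
            load_session(broken, "turtle", hpv_graph.schema)

    def test_unknown_instance_class_rejected(self, hpv_graph):
        text = serialize_session(hpv_graph, "turtle").replace(
            "phido:SystemGreet", "phido:MysteryClass", 1)
        with pytest.raises(SessionError, match="MysteryClass"):
            load_session(text, "turtle", hpv_graph.schema)

    def test_compile_script_validates(self, hpv_script, schema):
        graph = compile_script(hpv_script, schema)
        assert graph.validate() == []
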