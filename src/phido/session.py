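"""Instance-level session graphs (the A-Box).

A session graph holds utterance instances populated from a dialogue
script, linked by ``precedes`` edges inside each speech task and by
``speechSegue`` edges between tasks.  ``follows`` is never stored: it is
the declared inverse of ``precedes`` and is answered by querying the
stored edges backwards.

Each of the seven speech-task kinds has a fixed utterance template; the
compiler instantiates the template per task, chains the tasks with segues
in script order, and wires the off-path transitions (participant question
-> question-answering task; disconfirmation -> pursuit-before-exit nudge,
then valediction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from rdflib import Graph, Literal, Namespace, RDF, RDFS, OWL, XSD, URIRef

from .builder import build_schema
from .schema import OntologySchema, camel_case
from .script import DialogueScript, GOAL_CLASS, TASK_CLASS

__all__ = [
    "UtteranceInstance",
    "SessionGraph",
    "TaskFragment",
    "SessionError",
    "instantiate_task",
    "link_tasks",
    "compile_script",
    "serialize_session",
    "load_session",
    "PARTICIPANT_EXAMPLES",
]

PRECEDES = "precedes"
SEGUE = "speechSegue"


class SessionError(ValueError):
    """Malformed session graph or template content."""


#: Default example texts for participant utterance classes; these feed the
#: Jaccard similarity matcher, so each class gets a few paraphrases.
PARTICIPANT_EXAMPLES: dict[str, list[str]] = {
    "Reciprocal Greet": ["hello there", "hi good morning", "hey hello"],
    "Reciprocal Farewell": ["goodbye now", "bye take care", "goodbye thank you"],
    "Confirmation": ["yes", "yes i understand", "okay that makes sense", "sure go ahead"],
    "Disconfirmation": ["no", "no i disagree with that", "no thanks not interested"],
    "Request System Repeat": [
        "could you say that again please",
        "please repeat that information",
        "say that again",
    ],
    "Question": [
        "i have a question",
        "can i ask a question about that",
        "what does that mean exactly",
    ],
    "Positive Personal Status": ["i am doing well today", "pretty good thanks"],
    "Negative Personal Status": ["not so well today", "i have been feeling bad"],
    # Placeholder; unintelligible input is whatever fails to match the
    # other candidates, so these examples are never scored.
    "Unintelligible": ["<unintelligible>"],
}

_SYSTEM_DEFAULTS = {
    "greeting": "Hello! I am a virtual assistant here to talk with you about your health.",
    "introduction": "Let me introduce myself: I can share health information and answer questions.",
    "farewell": "That is everything I had to share today. Goodbye for now!",
    "concluding_farewell": "Thank you for talking with me. Take care!",
    "disclaimer": (
        "Before we begin: I may not cover every concern, so please also "
        "bring your questions to your health care provider."
    ),
    "overview": "Today we will go over some key facts, and you can ask questions at any time.",
    "request_repeat": "I'm sorry, I didn't catch that. Could you say it again?",
    "confirm": "Does that make sense to you?",
    "acknowledgment": "Thank you for sharing that with me.",
    "no_answer": "I'm sorry, I don't have an answer for that question, but your provider will.",
    "question_options": "Do you have any more questions?",
    "transition": "Now I would like to move on to the next topic. Is that all right?",
}


@dataclass
class UtteranceInstance:
    """One utterance node with its data-property values."""

    id: str
    class_name: str
    utterance_string: str = ""
    examples: list[str] = field(default_factory=list)
    priority: int = 0
    been_said: bool = False
    focus: bool = False

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UtteranceInstance):
            return NotImplemented
        # example order is not significant (RDF serialization is unordered)
        return (
            (self.id, self.class_name, self.utterance_string, self.priority,
             self.been_said, self.focus, sorted(self.examples))
            == (other.id, other.class_name, other.utterance_string, other.priority,
                other.been_said, other.focus, sorted(other.examples))
        )


@dataclass
class SessionGraph:
    """Utterance instances, their edges, and the task/goal grouping."""

    schema: OntologySchema = field(default_factory=build_schema, repr=False)
    instances: dict[str, UtteranceInstance] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)  # (src, kind, dst)
    tasks: dict[str, str] = field(default_factory=dict)  # task id -> task class label
    task_membership: dict[str, str] = field(default_factory=dict)  # instance -> task
    goals: dict[str, str] = field(default_factory=dict)  # goal id -> goal class label
    task_goal: dict[str, str] = field(default_factory=dict)  # task id -> goal id
    goal_discussion: dict[str, str] = field(default_factory=dict)  # goal id -> discussion id
    discussion_id: str = "discussion"
    #: return addresses for off-path transitions: the node whose segue is
    #: taken -> the node to resume through when the excursion finishes
    resume_map: dict[str, str] = field(default_factory=dict)

    # -- structure queries ----------------------------------------------
    def add_instance(self, inst: UtteranceInstance, task_id: str) -> None:
        if inst.id in self.instances:
            raise SessionError(f"duplicate instance id {inst.id!r}")
        self.instances[inst.id] = inst
        self.task_membership[inst.id] = task_id

    def followers(self, node_id: str) -> list[UtteranceInstance]:
        """Instances one ``precedes`` step ahead, by priority then id."""
        out = [self.instances[d] for (s, k, d) in self.edges if s == node_id and k == PRECEDES]
        return sorted(out, key=lambda i: (i.priority, i.id))

    def follows(self, node_id: str) -> list[UtteranceInstance]:
        """Inverse query: instances this one follows (derived, not stored)."""
        out = [self.instances[s] for (s, k, d) in self.edges if d == node_id and k == PRECEDES]
        return sorted(out, key=lambda i: (i.priority, i.id))

    def segue_targets(self, node_id: str) -> list[UtteranceInstance]:
        out = [self.instances[d] for (s, k, d) in self.edges if s == node_id and k == SEGUE]
        return sorted(out, key=lambda i: (i.priority, i.id))

    def focus_instances(self) -> list[UtteranceInstance]:
        return [i for i in self.instances.values() if i.focus]

    def is_system(self, inst: UtteranceInstance) -> bool:
        return self.schema.is_a(inst.class_name, "System Utterance")

    def is_participant(self, inst: UtteranceInstance) -> bool:
        return self.schema.is_a(inst.class_name, "Participant Utterance")

    def by_class(self, class_name: str) -> list[UtteranceInstance]:
        return sorted(
            (i for i in self.instances.values() if i.class_name == class_name),
            key=lambda i: i.id,
        )

    def copy(self) -> "SessionGraph":
        return SessionGraph(
            schema=self.schema,
            instances={k: replace(v, examples=list(v.examples)) for k, v in self.instances.items()},
            edges=set(self.edges),
            tasks=dict(self.tasks),
            task_membership=dict(self.task_membership),
            goals=dict(self.goals),
            task_goal=dict(self.task_goal),
            goal_discussion=dict(self.goal_discussion),
            discussion_id=self.discussion_id,
            resume_map=dict(self.resume_map),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SessionGraph):
            return NotImplemented
        return (
            self.instances == other.instances
            and self.edges == other.edges
            and self.tasks == other.tasks
            and self.task_membership == other.task_membership
            and self.goals == other.goals
            and self.task_goal == other.task_goal
            and self.goal_discussion == other.goal_discussion
            and self.discussion_id == other.discussion_id
            and self.resume_map == other.resume_map
        )

    def validate(self) -> list[str]:
        """Structural invariant check; returns human-readable problems."""
        problems = []
        for (s, k, d) in self.edges:
            for end in (s, d):
                if end not in self.instances:
                    problems.append(f"edge {s}->{d} references unknown instance {end!r}")
        for iid, inst in self.instances.items():
            if inst.class_name not in self.schema.class_map:
                problems.append(f"instance {iid} has unknown class {inst.class_name!r}")
            elif not self.schema.is_a(inst.class_name, "Utterance"):
                problems.append(f"instance {iid} class {inst.class_name!r} is not an Utterance")
            elif self.is_system(inst) and not inst.utterance_string:
                problems.append(f"system instance {iid} has empty utterance string")
            elif self.is_participant(inst) and not inst.examples:
                problems.append(f"participant instance {iid} has no examples")
            if iid not in self.task_membership:
                problems.append(f"instance {iid} belongs to no speech task")
        n_focus = len(self.focus_instances())
        if n_focus != 1:
            problems.append(f"expected exactly one focus instance, found {n_focus}")
        # segues only leave task-terminal nodes and enter another task
        for (s, k, d) in self.edges:
            if k != SEGUE:
                continue
            if any(e[0] == s and e[1] == PRECEDES for e in self.edges):
                problems.append(f"segue from non-terminal node {s}")
            if self.task_membership.get(s) == self.task_membership.get(d):
                problems.append(f"segue {s}->{d} stays inside one task")
        return problems


@dataclass
class TaskFragment:
    """One instantiated speech-task template plus its wiring hooks."""

    task_id: str
    task_class: str
    instances: list[UtteranceInstance]
    edges: set[tuple[str, str, str]]
    entry: str
    exits: list[str]  # happy-path terminals that take the inter-task segue
    #: (question node, resume-through node) pairs -> question-answering task
    question_hooks: list[tuple[str, str]] = field(default_factory=list)
    #: (disconfirmation node, resume-through node) pairs -> goal handling
    disconfirm_hooks: list[tuple[str, str]] = field(default_factory=list)
    #: terminal that pops the return-address stack instead of a static segue
    pop_exits: list[str] = field(default_factory=list)


def _participant(nid: str, class_name: str, priority: int,
                 examples: list[str] | None = None) -> UtteranceInstance:
    ex = examples if examples is not None else PARTICIPANT_EXAMPLES[class_name]
    return UtteranceInstance(nid, class_name, examples=list(ex), priority=priority)


def _system(nid: str, class_name: str, text: str, priority: int = 0) -> UtteranceInstance:
    return UtteranceInstance(nid, class_name, utterance_string=text, priority=priority)


def _require(content: dict, slot: str, kind: str):
    value = content.get(slot)
    if not value:
        raise SessionError(f"task kind {kind!r} requires content slot {slot!r}")
    return value


def instantiate_task(kind: str, content: dict, id_prefix: str) -> TaskFragment:
    """Build the utterance subgraph for one speech task.

    ``content`` fills the system-side text slots; participant nodes get
    the default example sets unless overridden via ``content['examples']``
    (a class-label -> list-of-strings map).
    """
    if kind not in TASK_CLASS:
        raise SessionError(
            f"unknown task kind {kind!r}; allowed kinds: {', '.join(TASK_CLASS)}"
        )
    overrides = content.get("examples", {})

    def part(nid, cls, prio):
        return _participant(nid, cls, prio, overrides.get(cls))

    p = id_prefix
    nodes: list[UtteranceInstance] = []
    edges: set[tuple[str, str, str]] = set()

    def pe(a, b):
        edges.add((a, PRECEDES, b))

    if kind == "salutation":
        greet = _system(f"{p}.greet", "System Greet",
                        content.get("greeting", _SYSTEM_DEFAULTS["greeting"]))
        rg = part(f"{p}.reciprocal_greet", "Reciprocal Greet", 0)
        un = part(f"{p}.unintelligible", "Unintelligible", 1)
        rr = _system(f"{p}.request_repeat", "Request Repeat",
                     content.get("request_repeat", _SYSTEM_DEFAULTS["request_repeat"]))
        intro = _system(f"{p}.introduction", "System Introduction",
                        content.get("introduction", _SYSTEM_DEFAULTS["introduction"]))
        nodes += [greet, rg, un, rr, intro]
        pe(greet.id, rg.id); pe(greet.id, un.id)
        pe(un.id, rr.id); pe(rr.id, rg.id); pe(rr.id, un.id)
        pe(rg.id, intro.id)
        entry, exits = greet.id, [intro.id]

    elif kind == "valediction":
        fw = _system(f"{p}.farewell", "System Farewell",
                     content.get("farewell", _SYSTEM_DEFAULTS["farewell"]))
        rf = part(f"{p}.reciprocal_farewell", "Reciprocal Farewell", 0)
        un = part(f"{p}.unintelligible", "Unintelligible", 1)
        rr = _system(f"{p}.request_repeat", "Request Repeat",
                     content.get("request_repeat", _SYSTEM_DEFAULTS["request_repeat"]))
        cf = _system(f"{p}.concluding_farewell", "Concluding Farewell",
                     content.get("concluding_farewell", _SYSTEM_DEFAULTS["concluding_farewell"]))
        nodes += [fw, rf, un, rr, cf]
        pe(fw.id, rf.id); pe(fw.id, un.id)
        pe(un.id, rr.id); pe(rr.id, rf.id); pe(rr.id, un.id)
        pe(rf.id, cf.id)
        entry, exits = fw.id, []  # Concluding Farewell ends the session

    elif kind == "initiate_discussion":
        disc = _system(f"{p}.disclaimer", "Disclaimer",
                       content.get("disclaimer", _SYSTEM_DEFAULTS["disclaimer"]))
        conf = part(f"{p}.confirmation", "Confirmation", 0)
        un = part(f"{p}.unintelligible", "Unintelligible", 1)
        rr = _system(f"{p}.request_repeat", "Request Repeat",
                     content.get("request_repeat", _SYSTEM_DEFAULTS["request_repeat"]))
        over = _system(f"{p}.overview", "Overview",
                       content.get("overview", _SYSTEM_DEFAULTS["overview"]))
        options = content.get("topic_options", [])
        opt_text = "We can talk about: " + "; ".join(options) + "." if options \
            else "Shall we get started with the first topic?"
        topt = _system(f"{p}.topic_options", "Topic Options", opt_text)
        nodes += [disc, conf, un, rr, over, topt]
        pe(disc.id, conf.id); pe(disc.id, un.id)
        pe(un.id, rr.id); pe(rr.id, conf.id); pe(rr.id, un.id)
        pe(conf.id, over.id); pe(over.id, topt.id)
        entry, exits = disc.id, [topt.id]

    elif kind == "transition_to_topic":
        tt = _system(f"{p}.topic_transition", "Topic Transition",
                     content.get("transition", _SYSTEM_DEFAULTS["transition"]))
        conf = part(f"{p}.confirmation", "Confirmation", 0)
        un = part(f"{p}.unintelligible", "Unintelligible", 1)
        dis = part(f"{p}.disconfirmation", "Disconfirmation", 2)
        rr = _system(f"{p}.request_repeat", "Request Repeat",
                     content.get("request_repeat", _SYSTEM_DEFAULTS["request_repeat"]))
        nodes += [tt, conf, un, dis, rr]
        pe(tt.id, conf.id); pe(tt.id, un.id); pe(tt.id, dis.id)
        pe(un.id, rr.id); pe(rr.id, conf.id); pe(rr.id, un.id); pe(rr.id, dis.id)
        entry, exits = tt.id, [conf.id]
        return TaskFragment(p, TASK_CLASS[kind], nodes, edges, entry, exits,
                            disconfirm_hooks=[(dis.id, conf.id)])

    elif kind == "interview_participant":
        questions = _require(content, "interview_questions", kind)
        prev_ack = None
        first = None
        for i, q in enumerate(questions):
            iq = _system(f"{p}.q{i}.interview_question", "Interview Question", q)
            pos = part(f"{p}.q{i}.positive_status", "Positive Personal Status", 0)
            neg = part(f"{p}.q{i}.negative_status", "Negative Personal Status", 1)
            ack = _system(f"{p}.q{i}.acknowledgment", "Acknowledgment",
                          content.get("acknowledgment", _SYSTEM_DEFAULTS["acknowledgment"]))
            nodes += [iq, pos, neg, ack]
            pe(iq.id, pos.id); pe(iq.id, neg.id)
            pe(pos.id, ack.id); pe(neg.id, ack.id)
            if prev_ack is not None:
                pe(prev_ack, iq.id)
            else:
                first = iq.id
            prev_ack = ack.id
        entry, exits = first, [prev_ack]

    elif kind == "discuss_health_topic":
        items = _require(content, "health_items", kind)
        question_hooks, disconfirm_hooks = [], []
        prev_conf = None
        first = None
        for i, item in enumerate(items):
            hi = _system(f"{p}.i{i}.health_information", "Health Information", item)
            chi = _system(f"{p}.i{i}.confirm", "Confirm Health Information",
                          content.get("confirm", _SYSTEM_DEFAULTS["confirm"]))
            conf = part(f"{p}.i{i}.confirmation", "Confirmation", 0)
            rsr = part(f"{p}.i{i}.request_system_repeat", "Request System Repeat", 1)
            q = part(f"{p}.i{i}.question", "Question", 2)
            dis = part(f"{p}.i{i}.disconfirmation", "Disconfirmation", 3)
            un = part(f"{p}.i{i}.unintelligible", "Unintelligible", 4)
            rr = _system(f"{p}.i{i}.request_repeat", "Request Repeat",
                         content.get("request_repeat", _SYSTEM_DEFAULTS["request_repeat"]))
            nodes += [hi, chi, conf, rsr, q, dis, un, rr]
            pe(hi.id, chi.id)
            for c in (conf, rsr, q, dis, un):
                pe(chi.id, c.id)
            pe(rsr.id, hi.id)  # re-deliver the same piece of information
            pe(un.id, rr.id)
            for c in (conf, rsr, q, dis, un):
                pe(rr.id, c.id)
            if prev_conf is not None:
                pe(prev_conf, hi.id)
            else:
                first = hi.id
            question_hooks.append((q.id, conf.id))
            disconfirm_hooks.append((dis.id, conf.id))
            prev_conf = conf.id
        return TaskFragment(p, TASK_CLASS[kind], nodes, edges, first, [prev_conf],
                            question_hooks=question_hooks,
                            disconfirm_hooks=disconfirm_hooks)

    elif kind == "question_answering":
        answers = content.get("answers") or {}
        q = part(f"{p}.question", "Question", 0)
        na = _system(f"{p}.no_answer", "No Answer",
                     content.get("no_answer", _SYSTEM_DEFAULTS["no_answer"]), priority=1)
        qo = _system(f"{p}.question_options", "Question Options",
                     content.get("question_options", _SYSTEM_DEFAULTS["question_options"]))
        # proceed branch outranks the loop so an out-of-questions
        # participant defaults to moving on
        dis = part(f"{p}.disconfirmation", "Disconfirmation", 0)
        nodes += [q, na, qo, dis]
        if answers:
            text = " ".join(str(v) for v in answers.values())
            ans = _system(f"{p}.answer", "Answer", text, priority=0)
            nodes.append(ans)
            pe(q.id, ans.id)
            pe(ans.id, qo.id)
        pe(q.id, na.id)
        pe(na.id, qo.id)
        pe(qo.id, dis.id)
        q_loop = replace(q, priority=1)  # re-ask enters the same node
        nodes[0] = q_loop
        pe(qo.id, q.id)
        entry = q.id
        return TaskFragment(p, TASK_CLASS[kind], nodes, edges, entry, exits=[],
                            pop_exits=[dis.id])

    else:  # pragma: no cover - guarded above
        raise SessionError(f"unknown task kind {kind!r}")

    return TaskFragment(p, TASK_CLASS[kind], nodes, edges, entry, exits)


def link_tasks(script: DialogueScript, schema: OntologySchema | None = None) -> SessionGraph:
    """Compile a validated script into one linked session graph.

    Tasks are chained with ``speechSegue`` edges in script order; tasks of
    the question-answering kind and tasks under a pursuit-before-exit goal
    sit off the happy path and are entered only through participant
    Question or Disconfirmation utterances.  Initial focus lands on the
    first system utterance of the first on-path task.
    """
    graph = SessionGraph(schema=schema or build_schema())
    fragments: list[tuple[str, str, TaskFragment]] = []  # (goal_id, goal_kind, fragment)

    for gi, goal in enumerate(script.goals):
        goal_id = f"g{gi}"
        graph.goals[goal_id] = GOAL_CLASS[goal.goal_kind]
        graph.goal_discussion[goal_id] = graph.discussion_id
        for ti, task in enumerate(goal.tasks):
            frag = instantiate_task(task.task_kind, task.content, f"{goal_id}.t{ti}")
            fragments.append((goal_id, goal.goal_kind, frag))

    qa_frag = next(
        (f for _, _, f in fragments if f.task_class == "Question and Answering Task"), None
    )
    needs_qa = any(f.question_hooks for _, _, f in fragments)
    if qa_frag is None and needs_qa:
        # default question-answering task so Question segues always land
        qa_frag = instantiate_task("question_answering", {}, "g0.qa")
        fragments.insert(1 if fragments else 0, ("g0", script.goals[0].goal_kind, qa_frag))

    for goal_id, _, frag in fragments:
        graph.tasks[frag.task_id] = frag.task_class
        graph.task_goal[frag.task_id] = goal_id
        for inst in frag.instances:
            graph.add_instance(inst, frag.task_id)
        graph.edges |= frag.edges

    # happy-path chain: everything except QA tasks and pursuit goals
    chain = [
        f for _, kind, f in fragments
        if f.task_class != "Question and Answering Task" and kind != "pursuit_before_exit"
    ]
    for a, b in zip(chain, chain[1:]):
        for exit_id in a.exits:
            graph.edges.add((exit_id, SEGUE, b.entry))

    valediction = next((f for f in chain if f.task_class == "Valediction"), None)
    pursuit = next(
        (f for _, kind, f in fragments if kind == "pursuit_before_exit"), None
    )

    # pursuit-before-exit wiring: its Disconfirmation leads to a
    # capitulation and then the valediction; its Confirmation pops back
    if pursuit is not None:
        cap = _system(f"{pursuit.task_id}.capitulate", "Capitulate",
                      "I understand. Thank you for listening; please do talk "
                      "with your provider about anything we discussed.")
        graph.add_instance(cap, pursuit.task_id)
        for dis_id, _ in pursuit.disconfirm_hooks:
            graph.edges.add((dis_id, PRECEDES, cap.id))
        if valediction is not None:
            graph.edges.add((cap.id, SEGUE, valediction.entry))
        # confirmation exits pop the return-address stack
        pursuit.pop_exits.extend(pursuit.exits)
        pursuit.exits.clear()

    # off-path targets for participant hooks in on-path tasks
    for _, kind, frag in fragments:
        if kind == "pursuit_before_exit":
            continue
        for q_id, resume_id in frag.question_hooks:
            if qa_frag is not None:
                graph.edges.add((q_id, SEGUE, qa_frag.entry))
                graph.resume_map[q_id] = resume_id
        for dis_id, resume_id in frag.disconfirm_hooks:
            if pursuit is not None:
                graph.edges.add((dis_id, SEGUE, pursuit.entry))
                graph.resume_map[dis_id] = resume_id
            elif valediction is not None and frag is not valediction:
                graph.edges.add((dis_id, SEGUE, valediction.entry))

    if chain:
        graph.instances[chain[0].entry].focus = True
    return graph


def compile_script(script: DialogueScript, schema: OntologySchema | None = None) -> SessionGraph:
    """Validate-and-compile convenience wrapper around :func:`link_tasks`."""
    graph = link_tasks(script, schema)
    problems = graph.validate()
    if problems:
        raise SessionError("compiled session graph is inconsistent: " + "; ".join(problems))
    return graph


# ---------------------------------------------------------------------------
# RDF serialization of the A-Box

_DIALECTS = {"turtle": "turtle", "rdfxml": "xml"}


def serialize_session(graph: SessionGraph, dialect: str = "turtle") -> str:
    """Emit the session A-Box as RDF referencing the schema IRIs."""
    if dialect not in _DIALECTS:
        raise SessionError(
            f"unknown dialect {dialect!r}; supported dialects: {sorted(_DIALECTS)}"
        )
    schema = graph.schema
    ns = Namespace(schema.iri_base + "#")
    inst_ns = Namespace(schema.iri_base + "/session#")
    g = Graph()
    g.bind("phido", ns)
    g.bind("session", inst_ns)
    g.bind("owl", OWL)

    def inst_iri(iid: str) -> URIRef:
        return inst_ns[iid]

    for iid, inst in graph.instances.items():
        iri = inst_iri(iid)
        g.add((iri, RDF.type, schema.class_iri(inst.class_name)))
        g.add((iri, RDFS.label, Literal(iid)))
        if inst.utterance_string:
            g.add((iri, ns.hasUtteranceString, Literal(inst.utterance_string)))
        for ex in inst.examples:
            g.add((iri, ns.hasUtteranceExamples, Literal(ex)))
        g.add((iri, ns.hasUtterancePriority, Literal(inst.priority, datatype=XSD.integer)))
        g.add((iri, ns.hasBeenSaid, Literal(inst.been_said)))
        g.add((iri, ns.hasFocus, Literal(inst.focus)))
        g.add((iri, ns.belongsToSpeechTask, inst_iri(graph.task_membership[iid])))

    for (s, kind, d) in graph.edges:
        g.add((inst_iri(s), ns[kind], inst_iri(d)))

    for task_id, task_class in graph.tasks.items():
        g.add((inst_iri(task_id), RDF.type, schema.class_iri(task_class)))
    for goal_id, goal_class in graph.goals.items():
        g.add((inst_iri(goal_id), RDF.type, schema.class_iri(goal_class)))
    for task_id, goal_id in graph.task_goal.items():
        g.add((inst_iri(goal_id), ns.hasSpeechTask, inst_iri(task_id)))
    for goal_id, disc_id in graph.goal_discussion.items():
        g.add((inst_iri(disc_id), ns.hasGoal, inst_iri(goal_id)))
    g.add((inst_iri(graph.discussion_id), RDF.type, schema.class_iri("Vaccine Counseling")))
    for src, resume in graph.resume_map.items():
        g.add((inst_iri(src), ns.resumesAt, inst_iri(resume)))

    return g.serialize(format=_DIALECTS[dialect])


def load_session(document: str, dialect: str = "turtle",
                 schema: OntologySchema | None = None) -> SessionGraph:
    """Parse an A-Box document produced by :func:`serialize_session`."""
    if dialect not in _DIALECTS:
        raise SessionError(
            f"unknown dialect {dialect!r}; supported dialects: {sorted(_DIALECTS)}"
        )
    schema = schema or build_schema()
    ns = Namespace(schema.iri_base + "#")
    prefix = schema.iri_base + "/session#"
    g = Graph()
    g.parse(data=document, format=_DIALECTS[dialect])

    class_by_iri = {str(schema.class_iri(c.name)): c.name for c in schema.classes}

    def local(iri) -> str:
        s = str(iri)
        if not s.startswith(prefix):
            raise SessionError(f"instance IRI {s!r} outside the session namespace")
        return s[len(prefix):]

    out = SessionGraph(schema=schema)
    utter_ids: set[str] = set()
    for subj, _, cls in g.triples((None, RDF.type, None)):
        cls_s = str(cls)
        if cls_s not in class_by_iri:
            if cls_s.startswith(schema.iri_base):
                raise SessionError(f"instance {subj} references unknown class {cls_s!r}")
            continue
        name = class_by_iri[cls_s]
        iid = local(subj)
        if schema.is_a(name, "Utterance"):
            examples = sorted(str(e) for e in g.objects(subj, ns.hasUtteranceExamples))
            prio = g.value(subj, ns.hasUtterancePriority)
            out.instances[iid] = UtteranceInstance(
                id=iid,
                class_name=name,
                utterance_string=str(g.value(subj, ns.hasUtteranceString) or ""),
                examples=examples,
                priority=int(prio) if prio is not None else 0,
                been_said=bool(g.value(subj, ns.hasBeenSaid)),
                focus=bool(g.value(subj, ns.hasFocus)),
            )
            task = g.value(subj, ns.belongsToSpeechTask)
            if task is not None:
                out.task_membership[iid] = local(task)
        elif schema.is_a(name, "Speech Task"):
            out.tasks[iid] = name
        elif schema.is_a(name, "Goal"):
            out.goals[iid] = name
        elif schema.is_a(name, "Discussion"):
            out.discussion_id = iid
        utter_ids.add(iid)

    for kind in (PRECEDES, SEGUE):
        for s, _, d in g.triples((None, ns[kind], None)):
            src, dst = local(s), local(d)
            if src not in out.instances or dst not in out.instances:
                raise SessionError(f"dangling {kind} edge {src!r} -> {dst!r}")
            out.edges.add((src, kind, dst))
    for goal, _, task in g.triples((None, ns.hasSpeechTask, None)):
        out.task_goal[local(task)] = local(goal)
    for disc, _, goal in g.triples((None, ns.hasGoal, None)):
        out.goal_discussion[local(goal)] = local(disc)
    for s, _, r in g.triples((None, ns.resumesAt, None)):
        out.resume_map[local(s)] = local(r)
    return out
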