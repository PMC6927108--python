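"""Focus-based dialogue execution over a session graph.

The engine walks the utterance graph one focus move at a time: a query
for what follows the focused instance yields either a system utterance to
speak or a set of expected participant utterances to match free-text
input against.  Matching is token-set Jaccard similarity over each
candidate's example texts; input below the threshold is treated as
unintelligible and triggers a repeat request, with a bounded retry budget
after which the session is ended.

Exactly one instance holds ``hasFocus`` at any time while the session is
live, and ``hasBeenSaid`` flags are monotone: once an utterance has been
spoken (or heard), the flag never reverts.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .session import PRECEDES, SEGUE, SessionGraph, UtteranceInstance

__all__ = [
    "EngineConfig",
    "EngineEvent",
    "ClassificationResult",
    "DialogueState",
    "DialogueError",
    "DanglingGraphError",
    "tokenize",
    "jaccard",
    "classify_input",
    "next_candidates",
    "step",
    "run_session",
    "transcript_to_jsonl",
]

UNINTELLIGIBLE = "Unintelligible"


class DialogueError(RuntimeError):
    """Engine protocol violation (bad input timing, stepping a dead session)."""


class DanglingGraphError(DialogueError):
    """Focus reached a node with no follower, segue, or legal terminal."""


@dataclass(frozen=True)
class EngineConfig:
    """Tunable engine parameters.

    threshold
        Minimum token-set Jaccard similarity for a participant utterance
        to count as matched (default 0.5).
    retry_budget
        Repeat requests allowed per request-repeat site before the
        session is abandoned (default 2).
    """

    threshold: float = 0.5
    retry_budget: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        if self.retry_budget < 0:
            raise ValueError("retry budget must be non-negative")


@dataclass(frozen=True)
class EngineEvent:
    """One transcript entry."""

    kind: str  # system_say | await_input | classified_as | segue | repeat_requested | session_end
    turn: int
    utterance_id: str = ""
    class_name: str = ""
    text: str = ""
    score: float | None = None

    def to_json(self) -> str:
        payload = {"turn": self.turn, "kind": self.kind,
                   "utterance_id": self.utterance_id, "class": self.class_name,
                   "text": self.text}
        if self.score is not None:
            payload["score"] = round(self.score, 6)
        return json.dumps(payload, sort_keys=True)


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of matching participant input against expected utterances."""

    matched_class: str
    score: float
    candidate_scores: dict[str, float]


@dataclass
class DialogueState:
    """The running conversation over one session graph."""

    session: SessionGraph
    config: EngineConfig = field(default_factory=EngineConfig)
    focus_id: str | None = None
    awaiting: bool = False
    await_site: str | None = None  # node whose followers are the expected inputs
    retries: dict[str, int] = field(default_factory=dict)
    resume_stack: list[str] = field(default_factory=list)
    turn: int = 0
    transcript: list[EngineEvent] = field(default_factory=list)
    ended: bool = False

    def __post_init__(self) -> None:
        if self.focus_id is None:
            holders = self.session.focus_instances()
            if len(holders) != 1:
                raise DialogueError(
                    f"session must start with exactly one focus holder, found {len(holders)}"
                )
            self.focus_id = holders[0].id

    @property
    def focus(self) -> UtteranceInstance:
        return self.session.instances[self.focus_id]

    def _set_focus(self, node_id: str | None) -> None:
        if self.focus_id is not None:
            self.session.instances[self.focus_id].focus = False
        self.focus_id = node_id
        if node_id is not None:
            self.session.instances[node_id].focus = True

    def _emit(self, kind: str, node: UtteranceInstance | None = None,
              score: float | None = None, text: str | None = None) -> None:
        self.transcript.append(EngineEvent(
            kind=kind, turn=self.turn,
            utterance_id=node.id if node else "",
            class_name=node.class_name if node else "",
            text=text if text is not None else (node.utterance_string if node else ""),
            score=score,
        ))


_TOKEN_RE = re.compile(r"[a-z0-9']+")


def tokenize(text: str) -> frozenset[str]:
    """Lower-cased, punctuation-stripped token set."""
    return frozenset(_TOKEN_RE.findall(text.lower()))


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def classify_input(text: str, candidates: list[UtteranceInstance],
                   threshold: float = 0.5) -> ClassificationResult:
    """Match free text against the expected participant utterances.

    The score for a candidate is the best Jaccard similarity between the
    input's token set and any of the candidate's example texts.  Below
    ``threshold`` the input is classified unintelligible.  Candidates of
    the Unintelligible class itself are never scored: that class is the
    fallback, not a matchable target.
    """
    scorable = [c for c in candidates if c.class_name != UNINTELLIGIBLE]
    if not scorable:
        raise DialogueError("no expected participant utterance to classify against")
    tokens = tokenize(text)
    scores: dict[str, float] = {}
    for cand in scorable:
        s = max((jaccard(tokens, tokenize(ex)) for ex in cand.examples), default=0.0)
        scores[cand.class_name] = max(scores.get(cand.class_name, 0.0), s)
    # argmax with deterministic tie-break on class name
    best_class = min((c for c in scores), key=lambda c: (-scores[c], c))
    best = scores[best_class]
    if best >= threshold:
        return ClassificationResult(best_class, best, scores)
    return ClassificationResult(UNINTELLIGIBLE, best, scores)


def next_candidates(state: DialogueState) -> list[UtteranceInstance]:
    """What can come next from the current focus.

    While input is awaited this is the expected participant utterance
    set; otherwise the instances one ``precedes`` step from the focus
    (priority order), falling back to the segue target(s).
    """
    if state.ended:
        return []
    sess = state.session
    if state.awaiting:
        return sess.followers(state.await_site)
    out = sess.followers(state.focus_id)
    if out:
        return out
    segues = sess.segue_targets(state.focus_id)
    if segues:
        return segues
    if state.focus.class_name == "Concluding Farewell":
        return []
    raise DanglingGraphError(
        f"focus {state.focus_id!r} has neither followers nor a segue"
    )


def _end(state: DialogueState) -> None:
    state._emit("session_end")
    state._set_focus(None)
    state.ended = True
    state.awaiting = False


def _advance_from(state: DialogueState, node: UtteranceInstance) -> None:
    """Move focus onward from ``node`` after it was said or heard."""
    sess = state.session
    followers = sess.followers(node.id)
    if followers:
        top = followers[0]
        if sess.is_participant(top):
            # expected participant input: focus rests on the slot
            state.awaiting = True
            state.await_site = node.id
            state._set_focus(top.id)
            state._emit("await_input", top, text="")
        else:
            state._set_focus(top.id)
        return
    segues = sess.segue_targets(node.id)
    if segues:
        target = segues[0]
        if node.id in sess.resume_map:
            state.resume_stack.append(sess.resume_map[node.id])
        state._emit("segue", target, text="")
        if sess.is_participant(target):
            # entering a task through its participant entry (the question
            # that triggered the segue stands for it): pass straight through
            target.been_said = True
            _advance_from(state, target)
        else:
            state._set_focus(target.id)
        return
    if node.class_name == "Concluding Farewell":
        _end(state)
        return
    if state.resume_stack:
        resume = sess.instances[state.resume_stack.pop()]
        _advance_from(state, resume)
        return
    raise DanglingGraphError(
        f"node {node.id!r} has no follower, segue, resume point or legal end"
    )


def _handle_unintelligible(state: DialogueState) -> None:
    sess = state.session
    candidates = sess.followers(state.await_site)
    unint = next((c for c in candidates if c.class_name == UNINTELLIGIBLE), None)
    if unint is not None:
        rr = sess.followers(unint.id)
        site_id = rr[0].id if rr else state.await_site
    else:
        site_id = state.await_site
    state.retries[site_id] = state.retries.get(site_id, 0) + 1
    state._emit("repeat_requested", sess.instances[site_id], text="")
    if state.retries[site_id] > state.config.retry_budget:
        _end(state)
        return
    if unint is not None:
        unint.been_said = True
    state.awaiting = False
    state.await_site = None
    # the repeat-request (or original prompt) is spoken on the next step
    state._set_focus(site_id)


def step(state: DialogueState, participant_input: str | None = None
         ) -> tuple[DialogueState, list[EngineEvent]]:
    """Advance the conversation by one move.

    System focus: speak the focused utterance and move focus onward.
    Awaiting input: classify the supplied text; a match moves focus
    through the matched instance to its follower, a non-match requests a
    repeat and charges the retry budget.  Returns the (mutated) state and
    the events this step appended.
    """
    if state.ended:
        raise DialogueError("session has already ended")
    state.turn += 1
    mark = len(state.transcript)

    if state.awaiting:
        if participant_input is None:
            raise DialogueError("participant input required while awaiting a reply")
        candidates = state.session.followers(state.await_site)
        result = classify_input(participant_input, candidates, state.config.threshold)
        if result.matched_class == UNINTELLIGIBLE:
            _handle_unintelligible(state)
        else:
            matched = next(
                c for c in candidates if c.class_name == result.matched_class
            )
            matched.been_said = True
            state.awaiting = False
            state.await_site = None
            state._emit("classified_as", matched, score=result.score,
                        text=participant_input)
            state._set_focus(matched.id)
            _advance_from(state, matched)
    else:
        if participant_input is not None:
            raise DialogueError(
                "input supplied while focus is on a system utterance"
            )
        node = state.focus
        if not state.session.is_system(node):
            raise DanglingGraphError(
                f"focus rests on participant instance {node.id!r} outside an input slot"
            )
        node.been_said = True
        state._emit("system_say", node)
        _advance_from(state, node)

    return state, state.transcript[mark:]


def run_session(session: SessionGraph, policy, seed: int = 0,
                max_turns: int = 500,
                config: EngineConfig | None = None) -> list[EngineEvent]:
    """Drive a full conversation with a participant policy.

    The policy supplies text whenever the engine awaits input; the loop
    stops at session end or after ``max_turns`` steps.  Bit-for-bit
    reproducible for a fixed (session, policy, seed) triple.
    """
    if max_turns < 1:
        raise ValueError("max_turns must be at least 1")
    state = DialogueState(session=session.copy(),
                          config=config or EngineConfig())
    rng_policy = policy.bind(seed) if hasattr(policy, "bind") else policy
    while not state.ended and state.turn < max_turns:
        text = None
        if state.awaiting:
            text = rng_policy.respond(next_candidates(state))
        step(state, text)
    return state.transcript


def transcript_to_jsonl(transcript: list[EngineEvent]) -> str:
    """One JSON object per line, one line per event."""
    return "\n".join(ev.to_json() for ev in transcript) + "\n"
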