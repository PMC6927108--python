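"""Deterministic toy lexicon for the label-quality metrics.

The interpretability and clarity scores need a word -> sense-count
oracle.  To keep the test suite offline and reproducible, the package
bundles a small hand-set lexicon covering the vocabulary that appears in
dialogue-ontology labels, with sense counts reflecting ordinary English
polysemy (e.g. "focus" and "string" are polysemous, "valediction" is
not).  Any callable ``word -> int`` can be supplied instead, e.g. an
adapter over a full word-sense database.
"""

from __future__ import annotations

__all__ = ["toy_sense_count", "TOY_LEXICON"]

TOY_LEXICON: dict[str, int] = {
    # structural vocabulary
    "discussion": 2, "goal": 3, "task": 2, "utterance": 1, "speech": 4,
    "participant": 1, "system": 5, "communication": 2, "level": 6,
    # participant utterance labels
    "acceptance": 2, "negative": 4, "disconfirmation": 1, "personal": 2,
    "status": 3, "farewell": 1, "introduction": 4, "positive": 5,
    "confirmation": 2, "prattle": 1, "question": 3, "divergent": 2,
    "reciprocal": 2, "greet": 1, "request": 2, "repeat": 3,
    "unintelligible": 1,
    # system utterance labels
    "acknowledgment": 2, "agenda": 2, "answer": 3, "no": 2, "apology": 2,
    "capitulate": 1, "compassionate": 1, "condolence": 1, "happy": 3,
    "for": 1, "confirm": 2, "health": 2, "information": 2,
    "declaration": 3, "disclaimer": 1, "topic": 2, "transition": 3,
    "concluding": 2, "inform": 1, "inquire": 1, "interview": 2,
    "option": 3, "options": 3, "clarification": 1, "overview": 1,
    "satisfaction": 3, "prompt": 4, "and": 1, "answering": 2,
    # task / goal labels
    "salutation": 1, "valediction": 1, "initiate": 1, "discuss": 1,
    "pleasantry": 1, "proposition": 4, "acclimate": 1, "conclude": 2,
    "communicate": 2, "benefit": 3, "effectiveness": 1, "harms": 2,
    "uncertainty": 2, "pursuit": 3, "before": 1, "exit": 2,
    "vaccine": 1, "counseling": 1,
    # property labels
    "has": 1, "been": 1, "said": 1, "focus": 5, "priority": 2,
    "string": 8, "examples": 2, "belongs": 1, "to": 1, "link": 4,
    "segue": 1, "follows": 2, "precedes": 1, "act": 6, "type": 4,
    "utterances": 1,
}


def toy_sense_count(word: str) -> int:
    """Sense count from the bundled lexicon; 0 for unknown words."""
    return TOY_LEXICON.get(word.lower(), 0)
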