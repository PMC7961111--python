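"""The 37-step reference outline of assembling the two-person dome tent.

Each mid-level step carries its compressed subtask label and an *act* id.
An act is one grouped object interaction with a clear beginning (finger
contact to pick up) and end (release): picking up, opening and emptying the
tent bag is a single act of the "tent bag" subtask, while staking each of
the four corners is four separate acts of the "stake corner" subtask.
Consecutive steps of the same act compress to one subtask occurrence;
repeated acts are retained, which is what puts self-transitions on the
diagonal of the idealized transition matrix.
"""

from __future__ import annotations

from .vocab import VocabularyError

__all__ = ["STEPS", "STEP_LABELS", "IDEALIZED_SEQUENCE", "step_label", "step_act"]

# (step name, compressed subtask label, act id)
STEPS: tuple[tuple[str, str, int], ...] = (
    ("Read instructions", "read instructions", 1),
    ("Pick up main bag", "tent bag", 2),
    ("Open main bag", "tent bag", 2),
    ("Empty main bag out", "tent bag", 2),
    ("Pick up tent", "spread tent", 3),
    ("Spread tent out", "spread tent", 3),
    ("Pick up support pole bag", "support bag", 4),
    ("Open support pole bag", "support bag", 4),
    ("Empty support pole bag", "support bag", 4),
    ("Pick up support pole #1", "assemble support", 5),
    ("Assemble support pole #1", "assemble support", 5),
    ("Pick up support pole #2", "assemble support", 6),
    ("Assemble support pole #2", "assemble support", 6),
    ("Insert support pole #1", "insert support", 7),
    ("Insert support pole #2", "insert support", 8),
    ("Insert support pole #1 into plastic tab 1", "insert tabs", 9),
    ("Insert support pole #1 into plastic tab 2", "insert tabs", 10),
    ("Insert support pole #2 into plastic tab 1", "insert tabs", 11),
    ("Insert support pole #2 into plastic tab 2", "insert tabs", 12),
    ("Pick up stake bag", "stake bag", 13),
    ("Open stake bag", "stake bag", 13),
    ("Take stakes", "stake bag", 13),
    ("Stake corner 1", "stake corner", 14),
    ("Stake corner 2", "stake corner", 15),
    ("Stake corner 3", "stake corner", 16),
    ("Stake corner 4", "stake corner", 17),
    ("Pick up guyline 1", "place guyline", 18),
    ("Stake guyline 1", "place guyline", 18),
    ("Pick up guyline 2", "place guyline", 19),
    ("Stake guyline 2", "place guyline", 19),
    ("Pick up guyline 3", "place guyline", 20),
    ("Stake guyline 3", "place guyline", 20),
    ("Pick up guyline 4", "place guyline", 21),
    ("Stake guyline 4", "place guyline", 21),
    ("Tie support poles above vent", "tie top", 22),
    ("Pick up vent cover", "vent cover", 23),
    ("Attach vent cover", "vent cover", 23),
)

#: The reference sequence of mid-level step names in idealized order.
STEP_LABELS: tuple[str, ...] = tuple(s[0] for s in STEPS)

_norm = lambda s: " ".join(s.lower().split())  # noqa: E731
_STEP_TO_LABEL = {_norm(name): label for name, label, _ in STEPS}
_STEP_TO_ACT = {_norm(name): act for name, _, act in STEPS}


def step_label(step: str) -> str:
    """Compressed subtask label for a mid-level step name."""
    try:
        return _STEP_TO_LABEL[_norm(step)]
    except KeyError:
        raise VocabularyError(f"unknown step name: {step!r}") from None


def step_act(step: str) -> int:
    """Act id (grouped object interaction) for a mid-level step name."""
    try:
        return _STEP_TO_ACT[_norm(step)]
    except KeyError:
        raise VocabularyError(f"unknown step name: {step!r}") from None


def _compress_reference() -> tuple[str, ...]:
    out: list[str] = []
    prev_act = None
    for _, label, act in STEPS:
        if act != prev_act:
            out.append(label)
            prev_act = act
    return tuple(out)


#: The idealized subtask-occurrence sequence obtained by compressing the
#: reference steps (23 occurrences over the 12 labels; staking, guylines and
#: tab insertion repeat four times, pole assembly and insertion twice).
IDEALIZED_SEQUENCE: tuple[str, ...] = _compress_reference()
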