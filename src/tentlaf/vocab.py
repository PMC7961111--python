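"""Controlled vocabularies for the tent-assembly event streams.

Two closed label sets drive the whole pipeline: the 12 object categories a
fixation or touch can be directed at, and the 12 compressed subtask labels
(plus the special ``approach`` label marking transitions between subtasks).
Labels are matched case- and whitespace-insensitively on input and written in
canonical spelling on output.
"""

from __future__ import annotations

import re

__all__ = [
    "OBJECT_LABELS",
    "SUBTASK_LABELS",
    "APPROACH",
    "NONE_TARGET",
    "VocabularyError",
    "canonical_object",
    "canonical_subtask",
]


class VocabularyError(ValueError):
    """An object or subtask label outside the controlled vocabulary."""


#: The 12 object categories that can be the target of a fixation or touch.
#: Categories, not instances: all four tent corners share "tent corner".
OBJECT_LABELS: tuple[str, ...] = (
    "vent cover",
    "tent top",
    "tent corner",
    "tent bag",
    "tent",
    "support tab",
    "support bag",
    "support",
    "stake bag",
    "stake",
    "instruction",
    "guyline",
)

#: The 12 compressed subtask labels, in idealized chronological order.
SUBTASK_LABELS: tuple[str, ...] = (
    "read instructions",
    "tent bag",
    "spread tent",
    "support bag",
    "assemble support",
    "insert support",
    "insert tabs",
    "stake bag",
    "stake corner",
    "place guyline",
    "tie top",
    "vent cover",
)

#: Special label for transition periods between subtasks (walking around the
#: tent, fetching an item).  Never a Markov state.
APPROACH = "approach"

#: Sentinel target for fixations that land on no annotated object (saccade,
#: blink, background).  These count as "fixation elsewhere" when deciding
#: whether a look-ahead is separated from its guiding look.
NONE_TARGET = None


def _key(name: str) -> str:
    """Normalization key: lowercase with all non-alphanumerics removed."""
    return re.sub(r"[^a-z0-9]+", "", name.lower())


def _build_lookup(canonical: tuple[str, ...], aliases: dict[str, str]) -> dict[str, str]:
    table = {_key(c): c for c in canonical}
    for alias, target in aliases.items():
        table[_key(alias)] = target
    return table


# Aliases accept the long annotation-sheet spellings as well as the short
# forms used in running text (e.g. "insert stake" for the staking subtask).
_SUBTASK_ALIASES = {
    "pick up/open/empty tent bag": "tent bag",
    "pick up/spread tent": "spread tent",
    "pick up/open/empty support pole bag": "support bag",
    "assemble support pole": "assemble support",
    "insert support poles": "insert support",
    "insert support pole into tabs": "insert tabs",
    "insert tab": "insert tabs",
    "pick up/open/empty stake bag": "stake bag",
    "stake corner": "stake corner",
    "insert stake": "stake corner",
    "place guyline": "place guyline",
    "tie support poles above vent": "tie top",
    "pick up/attach vent cover": "vent cover",
    "instruction": "read instructions",
    "instructions": "read instructions",
    "read instruction": "read instructions",
}

_OBJECT_ALIASES = {
    "guy line": "guyline",
    "guylines": "guyline",
    "corner": "tent corner",
    "instructions": "instruction",
    "stakes": "stake",
    "supports": "support",
}

_OBJECT_LOOKUP = _build_lookup(OBJECT_LABELS, _OBJECT_ALIASES)
_SUBTASK_LOOKUP = _build_lookup(SUBTASK_LABELS + (APPROACH,), _SUBTASK_ALIASES)


def canonical_object(name: str) -> str:
    """Return the canonical spelling of an object label.

    Raises :class:`VocabularyError` for names outside the 12-category set.
    """
    try:
        return _OBJECT_LOOKUP[_key(name)]
    except KeyError:
        raise VocabularyError(f"unknown object label: {name!r}") from None


def canonical_subtask(name: str) -> str:
    """Return the canonical spelling of a subtask label (or ``approach``)."""
    try:
        return _SUBTASK_LOOKUP[_key(name)]
    except KeyError:
        raise VocabularyError(f"unknown subtask label: {name!r}") from None
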