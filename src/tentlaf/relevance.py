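"""Subtask → relevant-object mapping used for on-/off-task classification.

The default mapping is a reconstruction from the task structure (which
objects are manipulated, or directly support the manipulation, during each
subtask) and is fully overridable from a YAML file of
``subtask: [object, ...]`` entries.  Instruction reading maps to the
instructions alone; approach has no mapping because on-/off-task status is
not applicable there.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .vocab import SUBTASK_LABELS, canonical_object, canonical_subtask

__all__ = ["DEFAULT_RELEVANCE", "PRIMARY_OBJECT", "load_relevance_map", "validate_relevance_map"]

#: Reconstruction of which object categories are relevant to each subtask.
DEFAULT_RELEVANCE: dict[str, frozenset[str]] = {
    "read instructions": frozenset({"instruction"}),
    "tent bag": frozenset({"tent bag"}),
    "spread tent": frozenset({"tent", "tent bag"}),
    "support bag": frozenset({"support bag"}),
    "assemble support": frozenset({"support"}),
    "insert support": frozenset({"support", "tent", "tent corner"}),
    "insert tabs": frozenset({"support tab", "support"}),
    "stake bag": frozenset({"stake bag"}),
    "stake corner": frozenset({"stake", "tent corner"}),
    "place guyline": frozenset({"guyline", "stake"}),
    "tie top": frozenset({"tent top"}),
    "vent cover": frozenset({"vent cover", "tent top"}),
}

#: The single object manipulated first in each subtask; the simulator places
#: that subtask's touch events starting from this object.
PRIMARY_OBJECT: dict[str, str] = {
    "read instructions": "instruction",
    "tent bag": "tent bag",
    "spread tent": "tent",
    "support bag": "support bag",
    "assemble support": "support",
    "insert support": "support",
    "insert tabs": "support tab",
    "stake bag": "stake bag",
    "stake corner": "stake",
    "place guyline": "guyline",
    "tie top": "tent top",
    "vent cover": "vent cover",
}


def validate_relevance_map(mapping: dict[str, frozenset[str]]) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for subtask, objects in mapping.items():
        s = canonical_subtask(subtask)
        objs = frozenset(canonical_object(o) for o in objects)
        if not objs:
            raise ValueError(f"relevance map entry for {s!r} is empty")
        out[s] = objs
    missing = [s for s in SUBTASK_LABELS if s not in out]
    if missing:
        raise ValueError(f"relevance map missing subtask(s): {missing}")
    if out["read instructions"] != frozenset({"instruction"}):
        raise ValueError("instruction reading must map to {'instruction'}")
    return out


def load_relevance_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Load a relevance-map override from YAML (subtask → list of objects)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of subtask -> [objects]")
    return validate_relevance_map({k: frozenset(v) for k, v in raw.items()})
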