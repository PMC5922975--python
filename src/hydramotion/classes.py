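"""Behavior-class table.

Hydra behavior is annotated per frame with integer codes 0-10.  Code 0 is the
"none" class (unannotated / ambiguous frames); codes 1-10 are behaviors
ordered by *prominence*: larger codes are visually more prominent behaviors
(a brief whole-body contraction is more salient than minutes of stillness),
and the window-label aggregation rule in :mod:`hydramotion.classify` uses this
ordering to favor short prominent behaviors over long quiet ones.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BehaviorClass:
    code: int
    name: str
    prominence_rank: int


#: The full annotation vocabulary.  The three feeding stages and somersaulting
#: are part of the vocabulary but are excluded from the basic 6-class training
#: configuration (see :data:`BASIC_SIX`).
BEHAVIOR_CLASSES: tuple[BehaviorClass, ...] = (
    BehaviorClass(0, "none", 0),
    BehaviorClass(1, "silent", 1),
    BehaviorClass(2, "elongation", 2),
    BehaviorClass(3, "tentacle_sway", 3),
    BehaviorClass(4, "body_sway", 4),
    BehaviorClass(5, "bending", 5),
    BehaviorClass(6, "contraction", 6),
    BehaviorClass(7, "somersaulting", 7),
    BehaviorClass(8, "feeding_writhing", 8),
    BehaviorClass(9, "feeding_ball", 9),
    BehaviorClass(10, "feeding_mouth", 10),
)

CODE_TO_CLASS = {c.code: c for c in BEHAVIOR_CLASSES}
NAME_TO_CLASS = {c.name: c for c in BEHAVIOR_CLASSES}

#: The six basic behaviors used for classifier training.
BASIC_SIX: tuple[str, ...] = (
    "silent",
    "elongation",
    "tentacle_sway",
    "body_sway",
    "bending",
    "contraction",
)

NONE_CODE = 0


def prominence(code: int) -> int:
    """Prominence rank of a behavior code (0 for the none class)."""
    return CODE_TO_CLASS[code].prominence_rank


def validate_codes(codes) -> None:
    """Raise ``ValueError`` listing any codes outside the class table."""
    bad = sorted({int(c) for c in codes} - set(CODE_TO_CLASS))
    if bad:
        raise ValueError(f"unknown behavior label codes: {bad}")
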