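"""Fatigue-state frame of discernment.

Three muscle states labelled on the RPE self-report scale:
relaxed (-1), transition (0), fatigue (1).
"""

from __future__ import annotations

STATES: tuple[int, int, int] = (-1, 0, 1)
"""Canonical class order used everywhere (fold splits, softmax head, fusion)."""

STATE_NAMES: dict[int, str] = {-1: "relaxed", 0: "transition", 1: "fatigue"}

FRAME: frozenset[int] = frozenset(STATES)
"""Theta, the full frame of discernment for evidence fusion."""


def check_state(state: int) -> int:
    """Validate a fatigue-state label, returning it unchanged."""
    if state not in STATES:
        raise ValueError(f"state must be one of {STATES}, got {state!r}")
    return state
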