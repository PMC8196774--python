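"""Modified Hughson-Westlake adaptive staircase for one ear at one frequency.

The track implements the clinical "10 dB down, 5 dB up" rule:

1. **Initial ascent** — start at 30 dB HL; after each miss, raise the level
   in 10 dB steps until the tone is first heard.
2. **Descending runs** — after a heard response, lower the level in 10 dB
   steps until a miss.
3. **Ascending runs** — after a miss, raise the level in 5 dB steps until a
   heard response.

Each change of direction in the main phase is a *reversal*; the turn from
the initial ascent into the first descent counts as reversal 1.  The
threshold is the level of the first heard response in an ascending run once
three reversals have already occurred.  Levels are clamped to the
configured floor and per-frequency ceiling; a miss at the ceiling
terminates the track with the :data:`~puretone.core.NO_RESPONSE` sentinel.

States are immutable; :func:`step` returns a new state, so a recorded
(level, heard) transcript replays to the identical terminal state.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence, Union

from .core import NO_RESPONSE, _NoResponse

__all__ = [
    "Phase",
    "StaircaseConfig",
    "StaircaseState",
    "StaircaseError",
    "ConvergenceError",
    "start",
    "step",
    "run_track",
    "replay",
    "history_to_transcript",
    "transcript_to_history",
]

Threshold = Union[float, _NoResponse]


class StaircaseError(RuntimeError):
    """Invalid staircase operation (e.g. stepping a terminal state)."""


class ConvergenceError(StaircaseError):
    """The presentation cap was reached before the track terminated."""


class Phase(enum.Enum):
    INITIAL_ASCENT = "initial_ascent"
    DESCENDING = "descending"
    ASCENDING = "ascending"
    COMPLETE = "complete"
    NO_RESPONSE = "no_response"


_TERMINAL = frozenset({Phase.COMPLETE, Phase.NO_RESPONSE})


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of one adaptive track.

    Defaults are the standard clinical values: start at 30 dB HL, ascend in
    10 dB steps until first heard, then descend 10 dB / ascend 5 dB, stop on
    the first heard ascending response after three reversals.  ``ceiling``
    should come from :func:`puretone.core.max_level_hl` for the tested
    frequency.  ``max_presentations`` is a hard termination guarantee for
    non-converging (e.g. randomly responding) listeners.
    """

    start_level: float = 30.0
    initial_step: float = 10.0
    descend_step: float = 10.0
    ascend_step: float = 5.0
    reversals_required: int = 3
    floor: float = -10.0
    ceiling: float = 80.0
    max_presentations: int = 50

    def __post_init__(self) -> None:
        if min(self.initial_step, self.descend_step, self.ascend_step) <= 0:
            raise ValueError("all step sizes must be positive")
        if self.reversals_required < 1:
            raise ValueError("reversals_required must be >= 1")
        if not self.floor < self.start_level <= self.ceiling:
            raise ValueError(
                f"need floor < start_level <= ceiling; got "
                f"{self.floor} / {self.start_level} / {self.ceiling}"
            )
        if self.max_presentations < 1:
            raise ValueError("max_presentations must be >= 1")


@dataclass(frozen=True)
class StaircaseState:
    """Full state of one track: the level about to be presented, the phase,
    the reversal count, the presentation history, and (once terminal) the
    threshold or NO_RESPONSE."""

    current_level: float
    phase: Phase
    reversal_count: int = 0
    history: tuple[tuple[float, bool], ...] = ()
    threshold: Threshold | None = None

    @property
    def is_terminal(self) -> bool:
        return self.phase in _TERMINAL


def start(config: StaircaseConfig) -> StaircaseState:
    """A fresh track about to present ``config.start_level``."""
    return StaircaseState(current_level=config.start_level, phase=Phase.INITIAL_ASCENT)


def step(state: StaircaseState, heard: bool, config: StaircaseConfig) -> StaircaseState:
    """Advance the track by one presentation outcome.

    Records ``(state.current_level, heard)`` and applies the transition rules
    described in the module docstring.  Raises :class:`StaircaseError` on a
    terminal state.
    """
    if state.is_terminal:
        raise StaircaseError(f"cannot step a terminal track (phase {state.phase.value})")

    level = state.current_level
    heard = bool(heard)
    history = state.history + ((level, heard),)
    reversals = state.reversal_count

    if state.phase is Phase.INITIAL_ASCENT:
        if heard:
            # First heard response: turn downward.  This turn is reversal 1.
            return replace(
                state,
                current_level=max(level - config.descend_step, config.floor),
                phase=Phase.DESCENDING,
                reversal_count=reversals + 1,
                history=history,
            )
        if level >= config.ceiling:
            return replace(
                state, phase=Phase.NO_RESPONSE, threshold=NO_RESPONSE, history=history
            )
        return replace(
            state,
            current_level=min(level + config.initial_step, config.ceiling),
            history=history,
        )

    if state.phase is Phase.DESCENDING:
        if heard:
            if level <= config.floor:
                # Cannot descend further: treat the floor as the turnaround.
                return replace(
                    state,
                    phase=Phase.ASCENDING,
                    reversal_count=reversals + 1,
                    history=history,
                )
            return replace(
                state,
                current_level=max(level - config.descend_step, config.floor),
                history=history,
            )
        # Miss while descending: reversal, switch to the 5 dB ascent.
        return replace(
            state,
            current_level=min(level + config.ascend_step, config.ceiling),
            phase=Phase.ASCENDING,
            reversal_count=reversals + 1,
            history=history,
        )

    # Phase.ASCENDING
    if heard:
        if reversals >= config.reversals_required:
            return replace(
                state, phase=Phase.COMPLETE, threshold=level, history=history
            )
        # Not enough reversals yet: turn back down and keep tracking.
        return replace(
            state,
            current_level=max(level - config.descend_step, config.floor),
            phase=Phase.DESCENDING,
            reversal_count=reversals + 1,
            history=history,
        )
    if level >= config.ceiling:
        return replace(
            state, phase=Phase.NO_RESPONSE, threshold=NO_RESPONSE, history=history
        )
    return replace(
        state,
        current_level=min(level + config.ascend_step, config.ceiling),
        history=history,
    )


def run_track(
    listener_response: Callable[[float], bool],
    config: StaircaseConfig | None = None,
) -> tuple[Threshold, tuple[tuple[float, bool], ...]]:
    """Drive a track to termination against a response callable.

    ``listener_response(level_dbhl) -> heard`` must be total over
    ``[floor, ceiling]``.  Returns the threshold (or NO_RESPONSE) and the
    full presentation history.  Raises :class:`ConvergenceError` if the
    presentation cap is hit first.
    """
    config = config or StaircaseConfig()
    state = start(config)
    for _ in range(config.max_presentations):
        state = step(state, listener_response(state.current_level), config)
        if state.is_terminal:
            return state.threshold, state.history
    raise ConvergenceError(
        f"track did not terminate within {config.max_presentations} presentations; "
        "listener responses are not converging"
    )


def replay(
    history: Sequence[tuple[float, bool]], config: StaircaseConfig | None = None
) -> StaircaseState:
    """Re-run a recorded (level, heard) sequence through :func:`step`.

    Checks that each recorded level matches the level the track would
    present, so a corrupted transcript is detected rather than silently
    accepted.
    """
    config = config or StaircaseConfig()
    state = start(config)
    for i, (level, heard) in enumerate(history):
        if abs(level - state.current_level) > 1e-9:
            raise StaircaseError(
                f"transcript mismatch at presentation {i}: recorded level {level}, "
                f"track expected {state.current_level}"
            )
        state = step(state, heard, config)
    return state


_TRANSCRIPT_HEADER = ["presentation_index", "level_dbhl", "heard"]


def history_to_transcript(history: Sequence[tuple[float, bool]]) -> str:
    """Serialize a presentation history to delimited text for audit/replay."""
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(_TRANSCRIPT_HEADER)
    for i, (level, heard) in enumerate(history):
        writer.writerow([i, level, int(heard)])
    return buf.getvalue()


def transcript_to_history(text: str | Path) -> tuple[tuple[float, bool], ...]:
    """Parse a transcript produced by :func:`history_to_transcript`."""
    if isinstance(text, Path):
        text = text.read_text()
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    if [h.strip() for h in header] != _TRANSCRIPT_HEADER:
        raise ValueError(f"bad transcript header {header!r}")
    return tuple(
        (float(level), bool(int(heard))) for _idx, level, heard in reader if level != ""
    )
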