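"""Full hearing-test sessions: both ears, six frequencies, audiogram assembly.

A session runs one Hughson-Westlake track per ear x frequency in the
configured order (right ear first, 250 Hz up to 8 kHz by default), applies
the per-frequency presentation ceiling, and assembles the results into an
:class:`Audiogram` with ASHA severity labels.  It also houses two session
policies of the smartphone test:

* the ambient-noise rule — pause the test whenever the background level
  exceeds 40 dB SPL (strictly greater, configurable);
* the masking rule — the minimum narrow-band noise level for the non-test
  ear is the presentation SPL minus the interaural attenuation (IA,
  clinical minimum assumption 40 dB for air conduction); at or below the
  IA no energy crosses over and no masking is needed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import staircase
from .core import (
    NO_RESPONSE,
    TEST_FREQUENCIES,
    LevelSPL,
    RetsplTable,
    _as_value,
    classify_threshold,
    max_level_hl,
    packaged_retspl_tables,
)
from .listeners import EARS, VirtualListener

__all__ = [
    "MaskingParams",
    "SessionConfig",
    "AudiogramEntry",
    "Audiogram",
    "TranscriptListener",
    "run_session",
    "should_pause",
    "masking_level",
    "plot_audiogram",
]


@dataclass(frozen=True)
class MaskingParams:
    """Interaural-attenuation assumption and whether masking is applied.

    Masking defaults to off: the normal-hearing workflow does not need it,
    but the crossover arithmetic is always available for reporting.
    """

    interaural_attenuation: float = 40.0
    enabled: bool = False

    def __post_init__(self) -> None:
        if self.interaural_attenuation <= 0:
            raise ValueError("interaural attenuation must be positive")


@dataclass(frozen=True)
class SessionConfig:
    """Configuration of a full two-ear test."""

    frequencies: tuple[int, ...] = TEST_FREQUENCIES
    ear_order: tuple[str, ...] = EARS
    noise_pause_threshold: float = 40.0
    retspl_table: Optional[RetsplTable] = None
    masking: MaskingParams = field(default_factory=MaskingParams)
    staircase_defaults: staircase.StaircaseConfig = field(
        default_factory=staircase.StaircaseConfig
    )

    def __post_init__(self) -> None:
        unknown = set(self.frequencies) - set(TEST_FREQUENCIES)
        if unknown:
            raise ValueError(f"unsupported frequencies {sorted(unknown)}")
        if self.noise_pause_threshold <= 0:
            raise ValueError("noise_pause_threshold must be positive")
        if self.retspl_table is None:
            object.__setattr__(
                self, "retspl_table", packaged_retspl_tables()["HearTest v2"]
            )

    def track_config(self, freq: int) -> staircase.StaircaseConfig:
        """Per-frequency staircase config with the correct ceiling."""
        from dataclasses import replace

        return replace(
            self.staircase_defaults, ceiling=max_level_hl(freq).value
        )


@dataclass(frozen=True)
class AudiogramEntry:
    """Result for one ear x frequency cell."""

    ear: str
    freq_hz: int
    threshold_dbhl: Optional[float]  # None when no response at ceiling
    no_response: bool
    category: Optional[str]  # None when no numeric threshold exists

    @property
    def threshold(self):
        return NO_RESPONSE if self.no_response else self.threshold_dbhl


@dataclass
class Audiogram:
    """Per-ear, per-frequency thresholds plus session metadata.

    Exactly one entry exists per tested ear x frequency; category labels are
    consistent with :func:`puretone.core.classify_threshold`.
    """

    entries: dict[tuple[str, int], AudiogramEntry]
    histories: dict[tuple[str, int], tuple[tuple[float, bool], ...]] = field(
        default_factory=dict
    )
    metadata: dict = field(default_factory=dict)

    def threshold(self, ear: str, freq: int):
        return self.entries[(ear, int(freq))].threshold

    def to_dict(self) -> dict:
        ears: dict[str, list] = {}
        for (ear, _f), e in sorted(self.entries.items()):
            ears.setdefault(ear, []).append(
                {
                    "freq_hz": e.freq_hz,
                    "threshold_dbhl": e.threshold_dbhl,
                    "no_response": e.no_response,
                    "category": e.category,
                }
            )
        return {"ears": ears, "metadata": self.metadata}

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "Audiogram":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            source = Path(source).read_text()
        doc = json.loads(source)
        entries = {}
        for ear, cells in doc["ears"].items():
            for c in cells:
                entries[(ear, int(c["freq_hz"]))] = AudiogramEntry(
                    ear=ear,
                    freq_hz=int(c["freq_hz"]),
                    threshold_dbhl=c["threshold_dbhl"],
                    no_response=bool(c["no_response"]),
                    category=c["category"],
                )
        return cls(entries=entries, metadata=doc.get("metadata", {}))

    def to_frame(self) -> pd.DataFrame:
        """Flat delimited form: one row per ear x frequency."""
        return pd.DataFrame(
            [
                {
                    "ear": e.ear,
                    "freq_hz": e.freq_hz,
                    "threshold_dbhl": e.threshold_dbhl,
                    "no_response": e.no_response,
                    "category": e.category,
                }
                for _k, e in sorted(self.entries.items())
            ]
        )


class TranscriptListener:
    """Replays recorded (level, heard) transcripts instead of a live subject.

    ``transcripts`` maps (ear, freq) to the presentation history recorded by
    a previous session; feeding it back through :func:`run_session`
    reproduces the identical audiogram.
    """

    def __init__(self, transcripts: Mapping[tuple[str, int], Sequence[tuple[float, bool]]]):
        self._transcripts = {
            (ear, int(f)): list(h) for (ear, f), h in transcripts.items()
        }
        self._cursor: dict[tuple[str, int], int] = {}

    def respond(self, ear: str, freq: int, level: float) -> bool:
        key = (ear, int(freq))
        i = self._cursor.get(key, 0)
        try:
            rec_level, heard = self._transcripts[key][i]
        except (KeyError, IndexError):
            raise staircase.StaircaseError(
                f"transcript exhausted or missing for ({ear}, {freq} Hz)"
            )
        if abs(rec_level - level) > 1e-9:
            raise staircase.StaircaseError(
                f"transcript mismatch at ({ear}, {freq} Hz) presentation {i}: "
                f"recorded {rec_level}, expected {level}"
            )
        self._cursor[key] = i + 1
        return heard


def run_session(
    listener: Union[VirtualListener, TranscriptListener],
    config: SessionConfig | None = None,
) -> Audiogram:
    """Run one full test: a staircase per ear x frequency, in order.

    The listener only needs a ``respond(ear, freq, level) -> bool`` method;
    virtual listeners and transcript replayers both qualify.  Staircase
    non-convergence propagates as :class:`puretone.staircase.ConvergenceError`.
    """
    config = config or SessionConfig()
    entries: dict[tuple[str, int], AudiogramEntry] = {}
    histories: dict[tuple[str, int], tuple[tuple[float, bool], ...]] = {}
    for ear in config.ear_order:
        for freq in config.frequencies:
            track_cfg = config.track_config(freq)
            threshold, history = staircase.run_track(
                lambda level, ear=ear, freq=freq: listener.respond(ear, freq, level),
                track_cfg,
            )
            no_resp = threshold is NO_RESPONSE
            entries[(ear, freq)] = AudiogramEntry(
                ear=ear,
                freq_hz=freq,
                threshold_dbhl=None if no_resp else float(threshold),
                no_response=no_resp,
                category=None if no_resp else classify_threshold(threshold).label,
            )
            histories[(ear, freq)] = history
    metadata = {
        "frequencies": list(config.frequencies),
        "ear_order": list(config.ear_order),
        "noise_pause_threshold_dbspl": config.noise_pause_threshold,
        "masking": {
            "enabled": config.masking.enabled,
            "interaural_attenuation_db": config.masking.interaural_attenuation,
        },
        "retspl_transducer": config.retspl_table.transducer,
        "pause_events": [],
    }
    return Audiogram(entries=entries, histories=histories, metadata=metadata)


def should_pause(ambient_level: float, config: SessionConfig | None = None) -> bool:
    """Ambient-noise rule: pause iff the background level is strictly above
    the configured threshold (default 40 dB SPL)."""
    config = config or SessionConfig()
    return float(ambient_level) > config.noise_pause_threshold


def masking_level(
    presentation: Union[LevelSPL, float], params: MaskingParams | None = None
) -> Optional[LevelSPL]:
    """Minimum masking-noise SPL for the non-test ear, or None if unneeded.

    A tone at ``presentation`` dB SPL can reach the opposite cochlea at
    ``presentation - IA``; masking noise of at least that level is required
    there.  When the margin is zero or negative no crossover response is
    possible and the function returns None.
    """
    params = params or MaskingParams()
    margin = _as_value(presentation) - params.interaural_attenuation
    if margin <= 0:
        return None
    return LevelSPL(margin)


def plot_audiogram(audiogram: Audiogram, ax=None, title: str | None = None):
    """Plot in clinical orientation: log-frequency x-axis, inverted dB HL
    y-axis, circles for the right ear and crosses for the left."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 5))
    style = {"right": dict(marker="o", color="red"), "left": dict(marker="x", color="blue")}
    for ear in ("right", "left"):
        pts = [
            (e.freq_hz, e.threshold_dbhl)
            for (er, _f), e in sorted(audiogram.entries.items())
            if er == ear and not e.no_response
        ]
        if pts:
            xs, ys = zip(*pts)
            ax.plot(xs, ys, linestyle="-", label=f"{ear} ear", **style.get(ear, {}))
        ceil = [
            (e.freq_hz, max_level_hl(e.freq_hz).value)
            for (er, _f), e in sorted(audiogram.entries.items())
            if er == ear and e.no_response
        ]
        if ceil:
            xs, ys = zip(*ceil)
            ax.scatter(xs, ys, marker="v", **{k: v for k, v in style.get(ear, {}).items() if k == "color"})
    ax.set_xscale("log")
    ax.set_xticks(list(TEST_FREQUENCIES))
    ax.set_xticklabels([str(f) for f in TEST_FREQUENCIES])
    ax.set_xlabel("Frequency (Hz)")
    ax.set_ylabel("Hearing level (dB HL)")
    ax.set_ylim(120, -10)
    ax.grid(True, which="both", alpha=0.3)
    ax.legend()
    if title:
        ax.set_title(title)
    return ax
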