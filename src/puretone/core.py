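"""Units, reference levels, and audiogram classification for air-conduction audiometry.

Two decibel scales coexist in a hearing test and must never be confused:

* **dB HL** (hearing level) — level relative to the average normal-hearing
  threshold at each frequency; 0 dB HL is the normative threshold.
* **dB SPL** (sound pressure level) — absolute level re 20 µPa.

The bridge between them is the per-frequency, per-transducer RETSPL
(reference equivalent threshold sound pressure level)::

    dB SPL = dB HL + RETSPL(frequency)

This module carries the typed level wrappers (:class:`LevelHL`,
:class:`LevelSPL`), the :class:`RetsplTable` container with the packaged
reference tables, the HL/SPL conversions, the per-frequency presentation
ceilings of the smartphone test, and the ASHA severity categories used to
label an audiogram.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "TEST_FREQUENCIES",
    "NO_RESPONSE",
    "LevelHL",
    "LevelSPL",
    "RetsplTable",
    "HearingCategory",
    "ASHA_CATEGORIES",
    "load_retspl_tables",
    "packaged_retspl_tables",
    "hl_to_spl",
    "spl_to_hl",
    "classify_threshold",
    "max_level_hl",
    "FrequencyError",
]

#: The six octave test frequencies of the hearing test, in Hz.
TEST_FREQUENCIES: tuple[int, ...] = (250, 500, 1000, 2000, 4000, 8000)

#: Plausibility bound on |RETSPL| enforced when loading a table, in dB.
_RETSPL_BOUND = 50.0


class _NoResponse:
    """Sentinel recorded when no threshold exists (no response at ceiling)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NO_RESPONSE"

    def __bool__(self) -> bool:
        return False


#: Singleton sentinel for "no response at the maximum presentable level".
NO_RESPONSE = _NoResponse()


class FrequencyError(KeyError):
    """Raised when a frequency outside the supported test set is requested."""


def _check_frequency(freq: int) -> int:
    freq = int(freq)
    if freq not in TEST_FREQUENCIES:
        raise FrequencyError(
            f"unsupported test frequency {freq} Hz; expected one of {TEST_FREQUENCIES}"
        )
    return freq


@dataclass(frozen=True)
class LevelHL:
    """A hearing level in dB HL, restricted to the audiometric range [-10, 120]."""

    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("dB HL level must be finite")
        if not -10.0 <= self.value <= 120.0:
            raise ValueError(f"dB HL level {self.value} outside [-10, 120]")


@dataclass(frozen=True)
class LevelSPL:
    """A sound pressure level in dB SPL (re 20 µPa)."""

    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("dB SPL level must be finite")


def _as_value(level: Union[LevelHL, LevelSPL, float]) -> float:
    if isinstance(level, (LevelHL, LevelSPL)):
        return level.value
    return float(level)


@dataclass(frozen=True)
class RetsplTable:
    """Per-frequency RETSPL values for one transducer profile.

    Parameters
    ----------
    transducer : str
        Name of the transducer profile (e.g. ``"ER-3A"`` insert earphones).
    entries : mapping of int to float
        RETSPL in dB SPL for each of the six test frequencies.
    """

    transducer: str
    entries: Mapping[int, float]

    def __post_init__(self) -> None:
        entries = {int(f): float(v) for f, v in self.entries.items()}
        if set(entries) != set(TEST_FREQUENCIES):
            raise ValueError(
                f"RETSPL table '{self.transducer}' must cover exactly the "
                f"frequencies {TEST_FREQUENCIES}; got {sorted(entries)}"
            )
        for f, v in entries.items():
            if not math.isfinite(v) or abs(v) > _RETSPL_BOUND:
                raise ValueError(
                    f"implausible RETSPL {v} dB SPL at {f} Hz in table "
                    f"'{self.transducer}' (|RETSPL| must be <= {_RETSPL_BOUND})"
                )
        object.__setattr__(self, "entries", entries)

    def retspl(self, freq: int) -> float:
        """RETSPL in dB SPL at ``freq`` Hz; raises :class:`FrequencyError` otherwise."""
        return self.entries[_check_frequency(freq)]

    def __getitem__(self, freq: int) -> float:
        return self.retspl(freq)

    def row(self) -> list:
        """The table row in packaged-file order: name, then RETSPLs by frequency."""
        return [self.transducer] + [self.entries[f] for f in TEST_FREQUENCIES]


_HEADER = ["transducer"] + [f"f{f}" for f in TEST_FREQUENCIES]


def load_retspl_tables(path: Union[str, Path]) -> dict[str, RetsplTable]:
    """Load RETSPL tables from a delimited text file.

    The format is a CSV with header ``transducer,f250,f500,f1000,f2000,f4000,f8000``
    and one row per transducer profile.
    """
    with open(path, newline="") as fh:
        return _parse_retspl(fh)


def _parse_retspl(fh: Iterable[str]) -> dict[str, RetsplTable]:
    reader = csv.reader(fh)
    header = next(reader)
    if [h.strip() for h in header] != _HEADER:
        raise ValueError(f"bad RETSPL table header {header!r}; expected {_HEADER!r}")
    tables: dict[str, RetsplTable] = {}
    for line in reader:
        if not line:
            continue
        name = line[0].strip()
        entries = {f: float(x) for f, x in zip(TEST_FREQUENCIES, line[1:])}
        tables[name] = RetsplTable(name, entries)
    return tables


def write_retspl_tables(tables: Iterable[RetsplTable], path: Union[str, Path]) -> None:
    """Write RETSPL tables in the same delimited format they are loaded from."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for t in tables:
            writer.writerow(t.row())


def packaged_retspl_tables() -> dict[str, RetsplTable]:
    """The RETSPL tables shipped with the package.

    Rows: ``ER-3A`` (ANSI S3.6-2010 insert-earphone reference), ``HearTest v1``
    (initial smartphone-earphone estimate) and ``HearTest v2`` (the same
    combination after median-difference calibration).
    """
    ref = resources.files("puretone.data").joinpath("retspl.csv")
    with ref.open(newline="") as fh:
        return _parse_retspl(fh)


def hl_to_spl(
    level: Union[LevelHL, float], freq: int, table: RetsplTable
) -> LevelSPL:
    """Convert a hearing level to the sound pressure level a transducer must emit.

    Implements ``dB SPL = dB HL + RETSPL`` for the given transducer profile.
    """
    return LevelSPL(_as_value(level) + table.retspl(freq))


def spl_to_hl(
    level: Union[LevelSPL, float], freq: int, table: RetsplTable
) -> LevelHL:
    """Convert a sound pressure level back to hearing level (inverse of
    :func:`hl_to_spl`; the two round-trip exactly)."""
    return LevelHL(_as_value(level) - table.retspl(freq))


@dataclass(frozen=True)
class HearingCategory:
    """One ASHA hearing-loss severity band.

    ``lower_bound_dbhl``/``upper_bound_dbhl`` are the nominal printed bounds;
    classification treats the bands as contiguous half-open intervals
    ``(lower - 1, upper]`` so that every real-valued threshold falls in
    exactly one band, with thresholds below 0 dB HL counted as normal.
    """

    label: str
    lower_bound_dbhl: float
    upper_bound_dbhl: float


#: ASHA severity stratification, ordered by increasing severity.
ASHA_CATEGORIES: tuple[HearingCategory, ...] = (
    HearingCategory("normal", 0.0, 25.0),
    HearingCategory("mild", 26.0, 40.0),
    HearingCategory("moderate", 41.0, 55.0),
    HearingCategory("moderately_severe", 56.0, 70.0),
    HearingCategory("severe", 71.0, 90.0),
    HearingCategory("profound", 91.0, math.inf),
)

# Classification uses the upper bounds as cut points: threshold <= 25 -> normal,
# 25 < t <= 40 -> mild, ... , 90 < t -> profound.  A threshold of exactly
# 90 dB HL is severe, preserving the stated severe upper bound.
_CUTS = [25.0, 40.0, 55.0, 70.0, 90.0]


def classify_threshold(threshold: Union[LevelHL, float]) -> HearingCategory:
    """Map a hearing threshold (dB HL) to its ASHA severity category.

    Total over the constructible range: thresholds below 0 dB HL
    (better-than-normative hearing) classify as normal.
    """
    t = _as_value(threshold)
    for cut, cat in zip(_CUTS, ASHA_CATEGORIES):
        if t <= cut:
            return cat
    return ASHA_CATEGORIES[-1]


def max_level_hl(freq: int) -> LevelHL:
    """Maximum presentable hearing level of the smartphone test at ``freq``.

    The test spans -10 to 80 dB HL, except at 250 Hz where the transducer
    output caps the range at 75 dB HL.
    """
    _check_frequency(freq)
    return LevelHL(75.0 if freq == 250 else 80.0)
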