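"""Virtual listeners: synthetic subjects for exercising the hearing test.

A :class:`VirtualListener` carries per-ear, per-frequency true hearing
thresholds and a psychometric response model mapping presentation level to
the probability of an "I can hear it" button press:

* ``step`` — deterministic: heard iff level >= true threshold (boundary
  inclusive).
* ``logistic`` — heard with probability
  ``guess + (1 - guess - lapse) * F(slope * (level - threshold))`` where
  ``F`` is the standard logistic CDF and ``slope`` is the psychometric
  steepness in dB^-1.  ``guess`` models spurious presses far below
  threshold, ``lapse`` models misses far above it (including the instructed
  "unsure means I can't hear it" behaviour).

Cohort builders draw per-frequency thresholds from a normal distribution,
quantized to 1 dB and clamped to the audiometric range, emulating pools of
normal-hearing volunteers.  Thresholds are sampled independently across
ears and frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import TEST_FREQUENCIES

__all__ = [
    "EARS",
    "VirtualListener",
    "CohortSpec",
    "sample_cohort",
    "as_device_listener",
    "cohort_to_frame",
    "cohort_to_csv",
    "cohort_from_frame",
]

EARS: tuple[str, str] = ("right", "left")

_MIN_THRESHOLD, _MAX_THRESHOLD = -10.0, 120.0


@dataclass
class VirtualListener:
    """One simulated subject.

    Parameters
    ----------
    thresholds : mapping of (ear, freq) to float
        True hearing thresholds in dB HL.
    model : {"step", "logistic"}
        Response model.  ``step`` ignores slope/guess/lapse and the RNG.
    slope : float
        Psychometric steepness in dB^-1; at the default 2.0 the function
        rises from ~12% to ~88% over ±1 dB around threshold (logistic
        scale 1/slope = 0.5 dB).
    guess_rate, lapse_rate : float
        Floor and ceiling deviations of the psychometric function, each in
        [0, 0.1].
    seed : int
        Seed of the listener's private RNG; responses are reproducible.
    """

    thresholds: Mapping[tuple[str, int], float]
    model: str = "step"
    slope: float = 2.0
    guess_rate: float = 0.01
    lapse_rate: float = 0.01
    seed: int = 0
    listener_id: str = "listener"
    _rng: np.random.Generator = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.model not in ("step", "logistic"):
            raise ValueError(f"unknown response model {self.model!r}")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        for name, rate in (("guess_rate", self.guess_rate), ("lapse_rate", self.lapse_rate)):
            if not 0.0 <= rate <= 0.1:
                raise ValueError(f"{name} must lie in [0, 0.1]; got {rate}")
        self.thresholds = {
            (str(ear), int(freq)): float(t) for (ear, freq), t in self.thresholds.items()
        }
        for key, t in self.thresholds.items():
            if not _MIN_THRESHOLD <= t <= _MAX_THRESHOLD:
                raise ValueError(f"threshold {t} dB HL at {key} outside audiometric range")
        self._rng = np.random.default_rng(self.seed)

    def true_threshold(self, ear: str, freq: int) -> float:
        try:
            return self.thresholds[(ear, int(freq))]
        except KeyError:
            raise KeyError(f"listener has no threshold defined for ({ear}, {freq} Hz)")

    def p_heard(self, ear: str, freq: int, level: float) -> float:
        """Probability of a heard response at ``level`` dB HL."""
        t = self.true_threshold(ear, freq)
        if self.model == "step":
            return 1.0 if level >= t else 0.0
        p = expit(self.slope * (level - t))
        return self.guess_rate + (1.0 - self.guess_rate - self.lapse_rate) * p

    def respond(self, ear: str, freq: int, level: float) -> bool:
        """Simulate one button press at ``level`` dB HL."""
        p = self.p_heard(ear, freq, level)
        if p >= 1.0:
            return True
        if p <= 0.0:
            return False
        return bool(self._rng.random() < p)

    def reset(self) -> None:
        """Rewind the private RNG so a stochastic session replays identically."""
        self._rng = np.random.default_rng(self.seed)


def _per_freq(value: Union[float, Mapping[int, float]]) -> dict[int, float]:
    if isinstance(value, Mapping):
        return {int(f): float(value[f]) for f in TEST_FREQUENCIES}
    return {f: float(value) for f in TEST_FREQUENCIES}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a simulated cohort.

    ``threshold_mean``/``threshold_sd`` may be scalars or per-frequency
    maps (dB HL).  Defaults describe a normal-hearing pool: mean 5 dB HL,
    SD 8 dB, logistic responders with a 2 dB^-1 psychometric steepness and
    1% guess/lapse rates.
    """

    n_listeners: int
    threshold_mean: Union[float, Mapping[int, float]] = 5.0
    threshold_sd: Union[float, Mapping[int, float]] = 8.0
    model: str = "logistic"
    slope: float = 2.0
    guess_rate: float = 0.01
    lapse_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_listeners < 1:
            raise ValueError("n_listeners must be >= 1")
        if any(sd < 0 for sd in _per_freq(self.threshold_sd).values()):
            raise ValueError("threshold SD must be >= 0")


def sample_cohort(spec: CohortSpec) -> list[VirtualListener]:
    """Draw ``spec.n_listeners`` virtual listeners.

    Thresholds are sampled i.i.d. per ear x frequency from
    ``Normal(mean[f], sd[f])``, rounded to 1 dB and clamped to the
    audiometric range.  Deterministic under ``spec.seed``; each listener
    also receives an independent response-RNG seed derived from it.
    """
    means = _per_freq(spec.threshold_mean)
    sds = _per_freq(spec.threshold_sd)
    root = np.random.SeedSequence(spec.seed)
    threshold_rng = np.random.default_rng(root.spawn(1)[0])
    listener_seeds = root.generate_state(spec.n_listeners + 1)[1:]
    cohort = []
    for i in range(spec.n_listeners):
        thresholds = {}
        for ear in EARS:
            for f in TEST_FREQUENCIES:
                t = threshold_rng.normal(means[f], sds[f])
                thresholds[(ear, f)] = float(
                    np.clip(np.round(t), _MIN_THRESHOLD, _MAX_THRESHOLD)
                )
        cohort.append(
            VirtualListener(
                thresholds=thresholds,
                model=spec.model,
                slope=spec.slope,
                guess_rate=spec.guess_rate,
                lapse_rate=spec.lapse_rate,
                seed=int(listener_seeds[i] % (2**31)),
                listener_id=f"L{i:03d}",
            )
        )
    return cohort


def balanced_calibration_cohort(n_listeners: int = 20) -> list[VirtualListener]:
    """Deterministic cohort purpose-built for validating RETSPL calibration.

    The adaptive staircase reports thresholds on a 5 dB grid, so the
    median threshold difference can only identify a RETSPL error up to
    grid-quantization bias.  That bias cancels in the median when the true
    thresholds' residues modulo the 5 dB grid are balanced; this cohort
    alternates thresholds congruent to 1 and 3 (mod 5), spread over
    11-33 dB HL so that injected errors up to +/-15 dB keep every apparent
    threshold clear of the -10 dB HL floor and the presentation ceilings.
    ``n_listeners`` should be even to keep the residue split exact.
    """
    base_values = [11, 13, 16, 18, 21, 23, 26, 28, 31, 33]
    cohort = []
    for i in range(n_listeners):
        thresholds = {}
        for e, ear in enumerate(EARS):
            for j, f in enumerate(TEST_FREQUENCIES):
                idx = (2 * i + e + j) % len(base_values)
                thresholds[(ear, f)] = float(base_values[idx])
        cohort.append(
            VirtualListener(thresholds=thresholds, model="step", listener_id=f"C{i:03d}")
        )
    return cohort


def as_device_listener(
    listener: VirtualListener, retspl_error: Mapping[int, float]
) -> VirtualListener:
    """The same subject as seen through a miscalibrated device.

    A device whose assumed RETSPL understates the true transducer output by
    ``retspl_error[f]`` dB plays every tone that much softer than it
    believes, so it measures thresholds shifted up by exactly that error.
    The returned listener has apparent thresholds
    ``true + retspl_error[freq]`` and otherwise identical response
    behaviour.
    """
    errors = {int(f): float(e) for f, e in retspl_error.items()}
    shifted = {
        (ear, f): np.clip(t + errors.get(f, 0.0), _MIN_THRESHOLD, _MAX_THRESHOLD)
        for (ear, f), t in listener.thresholds.items()
    }
    return replace(listener, thresholds=shifted)


def cohort_to_frame(cohort: Sequence[VirtualListener]) -> pd.DataFrame:
    """Flatten a cohort to a table with one row per listener x ear x frequency."""
    rows = [
        {
            "listener_id": lst.listener_id,
            "ear": ear,
            "freq_hz": freq,
            "true_threshold_dbhl": t,
        }
        for lst in cohort
        for (ear, freq), t in sorted(lst.thresholds.items())
    ]
    return pd.DataFrame(rows)


def cohort_to_csv(cohort: Sequence[VirtualListener], path: Union[str, Path]) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def cohort_from_frame(
    frame: pd.DataFrame, model: str = "step", **model_kwargs
) -> list[VirtualListener]:
    """Rebuild listeners from a table written by :func:`cohort_to_frame`."""
    base_seed = int(model_kwargs.pop("seed", 0))
    cohort = []
    for i, (lid, grp) in enumerate(frame.groupby("listener_id", sort=True)):
        thresholds = {
            (r.ear, int(r.freq_hz)): float(r.true_threshold_dbhl)
            for r in grp.itertuples()
        }
        cohort.append(
            VirtualListener(
                thresholds=thresholds,
                model=model,
                listener_id=str(lid),
                seed=base_seed + i,
                **model_kwargs,
            )
        )
    return cohort
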