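"""Calibrated stimulus synthesis and level metering.

A smartphone plays test tones at its maximum hardware volume; calibration
rests on the measured full-scale output of each device, channel and
frequency (dB SPL on a 2-cc coupler).  The digital amplitude needed for a
target SPL is then simply::

    amplitude = 10 ** ((target_spl - max_output_spl) / 20)

A target above the device maximum is unreachable — this is exactly what
caps the testable dB HL range.

Tones are rendered as continuous sines with 20 ms raised-cosine
onset/offset ramps (continuous presentation minimises harmonic distortion
and attention lapses; the ramps avoid spectral splatter).  Masking noise is
one-third-octave band-limited noise centred on the test frequency, the
clinical convention for narrow-band maskers.  The level meter is an
unweighted RMS meter referenced to the same full-scale calibration and
drives the ambient-noise pause rule.

Audio is written as standard uncompressed WAV (32-bit float).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
from scipy.io import wavfile

from .core import LevelSPL, _as_value

__all__ = [
    "DeviceProfile",
    "ToneSpec",
    "amplitude_for_spl",
    "render_tone",
    "render_masking_noise",
    "measure_spl",
    "meter_reference",
    "write_wav",
    "read_wav",
    "OutputRangeError",
]

#: RMS of a full-scale sine relative to full scale, in dB (20*log10(1/sqrt2)).
_SINE_RMS_DBFS = 20.0 * math.log10(1.0 / math.sqrt(2.0))

_PLAUSIBLE_MAX_OUTPUT = (60.0, 130.0)


class OutputRangeError(ValueError):
    """Requested SPL exceeds what the device can produce at full scale."""


@dataclass(frozen=True)
class DeviceProfile:
    """Full-scale calibration of one device: per (channel, frequency)
    maximum output in dB SPL.  Built from a measured device-output table."""

    device: str
    max_output: Mapping[tuple[str, int], float]

    def __post_init__(self) -> None:
        cleaned = {
            (str(ch), int(f)): float(v) for (ch, f), v in self.max_output.items()
        }
        lo, hi = _PLAUSIBLE_MAX_OUTPUT
        for key, v in cleaned.items():
            if not lo <= v <= hi:
                raise ValueError(
                    f"implausible max output {v} dB SPL at {key} for {self.device} "
                    f"(expected within [{lo}, {hi}])"
                )
        object.__setattr__(self, "max_output", cleaned)

    @classmethod
    def from_output_table(cls, table, device: str) -> "DeviceProfile":
        """Extract one device's profile from a
        :class:`puretone.calibrate.DeviceOutputTable`."""
        from .core import TEST_FREQUENCIES

        rows = table.data[table.data["device"] == device]
        if rows.empty:
            raise KeyError(f"device {device!r} not in output table")
        max_output = {
            (str(r["channel"]), f): float(r[f"f{f}"])
            for _, r in rows.iterrows()
            for f in TEST_FREQUENCIES
        }
        return cls(device=device, max_output=max_output)

    def max_spl(self, channel: str, freq: int) -> float:
        try:
            return self.max_output[(channel, int(freq))]
        except KeyError:
            raise KeyError(f"profile {self.device!r} has no entry for ({channel}, {freq} Hz)")


@dataclass(frozen=True)
class ToneSpec:
    """One continuous pure-tone stimulus."""

    frequency: float
    level_spl: float
    channel: str = "L"
    duration: float = 1.0
    sample_rate: int = 44100

    def __post_init__(self) -> None:
        if not 0 < self.frequency < self.sample_rate / 2:
            raise ValueError(
                f"frequency {self.frequency} Hz must lie below Nyquist "
                f"({self.sample_rate / 2} Hz)"
            )
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def amplitude_for_spl(
    target: Union[LevelSPL, float], freq: int, channel: str, profile: DeviceProfile
) -> float:
    """Full-scale fraction producing ``target`` dB SPL under the profile.

    Raises :class:`OutputRangeError` when the target exceeds the device
    maximum at that channel/frequency.
    """
    target = _as_value(target)
    max_out = profile.max_spl(channel, freq)
    if target > max_out:
        raise OutputRangeError(
            f"target {target} dB SPL exceeds device maximum {max_out} dB SPL "
            f"at ({channel}, {freq} Hz) on {profile.device}"
        )
    return 10.0 ** ((target - max_out) / 20.0)


def _raised_cosine_ramps(n: int, sample_rate: int, ramp_s: float = 0.020) -> np.ndarray:
    env = np.ones(n)
    n_ramp = min(int(round(ramp_s * sample_rate)), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def render_tone(
    spec: ToneSpec, profile: DeviceProfile, ramp_s: float = 0.020
) -> np.ndarray:
    """Render a calibrated pure tone as a float array in [-1, 1].

    The steady-state amplitude is :func:`amplitude_for_spl` for the spec's
    level; raised-cosine ramps of ``ramp_s`` seconds shape onset and offset.
    """
    # Only the measured calibration frequencies can be rendered; no
    # interpolation of the device frequency response between them.
    amp = amplitude_for_spl(
        spec.level_spl, int(round(spec.frequency)), spec.channel, profile
    )
    n = int(round(spec.duration * spec.sample_rate))
    t = np.arange(n) / spec.sample_rate
    tone = amp * np.sin(2.0 * np.pi * spec.frequency * t)
    return tone * _raised_cosine_ramps(n, spec.sample_rate, ramp_s)


def render_masking_noise(
    center: int,
    level: Union[LevelSPL, float],
    channel: str,
    profile: DeviceProfile,
    duration: float = 1.0,
    sample_rate: int = 44100,
    rng: Optional[np.random.Generator] = None,
    ramp_s: float = 0.020,
) -> np.ndarray:
    """One-third-octave band noise centred on ``center`` Hz at ``level`` dB SPL.

    Gaussian noise is band-limited in the frequency domain to
    [center / 2^(1/6), center * 2^(1/6)] and scaled so its RMS meters at the
    requested SPL under the profile calibration.  Different RNG states give
    different waveforms with identical RMS.
    """
    rng = rng or np.random.default_rng()
    level = _as_value(level)
    max_out = profile.max_spl(channel, center)
    if level > max_out:
        raise OutputRangeError(
            f"masking level {level} dB SPL exceeds device maximum {max_out} dB SPL"
        )
    n = int(round(duration * sample_rate))
    noise = rng.standard_normal(n)
    spectrum = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    lo, hi = center / 2 ** (1 / 6), center * 2 ** (1 / 6)
    spectrum[(freqs < lo) | (freqs > hi)] = 0.0
    band = np.fft.irfft(spectrum, n)
    # Target RMS: a signal with RMS r meters at 20*log10(r) + reference.
    target_rms = 10.0 ** ((level - meter_reference(profile, channel, center)) / 20.0)
    band *= target_rms / np.sqrt(np.mean(band**2))
    return band * _raised_cosine_ramps(n, sample_rate, ramp_s)


def meter_reference(profile: DeviceProfile, channel: str, freq: int) -> float:
    """SPL produced by a signal of unit RMS (0 dBFS RMS) at this calibration
    point: the full-scale sine produces ``max_output`` SPL at an RMS 3.01 dB
    below full scale, so the unit-RMS reference sits 3.01 dB above it."""
    return profile.max_spl(channel, freq) - _SINE_RMS_DBFS


def measure_spl(buffer: np.ndarray, reference: float) -> float:
    """Unweighted RMS level of a buffer against a full-scale reference.

    ``reference`` is the SPL of a unit-RMS signal (see
    :func:`meter_reference`).  Digital silence returns ``-inf`` ("below
    floor"); an empty buffer is an error.
    """
    buffer = np.asarray(buffer, dtype=float)
    if buffer.size == 0:
        raise ValueError("cannot meter an empty buffer")
    rms = float(np.sqrt(np.mean(buffer**2)))
    if rms == 0.0:
        return -math.inf
    return 20.0 * math.log10(rms) + reference


def write_wav(path: Union[str, Path], buffer: np.ndarray, sample_rate: int = 44100) -> None:
    """Write a mono float buffer as an uncompressed 32-bit-float WAV file."""
    wavfile.write(str(path), sample_rate, np.asarray(buffer, dtype=np.float32))


def read_wav(path: Union[str, Path]) -> tuple[int, np.ndarray]:
    sample_rate, data = wavfile.read(str(path))
    return int(sample_rate), np.asarray(data, dtype=float)
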