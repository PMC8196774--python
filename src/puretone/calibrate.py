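"""RETSPL calibration from paired measurements, and agreement statistics.

A smartphone-earphone combination starts with guessed RETSPL values.  Each
normal-hearing volunteer is tested twice — on a reference clinical
audiometer and on the device — yielding paired thresholds per ear and
frequency.  Because ``dB SPL = dB HL + RETSPL`` is linear, a per-frequency
RETSPL error shifts every device-measured threshold by the same amount, so
the calibration is a per-frequency location estimate:

    median_diff[f] = median over ears of (audiometer - device)
    RETSPL_corrected[f] = RETSPL_assumed[f] - median_diff[f]

The median (not the mean) is used because threshold differences are not
normally distributed and the median resists outliers.  The sign follows
from the level equation: a device playing softer than it believes
(RETSPL_true > RETSPL_assumed) measures thresholds too high, making
(audiometer - device) negative, and the correction raises the table.

The module also provides the agreement statistics used to evaluate a
calibration — pooled Spearman rank correlation and per-frequency mean
absolute error — and the inter-device variability analysis of maximum
output levels measured with a 2-cc coupler.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from . import staircase
from .core import NO_RESPONSE, TEST_FREQUENCIES, RetsplTable, max_level_hl
from .listeners import VirtualListener, as_device_listener

__all__ = [
    "PairedMeasurements",
    "DeviceOutputTable",
    "packaged_device_output_table",
    "median_threshold_difference",
    "correct_retspl",
    "spearman_rank_correlation",
    "mean_absolute_error",
    "device_output_spread",
    "simulate_paired_measurements",
    "calibration_report",
]

_PAIR_COLUMNS = ["ear_id", "freq_hz", "audiometer_dbhl", "device_dbhl"]


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired audiometer/device thresholds, one row per ear x frequency.

    Rows where either instrument recorded no response at its ceiling carry
    no numeric threshold and are excluded on construction;
    ``n_no_response`` counts them so the exclusion is auditable.
    """

    data: pd.DataFrame
    n_no_response: int = 0
    frequencies_seen: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        missing = [c for c in _PAIR_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"paired measurements missing columns {missing}")
        df = df[_PAIR_COLUMNS]
        df["freq_hz"] = df["freq_hz"].astype(int)
        object.__setattr__(
            self, "frequencies_seen", tuple(sorted(df["freq_hz"].unique()))
        )
        # NO_RESPONSE cells arrive as NaN, the sentinel, or "NR" text; drop pairwise.
        def _to_float(v):
            if v is NO_RESPONSE or (isinstance(v, str) and v.strip().upper() in ("NR", "NO_RESPONSE")):
                return np.nan
            return float(v)

        for col in ("audiometer_dbhl", "device_dbhl"):
            df[col] = df[col].map(_to_float)
        valid = df.dropna(subset=["audiometer_dbhl", "device_dbhl"])
        n_dropped = len(df) - len(valid)
        if valid.duplicated(subset=["ear_id", "freq_hz"]).any():
            raise ValueError("duplicate (ear_id, freq_hz) rows in paired measurements")
        out_of_range = ~valid[["audiometer_dbhl", "device_dbhl"]].apply(
            lambda s: s.between(-10.0, 120.0)
        ).all(axis=1)
        if out_of_range.any():
            raise ValueError("paired thresholds must lie within [-10, 120] dB HL")
        object.__setattr__(self, "data", valid.reset_index(drop=True))
        object.__setattr__(self, "n_no_response", self.n_no_response + n_dropped)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "PairedMeasurements":
        return cls(pd.read_csv(path))

    def to_csv(self, path: Union[str, Path]) -> None:
        self.data.to_csv(path, index=False)


def median_threshold_difference(data: PairedMeasurements) -> dict[int, float]:
    """Per-frequency median of (audiometer - device) threshold differences.

    With an even number of ears the median is the midpoint of the two
    central values, which is how calibrated tables acquire off-grid entries
    such as 7.3 dB SPL.  A frequency with no valid pair raises an error
    naming the frequency.
    """
    df = data.data
    out: dict[int, float] = {}
    for freq, grp in df.groupby("freq_hz"):
        diffs = grp["audiometer_dbhl"] - grp["device_dbhl"]
        out[int(freq)] = float(np.median(diffs))
    empty = [f for f in data.frequencies_seen if f not in out]
    if empty:
        raise ValueError(f"no valid paired measurements at {empty} Hz")
    if not out:
        raise ValueError("no valid paired measurements at any frequency")
    return out


def correct_retspl(
    old: RetsplTable, med_diff: Mapping[int, float], name: Optional[str] = None
) -> RetsplTable:
    """Apply the median-difference correction: new RETSPL = old - median(aud - dev)."""
    missing = [f for f in TEST_FREQUENCIES if f not in med_diff]
    if missing:
        raise ValueError(f"median differences missing frequencies {missing} Hz")
    entries = {f: old.retspl(f) - float(med_diff[f]) for f in TEST_FREQUENCIES}
    return RetsplTable(name or f"{old.transducer} (corrected)", entries)


def spearman_rank_correlation(
    data: PairedMeasurements, exact_below: int = 10
) -> tuple[float, float]:
    """Pooled Spearman rho between audiometer and device thresholds.

    Thresholds are pooled across all ears and frequencies; ties receive
    average ranks.  The two-sided p-value uses the large-sample t
    approximation, switching to exact permutation below ``exact_below``
    pairs where the approximation is unreliable.
    """
    df = data.data
    if len(df) < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    x = df["audiometer_dbhl"].to_numpy()
    y = df["device_dbhl"].to_numpy()
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    if len(df) < exact_below:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = abs(_pearson(rx, ry))
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson(rx, np.asarray(perm))) >= obs - 1e-12:
                count += 1
        p = count / total
    return rho, float(p)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        return 0.0
    return float(a @ b) / denom


def mean_absolute_error(data: PairedMeasurements) -> dict[int, tuple[float, float]]:
    """Per-frequency mean and SD of |audiometer - device|, in dB HL."""
    out: dict[int, tuple[float, float]] = {}
    for freq, grp in data.data.groupby("freq_hz"):
        err = (grp["audiometer_dbhl"] - grp["device_dbhl"]).abs().to_numpy()
        if err.size == 0:  # pragma: no cover - dropna removes such groups
            raise ValueError(f"no valid pairs at {freq} Hz")
        sd = float(np.std(err, ddof=1)) if err.size > 1 else 0.0
        out[int(freq)] = (float(err.mean()), sd)
    return out


@dataclass(frozen=True)
class DeviceOutputTable:
    """Maximum output (dB SPL, 2-cc coupler) per device, channel and frequency."""

    data: pd.DataFrame  # columns: device, channel, f250 ... f8000

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        freq_cols = [f"f{f}" for f in TEST_FREQUENCIES]
        missing = [c for c in ["device", "channel", *freq_cols] if c not in df.columns]
        if missing:
            raise ValueError(f"device output table missing columns {missing}")
        if not np.isfinite(df[freq_cols].to_numpy(dtype=float)).all():
            raise ValueError("device output levels must be finite")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def max_output(self, device: str, channel: str, freq: int) -> float:
        row = self.data[
            (self.data["device"] == device) & (self.data["channel"] == channel)
        ]
        if row.empty:
            raise KeyError(f"no entry for device {device!r} channel {channel!r}")
        return float(row.iloc[0][f"f{int(freq)}"])

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "DeviceOutputTable":
        return cls(pd.read_csv(path))


def packaged_device_output_table() -> DeviceOutputTable:
    """The shipped maximum-output measurements (three iPhone models, both
    channels, Sennheiser CX300 earphones on a 2-cc coupler)."""
    ref = resources.files("puretone.data").joinpath("device_max_output.csv")
    with ref.open() as fh:
        return DeviceOutputTable(pd.read_csv(fh))


def device_output_spread(
    table: DeviceOutputTable,
) -> tuple[pd.DataFrame, float]:
    """Inter-device output variability.

    For each (frequency, channel) the spread is max - min of the maximum
    output across devices.  Returns the per-cell spread table and the
    overall maximum spread in dB SPL — the figure of merit for whether one
    calibration can serve a whole device family.
    """
    df = table.data
    if df["device"].nunique() < 2:
        raise ValueError("device spread requires at least 2 devices")
    rows = []
    for channel, grp in df.groupby("channel"):
        for f in TEST_FREQUENCIES:
            col = grp[f"f{f}"].astype(float)
            rows.append(
                {
                    "freq_hz": f,
                    "channel": channel,
                    "spread_db": float(col.max() - col.min()),
                }
            )
    spread = pd.DataFrame(rows)
    return spread, float(spread["spread_db"].max())


def simulate_paired_measurements(
    cohort: Sequence[VirtualListener],
    retspl_error: Mapping[int, float],
    track_config: staircase.StaircaseConfig | None = None,
    frequencies: Sequence[int] = TEST_FREQUENCIES,
) -> PairedMeasurements:
    """Run the two-instrument study on a simulated cohort.

    Each listener's ears are tested twice with the adaptive staircase: once
    as-is (the reference audiometer, assumed perfectly calibrated) and once
    through :func:`~puretone.listeners.as_device_listener` with the injected
    per-frequency RETSPL error (the miscalibrated device).  Cells where
    either track ends in NO_RESPONSE become excluded rows.
    """
    base = track_config or staircase.StaircaseConfig()
    records = []
    for lst in cohort:
        device = as_device_listener(lst, retspl_error)
        ears = sorted({ear for ear, _f in lst.thresholds.keys()})
        for ear in ears:
            for freq in frequencies:
                cfg = replace(base, ceiling=max_level_hl(freq).value)
                t_aud, _ = staircase.run_track(
                    lambda lv, e=ear, f=freq: lst.respond(e, f, lv), cfg
                )
                t_dev, _ = staircase.run_track(
                    lambda lv, e=ear, f=freq: device.respond(e, f, lv), cfg
                )
                records.append(
                    {
                        "ear_id": f"{lst.listener_id}:{ear}",
                        "freq_hz": freq,
                        "audiometer_dbhl": np.nan if t_aud is NO_RESPONSE else t_aud,
                        "device_dbhl": np.nan if t_dev is NO_RESPONSE else t_dev,
                    }
                )
    return PairedMeasurements(pd.DataFrame(records))


def calibration_report(
    data: PairedMeasurements, old_table: RetsplTable, corrected_name: Optional[str] = None
) -> dict:
    """Full calibration pass: medians, corrected table, agreement statistics.

    Returns a dict with keys ``median_diff`` (per frequency), ``corrected``
    (:class:`RetsplTable`), ``rho``/``p_value`` (pooled Spearman), ``mae``
    (per-frequency mean and SD of |difference|), and ``n_no_response``.
    """
    med = median_threshold_difference(data)
    corrected = correct_retspl(old_table, med, name=corrected_name)
    rho, p = spearman_rank_correlation(data)
    mae = mean_absolute_error(data)
    return {
        "median_diff": med,
        "corrected": corrected,
        "rho": rho,
        "p_value": p,
        "mae": mae,
        "n_pairs": len(data),
        "n_no_response": data.n_no_response,
    }


def format_calibration_report(report: dict) -> str:
    """Human-readable text rendering of :func:`calibration_report` output."""
    lines = [
        f"calibration report ({report['n_pairs']} pairs, "
        f"{report['n_no_response']} no-response rows excluded)",
        f"Spearman rho = {report['rho']:.3f}, p = {report['p_value']:.4g}",
        "freq_hz  median_diff_db  mae_db  mae_sd_db  corrected_retspl_dbspl",
    ]
    corrected = report["corrected"]
    for f in TEST_FREQUENCIES:
        mae, sd = report["mae"].get(f, (float("nan"), float("nan")))
        med = report["median_diff"].get(f, float("nan"))
        lines.append(
            f"{f:7d}  {med:14.2f}  {mae:6.2f}  {sd:9.2f}  {corrected.retspl(f):22.2f}"
        )
    return "\n".join(lines) + "\n"
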