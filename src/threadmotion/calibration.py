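"""Calibration: per-channel baseline, calibrated maximum and calibrated minimum.

Each thread is hand-made, so its impedance at a given elongation differs
from every other thread's, and the value it settles to with the head facing
front only becomes apparent after the wearer repeats a few excursions.  The
calibration protocol therefore records repeated moves to each extreme with
returns to front; from that recording we estimate, per channel:

* ``baseline`` — the settled front-facing value, taken as the median of the
  plateau means in the most frequently visited plateau level (the protocol
  returns to front after every excursion, so front dwells dominate);
* ``cal_max`` / ``cal_min`` — the global extremes of the *filtered* signal
  over the full range of motion (filtering first protects the extremes from
  single-sample spikes).

All three estimates are shift- and scale-equivariant: thresholds are defined
relative to the observed signal range, never in absolute impedance units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import CalibrationError, ParameterError
from .preprocessing import moving_average

if TYPE_CHECKING:  # pragma: no cover
    from .io import Recording


@dataclass(frozen=True)
class ChannelCalibration:
    """Calibration anchors for one channel, in raw impedance units."""

    baseline: float
    cal_max: float
    cal_min: float

    def __post_init__(self) -> None:
        if not (self.cal_min < self.baseline < self.cal_max):
            raise CalibrationError(
                f"calibration ordering violated: need cal_min < baseline < cal_max, "
                f"got ({self.cal_min}, {self.baseline}, {self.cal_max})"
            )


@dataclass(frozen=True)
class CalibrationProfile:
    """Calibration anchors for both channels."""

    slash: ChannelCalibration
    backslash: ChannelCalibration

    def channel(self, name: str) -> ChannelCalibration:
        if name == "slash":
            return self.slash
        if name == "backslash":
            return self.backslash
        raise KeyError(f"unknown channel {name!r}")


@dataclass(frozen=True)
class CalibrationParams:
    """Knobs of the calibration estimators.

    flatness_frac: a window counts as flat when its rolling standard
    deviation is at most this fraction of the signal's observed range.
    gap_frac: plateau means split into clusters at every gap exceeding this
    fraction of the spread of the means.
    """

    filter_len: int = 120
    min_dwell_s: float = 0.5
    std_window_s: float = 0.25
    flatness_frac: float = 0.01
    gap_frac: float = 0.2


def _rolling_std(x: np.ndarray, window: int) -> np.ndarray:
    """Trailing rolling standard deviation with a growing warm-up window."""
    mean = moving_average(x, window)
    mean_sq = moving_average(x * x, window)
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var)


def detect_plateaus(
    signal: np.ndarray,
    sampling_rate: float,
    min_dwell_s: float = 0.5,
    flatness_threshold: float | None = None,
    std_window_s: float = 0.25,
) -> list[tuple[int, int]]:
    """Find maximal flat intervals (half-open sample index pairs).

    An interval qualifies when it spans at least ``min_dwell_s`` and the
    rolling standard deviation (window ``std_window_s``) stays at or below
    ``flatness_threshold``.  The default threshold is 1% of the signal's
    observed range, which makes detection invariant to offset and gain.
    """
    if min_dwell_s <= 0:
        raise ParameterError("min_dwell_s must be positive")
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        return []
    if flatness_threshold is None:
        flatness_threshold = 0.01 * float(np.ptp(x))
    window = max(int(round(std_window_s * sampling_rate)), 2)
    flat = _rolling_std(x, window) <= flatness_threshold
    min_len = int(round(min_dwell_s * sampling_rate))
    plateaus: list[tuple[int, int]] = []
    start = None
    for i, ok in enumerate(np.concatenate([flat, [False]])):
        if ok and start is None:
            start = i
        elif not ok and start is not None:
            if i - start >= min_len:
                plateaus.append((start, i))
            start = None
    return plateaus


def _cluster_means(means: np.ndarray, gap_frac: float) -> list[np.ndarray]:
    """1-D clustering: sort and split at every gap above gap_frac * spread."""
    order = np.argsort(means)
    sorted_means = means[order]
    spread = float(sorted_means[-1] - sorted_means[0])
    if spread == 0.0 or means.size == 1:
        return [sorted_means]
    threshold = gap_frac * spread
    clusters: list[np.ndarray] = []
    start = 0
    gaps = np.diff(sorted_means)
    for i, g in enumerate(gaps):
        if g > threshold:
            clusters.append(sorted_means[start : i + 1])
            start = i + 1
    clusters.append(sorted_means[start:])
    return clusters


def estimate_baseline(
    signal: np.ndarray,
    plateaus: Sequence[tuple[int, int]],
    gap_frac: float = 0.2,
) -> float:
    """Settled front value: median of plateau means in the most populous cluster.

    The protocol dwells at front after every excursion, so front plateaus
    outnumber plateaus held at any single extreme.
    """
    if not plateaus:
        raise CalibrationError(
            "no flat dwells found; record a longer calibration with clear pauses "
            "at the front position"
        )
    x = np.asarray(signal, dtype=float)
    means = np.array([float(np.mean(x[a:b])) for a, b in plateaus])
    clusters = _cluster_means(means, gap_frac)
    front_cluster = max(clusters, key=len)
    return float(np.median(front_cluster))


def estimate_extremes(signal: np.ndarray) -> tuple[float, float]:
    """Calibrated (min, max): the global extremes of the filtered calibration signal."""
    x = np.asarray(signal, dtype=float)
    if x.size < 1:
        raise ParameterError("signal must contain at least one sample")
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        raise CalibrationError(
            "signal is constant: no range of motion observed during calibration"
        )
    return lo, hi


def calibrate(
    recording: "Recording", params: CalibrationParams | None = None
) -> CalibrationProfile:
    """Full calibration of both channels from a calibration recording."""
    params = params or CalibrationParams()
    channels = {}
    for name in ("slash", "backslash"):
        filtered = moving_average(recording.channel(name), params.filter_len)
        plateaus = detect_plateaus(
            filtered,
            recording.sampling_rate,
            min_dwell_s=params.min_dwell_s,
            std_window_s=params.std_window_s,
            flatness_threshold=params.flatness_frac * float(np.ptp(filtered)),
        )
        baseline = estimate_baseline(filtered, plateaus, gap_frac=params.gap_frac)
        cal_min, cal_max = estimate_extremes(filtered)
        if not (cal_min < baseline < cal_max):
            raise CalibrationError(
                f"channel {name}: baseline {baseline:g} does not lie strictly "
                f"between extremes ({cal_min:g}, {cal_max:g}); re-run calibration "
                "covering excursions on both sides of front"
            )
        channels[name] = ChannelCalibration(
            baseline=baseline, cal_max=cal_max, cal_min=cal_min
        )
    return CalibrationProfile(slash=channels["slash"], backslash=channels["backslash"])


def save_profile(profile: CalibrationProfile, path: str | Path) -> None:
    doc = {
        name: {
            "baseline": ch.baseline,
            "cal_max": ch.cal_max,
            "cal_min": ch.cal_min,
        }
        for name, ch in (("slash", profile.slash), ("backslash", profile.backslash))
    }
    Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")


def load_profile(path: str | Path) -> CalibrationProfile:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return CalibrationProfile(
        slash=ChannelCalibration(**doc["slash"]),
        backslash=ChannelCalibration(**doc["backslash"]),
    )
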