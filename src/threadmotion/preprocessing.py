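"""Filtering, normalization and segmentation of the two-channel stream.

The pipeline order is: moving-average filter (length 120 samples at 1 kHz),
piecewise normalization against the calibration profile (baseline -> 0,
calibrated max -> +1, calibrated min -> -1), then division into overlapping
windows of 550 samples with a 250-sample overlap (hop 300).

The moving average is causal (trailing): output ``i`` averages the most
recent ``filter_len`` samples, with a growing window during warm-up so the
output has the same length as the input.  A causal filter needs no future
samples, which keeps the pipeline usable in a streaming setting.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .errors import ParameterError, SegmentationError
from .orientations import Orientation

if TYPE_CHECKING:  # pragma: no cover
    from .calibration import CalibrationProfile, ChannelCalibration
    from .io import Recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Lengths that shape the preprocessing stages (all in samples)."""

    filter_len: int = 120
    window_len: int = 550
    overlap_len: int = 250
    sampling_rate: float = 1000.0

    def __post_init__(self) -> None:
        if self.filter_len < 1:
            raise ParameterError(f"filter_len must be >= 1, got {self.filter_len}")
        if not (0 < self.overlap_len < self.window_len):
            raise ParameterError(
                f"need 0 < overlap_len < window_len, got overlap {self.overlap_len}, "
                f"window {self.window_len}"
            )
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")

    @property
    def hop(self) -> int:
        """Segment start spacing: window_len - overlap_len (default 300)."""
        return self.window_len - self.overlap_len


@dataclass
class Segment:
    """One window of the normalized stream, the basic unit of feature extraction.

    ``start_index`` is 0-based and the window covers the half-open interval
    ``[start_index, start_index + window_len)``.
    """

    start_index: int
    sampling_rate: float
    ch_slash: np.ndarray
    ch_backslash: np.ndarray
    label: Orientation | None = field(default=None)

    def __post_init__(self) -> None:
        self.ch_slash = np.asarray(self.ch_slash, dtype=float)
        self.ch_backslash = np.asarray(self.ch_backslash, dtype=float)
        if self.ch_slash.size != self.ch_backslash.size:
            raise ParameterError("segment channels must have equal length")

    def __len__(self) -> int:
        return int(self.ch_slash.size)

    @property
    def start_time_s(self) -> float:
        return self.start_index / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        return self.ch_slash if name == "slash" else self.ch_backslash


def moving_average(signal: np.ndarray, filter_len: int) -> np.ndarray:
    """Causal moving average with a growing warm-up window.

    ``out[i] = mean(signal[max(0, i - filter_len + 1) : i + 1])``; the output
    length equals the input length and a constant signal is preserved.
    """
    if filter_len < 1:
        raise ParameterError(f"filter_len must be >= 1, got {filter_len}")
    x = np.asarray(signal, dtype=float)
    if x.size == 0:
        raise ParameterError("cannot filter an empty signal")
    cs = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - filter_len + 1, 0)
    return (cs[idx + 1] - cs[lo]) / (idx + 1 - lo)


def normalize(signal: np.ndarray, channel_cal: "ChannelCalibration") -> np.ndarray:
    """Map raw impedance onto the normalized [-1, 1] scale, piecewise about the baseline.

    Values above the baseline are divided by (cal_max - baseline), values
    below by (baseline - cal_min), so the calibration anchors map to exactly
    {-1, 0, +1}.  Stretching and relaxing excursions of equal mechanical
    extent are thereby given equal weight despite the thread responding more
    strongly to elongation.  Values are *not* clipped: excursions beyond the
    calibrated extremes survive (the min-max range feature relies on them);
    they are counted and logged.
    """
    if not (channel_cal.cal_min < channel_cal.baseline < channel_cal.cal_max):
        raise ParameterError(
            "degenerate calibration: need cal_min < baseline < cal_max, got "
            f"({channel_cal.cal_min}, {channel_cal.baseline}, {channel_cal.cal_max})"
        )
    x = np.asarray(signal, dtype=float)
    shifted = x - channel_cal.baseline
    pos_span = channel_cal.cal_max - channel_cal.baseline
    neg_span = channel_cal.baseline - channel_cal.cal_min
    out = np.where(shifted >= 0, shifted / pos_span, shifted / neg_span)
    n_out = int(np.count_nonzero((out < -1.0) | (out > 1.0)))
    if n_out:
        logger.info("normalize: %d of %d samples fall outside [-1, 1]", n_out, out.size)
    return out


def preprocess_recording(
    recording: "Recording",
    profile: "CalibrationProfile",
    config: PipelineConfig | None = None,
) -> "Recording":
    """Filter then normalize both channels; labels and time axis pass through."""
    from .io import Recording

    config = config or PipelineConfig(sampling_rate=recording.sampling_rate)
    return Recording(
        sampling_rate=recording.sampling_rate,
        time=recording.time,
        ch_slash=normalize(
            moving_average(recording.ch_slash, config.filter_len), profile.slash
        ),
        ch_backslash=normalize(
            moving_average(recording.ch_backslash, config.filter_len), profile.backslash
        ),
        labels=recording.labels,
    )


def _majority_label(
    labels: Sequence[Orientation | None], center: Orientation | None
) -> Orientation | None:
    counts = Counter(lab for lab in labels if lab is not None)
    if not counts:
        return None
    ranked = counts.most_common()
    top = ranked[0][1]
    tied = [lab for lab, c in ranked if c == top]
    if len(tied) == 1:
        return tied[0]
    # tie: fall back to the label at the window's center sample
    return center if center in tied else tied[0]


def segment_stream(
    recording: "Recording", config: PipelineConfig | None = None
) -> list[Segment]:
    """Cut the (already filtered + normalized) stream into overlapping windows.

    Windows start at multiples of ``hop = window_len - overlap_len``; a
    trailing partial window is discarded.  When per-sample labels exist, each
    window takes the majority label within it (ties resolved by the label at
    the window's center sample).
    """
    config = config or PipelineConfig(sampling_rate=recording.sampling_rate)
    n = len(recording)
    w, hop = config.window_len, config.hop
    if n < w:
        raise SegmentationError(
            f"recording of {n} samples is shorter than one window ({w} samples)"
        )
    segments: list[Segment] = []
    for start in range(0, n - w + 1, hop):
        label = None
        if recording.labels is not None:
            window_labels = recording.labels[start : start + w]
            center = recording.labels[start + w // 2]
            label = _majority_label(window_labels, center)
        segments.append(
            Segment(
                start_index=start,
                sampling_rate=recording.sampling_rate,
                ch_slash=recording.ch_slash[start : start + w],
                ch_backslash=recording.ch_backslash[start : start + w],
                label=label,
            )
        )
    return segments
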