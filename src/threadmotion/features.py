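"""The six per-window predictors.

From each 550-sample window of the normalized two-channel stream we compute,
in this canonical order:

==============  =====================================================
``mu_slash``    mean of the "/" channel within the window
``mu_backslash``mean of the "\\" channel
``delta_mu``    mu_slash - mu_backslash (separates the horizontal axis,
                where the channels move oppositely, from the vertical
                axis where it stays near 0)
``rho``         Pearson correlation between the channels (negative for
                horizontal intermediates, positive for vertical motion
                and held positions)
``delta_slash`` max - min of the "/" channel (large while the head is
                actually moving, i.e. for intermediate orientations)
``delta_backslash``  max - min of the "\\" channel
==============  =====================================================

Six predictors means the Gaussian-kernel SVM scale sqrt(6) ~ 2.449 (2.4 to
one decimal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParameterError
from .preprocessing import Segment

#: Canonical feature column order used everywhere (tables, models, reports).
FEATURE_NAMES: tuple[str, ...] = (
    "mu_slash",
    "mu_backslash",
    "delta_mu",
    "rho",
    "delta_slash",
    "delta_backslash",
)

N_FEATURES = len(FEATURE_NAMES)


@dataclass(frozen=True)
class FeatureVector:
    mu_slash: float
    mu_backslash: float
    delta_mu: float
    rho: float
    delta_slash: float
    delta_backslash: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def segment_mean(segment: Segment, channel: str) -> float:
    """Mean of the normalized samples of one channel within the window."""
    x = segment.channel(channel)
    if x.size == 0:
        raise ParameterError("cannot take the mean of an empty segment")
    return float(np.mean(x))


def mean_difference(mu_slash: float, mu_backslash: float) -> float:
    """The "/" mean minus the "\\" mean."""
    return mu_slash - mu_backslash


def correlation(segment: Segment) -> float:
    """Pearson correlation between the two channels within the window.

    A zero-variance channel has no linear relationship to measure; the
    defined fallback is 0.
    """
    x, y = segment.ch_slash, segment.ch_backslash
    if x.size < 2:
        raise ParameterError("correlation needs at least 2 samples")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def minmax_range(segment: Segment, channel: str) -> float:
    """|max - min| of one channel within the window (the in-window swing)."""
    x = segment.channel(channel)
    if x.size == 0:
        raise ParameterError("cannot take the range of an empty segment")
    return float(np.max(x) - np.min(x))


def extract_features(segment: Segment) -> FeatureVector:
    """Assemble the six predictors for one window."""
    mu_s = segment_mean(segment, "slash")
    mu_b = segment_mean(segment, "backslash")
    return FeatureVector(
        mu_slash=mu_s,
        mu_backslash=mu_b,
        delta_mu=mean_difference(mu_s, mu_b),
        rho=correlation(segment),
        delta_slash=minmax_range(segment, "slash"),
        delta_backslash=minmax_range(segment, "backslash"),
    )


def feature_table(segments: Iterable[Segment]) -> pd.DataFrame:
    """Per-segment feature table with traceability columns.

    Columns: ``start_index``, ``start_time_s``, the six features in
    canonical order, and ``label`` (empty string where unlabeled).
    """
    rows = []
    for seg in segments:
        fv = extract_features(seg)
        row = {"start_index": seg.start_index, "start_time_s": seg.start_time_s}
        row.update({name: getattr(fv, name) for name in FEATURE_NAMES})
        row["label"] = "" if seg.label is None else str(seg.label)
        rows.append(row)
    return pd.DataFrame(rows)


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Split a feature table into (X, y) for training; y holds label strings."""
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=object)
    return X, y
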