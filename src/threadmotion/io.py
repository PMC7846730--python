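"""Reading and writing recordings, calibration profiles, feature tables and reports.

The two impedance channels are named ``slash`` and ``backslash`` after the
"/" and "\\" threads of the X layout; the literal characters are avoided in
file headers because of escape ambiguity.  Recordings travel as CSV with
columns ``time_s, ch_slash, ch_backslash, label`` (label optional / may be
empty), UTF-8, "." decimal separator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import FormatError, SchemaError
from .orientations import Orientation

if TYPE_CHECKING:  # pragma: no cover
    from .evaluate import EvaluationReport

#: Maximum tolerated deviation of any sampling interval from 1/rate, seconds.
TIME_TOLERANCE_S = 1e-6

RECORDING_COLUMNS = ("time_s", "ch_slash", "ch_backslash")


@dataclass
class Recording:
    """A two-channel impedance time series at a fixed sampling rate.

    Parameters
    ----------
    sampling_rate : float
        Samples per second (the hardware streams at 1 kHz).
    time : ndarray
        Sample times in seconds, strictly increasing and uniform.
    ch_slash, ch_backslash : ndarray
        Impedance of the "/" and "\\" threads, arbitrary units.
    labels : ndarray of object, optional
        Per-sample :class:`Orientation` (or None where unlabeled).
    """

    sampling_rate: float
    time: np.ndarray
    ch_slash: np.ndarray
    ch_backslash: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.ch_slash = np.asarray(self.ch_slash, dtype=float)
        self.ch_backslash = np.asarray(self.ch_backslash, dtype=float)
        n = self.time.size
        if self.ch_slash.size != n or self.ch_backslash.size != n:
            raise FormatError(
                f"channel lengths ({self.ch_slash.size}, {self.ch_backslash.size}) "
                f"do not match time axis length {n}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if self.labels.size != n:
                raise FormatError(
                    f"label column length {self.labels.size} does not match time axis length {n}"
                )
        if n > 1:
            dt = np.diff(self.time)
            expected = 1.0 / self.sampling_rate
            if np.any(dt <= 0):
                raise FormatError("time axis is not strictly increasing")
            if np.max(np.abs(dt - expected)) > TIME_TOLERANCE_S:
                raise FormatError(
                    f"non-uniform sampling: interval deviates from {expected:g} s "
                    f"by more than {TIME_TOLERANCE_S:g} s"
                )

    def __len__(self) -> int:
        return int(self.time.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate

    def channel(self, name: str) -> np.ndarray:
        if name == "slash":
            return self.ch_slash
        if name == "backslash":
            return self.ch_backslash
        raise KeyError(f"unknown channel {name!r}; expected 'slash' or 'backslash'")


def read_recording(path: str | Path, sampling_rate: float | None = None) -> Recording:
    """Read a recording CSV, validating schema and time-axis uniformity.

    The sampling rate is inferred from the median time step unless given.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: recording contains no samples")
    time = df["time_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        if len(df) < 2:
            raise FormatError(f"{path}: cannot infer sampling rate from a single sample")
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    labels = None
    if "label" in df.columns:
        raw = df["label"].astype(object)
        labels = np.array(
            [None if (pd.isna(v) or v == "") else Orientation(v) for v in raw],
            dtype=object,
        )
    return Recording(
        sampling_rate=sampling_rate,
        time=time,
        ch_slash=df["ch_slash"].to_numpy(dtype=float),
        ch_backslash=df["ch_backslash"].to_numpy(dtype=float),
        labels=labels,
    )


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording to CSV (label column always present, empty when unlabeled)."""
    if recording.labels is None:
        label_col = [""] * len(recording)
    else:
        label_col = ["" if lab is None else str(lab) for lab in recording.labels]
    df = pd.DataFrame(
        {
            "time_s": recording.time,
            "ch_slash": recording.ch_slash,
            "ch_backslash": recording.ch_backslash,
            "label": label_col,
        }
    )
    df.to_csv(path, index=False)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-segment feature table (see :mod:`threadmotion.features`) to CSV."""
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    from .features import FEATURE_NAMES  # local import: features imports nothing from io

    df = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing feature column(s): {', '.join(missing)}")
    return df


def write_report(report: "EvaluationReport", path: str | Path) -> None:
    """Serialize an evaluation report to JSON.

    The document carries, per classifier, the averaged test accuracy, the
    per-repetition accuracies, and the pooled confusion matrix with named
    rows/columns, plus the evaluation protocol (reps, train fraction, seed).
    """
    from .evaluate import EvaluationReport  # noqa: F401  (type check only)

    if report.reps == 0 or not report.accuracies:
        raise ValueError("cannot serialize an empty report (zero repetitions)")
    doc = report.to_dict()
    Path(path).write_text(json.dumps(doc, indent=2), encoding="utf-8")


def read_report(path: str | Path) -> "EvaluationReport":
    from .evaluate import EvaluationReport

    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    return EvaluationReport.from_dict(doc)
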