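"""End-to-end convenience: raw recording -> per-segment feature table."""

from __future__ import annotations

import pandas as pd

from .calibration import CalibrationProfile
from .features import feature_table
from .io import Recording
from .preprocessing import PipelineConfig, preprocess_recording, segment_stream


def extract_feature_table(
    recording: Recording,
    profile: CalibrationProfile,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Filter, normalize, segment and featurize a raw recording.

    Returns the per-segment feature table (six predictors plus traceability
    and label columns) ready for training or streaming prediction.
    """
    config = config or PipelineConfig(sampling_rate=recording.sampling_rate)
    processed = preprocess_recording(recording, profile, config)
    return feature_table(segment_stream(processed, config))
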