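"""Shared fixtures: one full synthetic replication of the experiment protocol.

The replication is expensive relative to unit tests (calibration recording,
120 s motion recording, 400 segments, and a 100-round evaluation of all nine
classifiers), so it is built once per session and shared.
"""

from types import SimpleNamespace

import pytest

from threadmotion import (
    GeneratorConfig,
    MotionScript,
    calibrate,
    extract_feature_table,
    generate_calibration_recording,
    generate_recording,
    repeated_holdout,
)
from threadmotion.features import feature_matrix

REPLICATION_SEED = 11


@pytest.fixture(scope="session")
def replication():
    """Calibration + the 5-horizontal/5-vertical protocol, fully featurized."""
    config = GeneratorConfig(seed=REPLICATION_SEED)
    profile = calibrate(generate_calibration_recording(config))
    recording = generate_recording(MotionScript.setup_protocol(), config=config)
    table = extract_feature_table(recording, profile)
    X, y = feature_matrix(table)
    return SimpleNamespace(
        config=config, profile=profile, recording=recording, table=table, X=X, y=y
    )


@pytest.fixture(scope="session")
def replication_report(replication):
    """100 rounds of random 75/25 splitting over all nine classifiers."""
    return repeated_holdout(
        replication.X,
        replication.y,
        reps=100,
        train_frac=0.75,
        seed=REPLICATION_SEED + 1,
    )
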