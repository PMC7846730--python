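"""Generator contracts: determinism, level structure, labeling, script validation."""

import numpy as np
import pytest

from threadmotion import (
    GeneratorConfig,
    MotionScript,
    Orientation,
    ScriptStep,
    default_orientation_profiles,
    generate_calibration_recording,
    generate_recording,
)
from threadmotion.errors import ScriptError
from threadmotion.orientations import INTERMEDIATE, VERTICAL_AXIS
from threadmotion.synthetic import level_to_raw

#: Per-orientation segment-mean intervals reported for the real sensor.
STATED_LEVEL_RANGES = {
    "slash": {
        Orientation.RIGHT: (-1.0, -0.8),
        Orientation.FRONT_RIGHT: (-0.8, -0.2),
        Orientation.FRONT: (-0.2, 0.2),
        Orientation.FRONT_LEFT: (0.2, 0.6),
        Orientation.LEFT: (0.4, 1.0),
    },
    "backslash": {
        Orientation.RIGHT: (0.3, 1.0),
        Orientation.FRONT_RIGHT: (-0.2, 0.2),
        Orientation.FRONT: (-0.2, 0.2),
        Orientation.FRONT_LEFT: (-0.8, -0.4),
        Orientation.LEFT: (-1.0, -0.8),
    },
}


class TestOrientationProfiles:
    def test_front_is_zero_on_both_channels(self):
        front = default_orientation_profiles()[Orientation.FRONT]
        assert front.level_slash == 0.0 and front.level_backslash == 0.0

    def test_horizontal_levels_inside_stated_ranges(self):
        profiles = default_orientation_profiles()
        for channel, ranges in STATED_LEVEL_RANGES.items():
            for orientation, (lo, hi) in ranges.items():
                level = getattr(profiles[orientation], f"level_{channel}")
                assert lo <= level <= hi, (channel, orientation, level)

    def test_vertical_levels_monotone_down_to_up_on_both_channels(self):
        profiles = default_orientation_profiles()
        for channel in ("slash", "backslash"):
            levels = [getattr(profiles[o], f"level_{channel}") for o in VERTICAL_AXIS]
            assert np.all(np.diff(levels) > 0)

    def test_down_is_most_negative_and_equal_trend_on_both_channels(self):
        down = default_orientation_profiles()[Orientation.DOWN]
        assert down.level_slash < 0 and down.level_backslash < 0

    def test_intermediate_flag(self):
        profiles = default_orientation_profiles()
        assert {o for o, p in profiles.items() if p.is_intermediate} == set(INTERMEDIATE)


def _script(*targets, dwell=0.5, transition=0.4):
    steps = [ScriptStep(Orientation.FRONT, dwell, 0.0)]
    steps += [ScriptStep(t, dwell, transition) for t in targets]
    return MotionScript(steps)


class TestMotionScript:
    def test_empty_script_rejected(self):
        with pytest.raises(ScriptError, match="empty"):
            MotionScript([])

    def test_must_start_from_front(self):
        with pytest.raises(ScriptError, match="front"):
            MotionScript([ScriptStep(Orientation.LEFT, 1.0, 0.0)])

    def test_non_adjacent_jump_names_offending_step(self):
        with pytest.raises(ScriptError, match="step 2"):
            _script(Orientation.LEFT, Orientation.UP)

    def test_opposite_extremes_need_a_front_return(self):
        with pytest.raises(ScriptError):
            _script(Orientation.LEFT, Orientation.RIGHT)

    def test_setup_protocol_duration_yields_400_windows(self):
        script = MotionScript.setup_protocol()
        n = round(script.duration_s * 1000)
        assert n == 120_250
        assert (n - 550) // 300 + 1 == 400


class TestGenerateRecording:
    def test_same_seed_same_recording(self):
        script = _script(Orientation.LEFT, Orientation.FRONT)
        a = generate_recording(script, config=GeneratorConfig(seed=5))
        b = generate_recording(script, config=GeneratorConfig(seed=5))
        np.testing.assert_array_equal(a.ch_slash, b.ch_slash)
        np.testing.assert_array_equal(a.ch_backslash, b.ch_backslash)
        assert list(a.labels) == list(b.labels)

    def test_different_seed_differs(self):
        script = _script(Orientation.LEFT, Orientation.FRONT)
        a = generate_recording(script, config=GeneratorConfig(seed=5))
        b = generate_recording(script, config=GeneratorConfig(seed=6))
        assert not np.array_equal(a.ch_slash, b.ch_slash)

    def test_front_only_noiseless_recording_is_flat_baseline(self):
        config = GeneratorConfig.noiseless()
        rec = generate_recording(
            MotionScript([ScriptStep(Orientation.FRONT, 1.0, 0.0)]), config=config
        )
        np.testing.assert_array_equal(rec.ch_slash, config.slash.baseline_raw)
        np.testing.assert_array_equal(rec.ch_backslash, config.backslash.baseline_raw)
        assert all(lab is Orientation.FRONT for lab in rec.labels)

    def test_noiseless_dwell_levels_invert_exactly(self):
        """Raw dwell samples map back to the profile level through normalization."""
        from threadmotion.preprocessing import normalize
        from threadmotion.synthetic import calibration_truth

        config = GeneratorConfig.noiseless()
        profiles = default_orientation_profiles()
        script = _script(Orientation.LEFT, Orientation.FRONT, Orientation.RIGHT)
        rec = generate_recording(script, profiles, config)
        truth = calibration_truth(config)
        normalized = normalize(rec.ch_slash, truth.slash)
        # locate each dwell from the script arithmetic (transitions carry ramps)
        pos, dwells = 0, {}
        for i, step in enumerate(script.steps):
            if i:
                pos += round(step.transition_s * rec.sampling_rate)
            start = pos
            pos += round(step.dwell_s * rec.sampling_rate)
            dwells[step.target] = (start, pos)
        for target in (Orientation.LEFT, Orientation.RIGHT):
            start, end = dwells[target]
            np.testing.assert_allclose(
                normalized[start:end], profiles[target].level_slash, atol=1e-9
            )

    def test_intermediate_band_labels_transitions(self):
        config = GeneratorConfig.noiseless()
        rec = generate_recording(_script(Orientation.RIGHT), config=config)
        labels = list(rec.labels)
        assert Orientation.FRONT_RIGHT in labels
        frac = labels.count(Orientation.FRONT_RIGHT) / round(0.4 * 1000)
        assert frac == pytest.approx(config.intermediate_band, abs=0.02)

    def test_horizontal_channels_anticorrelated_vertical_correlated(self):
        config = GeneratorConfig.noiseless()
        horizontal = generate_recording(
            _script(Orientation.LEFT, Orientation.FRONT, Orientation.RIGHT,
                    Orientation.FRONT, dwell=1.0),
            config=config,
        )
        vertical = generate_recording(
            _script(Orientation.DOWN, Orientation.FRONT, Orientation.UP,
                    Orientation.FRONT, dwell=1.0),
            config=config,
        )
        assert np.corrcoef(horizontal.ch_slash, horizontal.ch_backslash)[0, 1] <= 0
        assert np.corrcoef(vertical.ch_slash, vertical.ch_backslash)[0, 1] >= 0


class TestCalibrationRecording:
    def test_noiseless_extremes_hit_span_exactly(self):
        config = GeneratorConfig.noiseless()
        rec = generate_calibration_recording(config)
        assert rec.ch_slash.max() == config.slash.baseline_raw + config.slash.span_pos
        assert rec.ch_slash.min() == config.slash.baseline_raw - config.slash.span_neg

    def test_determinism(self):
        a = generate_calibration_recording(GeneratorConfig(seed=9))
        b = generate_calibration_recording(GeneratorConfig(seed=9))
        np.testing.assert_array_equal(a.ch_backslash, b.ch_backslash)


def test_level_to_raw_uses_asymmetric_spans():
    from threadmotion.synthetic import ChannelParams

    ch = ChannelParams(baseline_raw=100.0, span_pos=40.0, span_neg=20.0)
    np.testing.assert_allclose(
        level_to_raw(np.array([-1.0, -0.5, 0.0, 0.5, 1.0]), ch),
        [80.0, 90.0, 100.0, 120.0, 140.0],
    )
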