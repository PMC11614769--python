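"""Container invariants: trial slicing, selections, save/load, arithmetic."""

import json
import os

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ephystream as es
from ephystream.datamodel import validate_trialdefinition
from ephystream.errors import (
    BoundsError,
    FormatError,
    IncompatibilityError,
    SelectionError,
    StateError,
    ValidationError,
    VersionError,
)


def _analog(arr, fs=1000.0, trl=None):
    return es.AnalogData.from_array(np.asarray(arr, dtype=np.float32), fs,
                                    trialdefinition=trl)


class TestTrialDefinition:
    def test_partition_into_trials(self):
        payload = np.arange(2000, dtype=np.float32).reshape(1000, 2)
        d = _analog(payload, trl=[[0, 500, -100], [500, 1000, -100]])
        assert d.n_trials == 2
        assert d.trial_shape(0) == (500, 2)
        np.testing.assert_array_equal(d.trial(0), payload[:500])
        np.testing.assert_array_equal(d.trial(1), payload[500:])

    def test_out_of_bounds_row_rejected(self):
        payload = np.zeros((1000, 1), np.float32)
        with pytest.raises(BoundsError, match="row 0"):
            _analog(payload, trl=[[0, 1200, 0]])

    def test_start_at_or_after_stop_rejected(self):
        with pytest.raises(ValidationError, match="start"):
            validate_trialdefinition([[10, 10, 0]], 100)

    def test_overlapping_trials_both_accessible(self):
        payload = np.arange(600, dtype=np.float32).reshape(600, 1)
        d = _analog(payload, trl=[[0, 400, 0], [200, 600, 0]])
        np.testing.assert_array_equal(d.trial(0), payload[0:400])
        np.testing.assert_array_equal(d.trial(1), payload[200:600])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        lengths=st.lists(st.integers(min_value=1, max_value=40), min_size=1,
                         max_size=8)
    )
    def test_partitioning_trials_concatenate_to_payload(self, lengths):
        """Half-open slicing: concatenating a partition reproduces the payload."""
        total = sum(lengths)
        payload = np.arange(total, dtype=np.float32).reshape(total, 1)
        edges = np.cumsum([0] + lengths)
        trl = [[int(a), int(b), 0] for a, b in zip(edges[:-1], edges[1:])]
        d = _analog(payload, trl=trl)
        recon = np.vstack([d.trial(i) for i in range(d.n_trials)])
        np.testing.assert_array_equal(recon, payload)


class TestTimeAxis:
    def test_offset_places_t0(self):
        d = _analog(np.zeros((100, 1), np.float32), trl=[[0, 100, -50]])
        t = d.time(0)
        assert t[0] == pytest.approx(-0.050)
        assert t[-1] == pytest.approx(0.049)
        assert np.allclose(np.diff(t), 0.001)

    def test_unit_samplerate(self):
        d = _analog(np.zeros((3, 1), np.float32), fs=1.0, trl=[[0, 3, 0]])
        np.testing.assert_allclose(d.time(0), [0.0, 1.0, 2.0])

    def test_positive_offset(self):
        d = _analog(np.zeros((300, 1), np.float32), fs=500.0, trl=[[100, 200, 25]])
        t = d.time(0)
        assert len(t) == 100
        assert t[0] == pytest.approx(0.05)

    def test_missing_trialdefinition_is_state_error(self):
        d = es.AnalogData.from_array(np.zeros((10, 1), np.float32), 1000.0)
        d._trialdefinition = None
        with pytest.raises(StateError):
            d.time(0)


class TestSelection:
    def test_select_all_copies_payload(self, small_noise):
        out = es.apply_selection(small_noise, es.Selection())
        np.testing.assert_array_equal(out.data[...], small_noise.data[...])
        assert out.channels == small_noise.channels

    def test_latency_window_realigns_offsets(self):
        payload = np.arange(150, dtype=np.float32).reshape(150, 1)
        d = _analog(payload, trl=[[0, 150, -50]])
        out = es.apply_selection(d, es.Selection(latency=[0, 0.1]))
        assert out.trial_shape(0) == (100, 1)
        assert out.trialdefinition[0, 2] == 0
        np.testing.assert_array_equal(out.trial(0)[:, 0], payload[50:150, 0])

    def test_missing_channel_label_is_selection_error(self, small_noise):
        with pytest.raises(SelectionError, match="ch7"):
            es.apply_selection(small_noise, es.Selection(channels=["ch7"]))

    def test_selection_idempotent(self, small_noise):
        sel = es.Selection(latency=[0.0, 0.2], channels=["channel1", "channel2"])
        once = es.apply_selection(small_noise, sel)
        twice = es.apply_selection(once, es.Selection())
        np.testing.assert_array_equal(once.data[...], twice.data[...])
        np.testing.assert_array_equal(once.trialdefinition, twice.trialdefinition)

    def test_empty_latency_names_criterion(self, small_noise):
        with pytest.raises(SelectionError, match="latency"):
            es.apply_selection(small_noise, es.Selection(latency=[5.0, 6.0]))


class TestSaveLoad:
    def test_roundtrip_preserves_payload_and_header(self, small_noise, tmp_path):
        base = str(tmp_path / "ds")
        header = es.save_dataset(small_noise, base)
        back = es.load_dataset(base)
        np.testing.assert_array_equal(back.data[...], small_noise.data[...])
        np.testing.assert_array_equal(back.trialdefinition,
                                      small_noise.trialdefinition)
        assert back.channels == small_noise.channels
        assert back.samplerate == small_noise.samplerate
        assert header["format_version"] == "1.0"

    def test_save_load_save_payload_byte_stable(self, small_noise, tmp_path):
        a = str(tmp_path / "a")
        b = str(tmp_path / "b")
        es.save_dataset(small_noise, a)
        mid = es.load_dataset(a)
        es.save_dataset(mid, b)
        mid.close()
        import h5py

        with h5py.File(a + ".h5", "r") as fa, h5py.File(b + ".h5", "r") as fb:
            assert np.array_equal(fa["data"][...], fb["data"][...])
            assert fa["data"].dtype == fb["data"].dtype

    def test_truncated_payload_is_format_error(self, small_noise, tmp_path):
        base = str(tmp_path / "ds")
        es.save_dataset(small_noise, base)
        import h5py

        with h5py.File(base + ".h5", "r+") as f:
            trunc = f["data"][:100]
            del f["data"]
            f.create_dataset("data", data=trunc)
        with pytest.raises(FormatError, match="shape"):
            es.load_dataset(base)

    def test_unknown_version_rejected(self, small_noise, tmp_path):
        base = str(tmp_path / "ds")
        es.save_dataset(small_noise, base)
        with open(base + ".json") as fh:
            header = json.load(fh)
        header["format_version"] = "9.9"
        with open(base + ".json", "w") as fh:
            json.dump(header, fh)
        with pytest.raises(VersionError):
            es.load_dataset(base)

    def test_spectral_roundtrip_preserves_freqs(self, small_noise, tmp_path):
        spec = es.spectral.mtmfft(small_noise, taper="hann")
        base = str(tmp_path / "spec")
        es.save_dataset(spec, base)
        back = es.load_dataset(base)
        np.testing.assert_array_equal(back.freqs, spec.freqs)
        np.testing.assert_array_equal(back.data[...], spec.data[...])


class TestArithmetic:
    def test_self_subtraction_is_zero(self, small_noise):
        z = small_noise - small_noise
        assert not np.any(z.data[...])

    def test_scalar_multiplication(self, small_noise):
        m = small_noise * 2
        np.testing.assert_array_equal(m.data[...],
                                      np.asarray(small_noise.data[...]) * 2)

    def test_power_ratio_recovers_known_factor(self, small_noise):
        stim = es.spectral.mtmfft(small_noise, taper="hann")
        quadrupled = small_noise * 2  # power scales with amplitude squared
        stim4 = es.spectral.mtmfft(quadrupled, taper="hann")
        with pytest.warns(RuntimeWarning):
            ratio = stim4 / stim
        vals = np.asarray(ratio.data[...])
        np.testing.assert_allclose(vals[np.isfinite(vals)], 4.0, rtol=1e-4)

    def test_matches_in_memory_oracle_exactly(self, small_noise):
        other = small_noise * 1  # content-identical copy
        for op, np_op in [("+", np.add), ("-", np.subtract), ("*", np.multiply)]:
            out = es.dataset_arithmetic(small_noise, other, op)
            oracle = np_op(np.asarray(small_noise.data[...]),
                           np.asarray(other.data[...]))
            np.testing.assert_array_equal(out.data[...], oracle)

    def test_shape_mismatch_rejected(self, small_noise):
        other = es.AnalogData.from_array(np.zeros((10, 3), np.float32), 1000.0)
        with pytest.raises(IncompatibilityError):
            small_noise + other

    def test_log_records_operation(self, small_noise):
        out = small_noise * 3
        assert any("arithmetic" in e["operation"] for e in out.log)


class TestTrialSource:
    def test_generator_streams_trials(self):
        def gen():
            for i in range(3):
                yield np.full((100, 4), i, np.float32)

        d = es.from_trial_source(gen(), 1000.0)
        assert d.shape == (300, 4)
        assert d.n_trials == 3
        np.testing.assert_array_equal(d.trial(2), np.full((100, 4), 2))

    def test_channel_count_mismatch_names_trial(self):
        def gen():
            yield np.zeros((50, 4), np.float32)
            yield np.zeros((50, 5), np.float32)

        with pytest.raises(ValidationError, match="trial 1"):
            es.from_trial_source(gen(), 1000.0)

    def test_timelock_requires_equal_trials(self):
        d = es.from_trial_source(
            [np.zeros((50, 2), np.float32), np.zeros((60, 2), np.float32)], 1000.0
        )
        with pytest.raises(ValidationError, match="time-locked"):
            d.as_timelock()

    def test_timelock_average_matches_oracle(self):
        trials = [np.full((40, 2), float(i), np.float32) for i in range(4)]
        tl = es.from_trial_source(trials, 1000.0).as_timelock()
        np.testing.assert_allclose(tl.avg(), np.full((40, 2), 1.5))
        np.testing.assert_allclose(
            tl.var(), np.var(np.stack(trials), axis=0, ddof=1), rtol=1e-6
        )
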