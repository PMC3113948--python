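"""Synthetic generator: determinism, protocol structure, signal statistics."""

import numpy as np
import pytest
from scipy import signal as sps

from emgdyn import ProtocolSpec, generate_dataset, generate_session, make_subject
from emgdyn.protocol import InvalidProtocolError
from emgdyn.synthetic import contraction_envelope


class TestMakeSubject:
    def test_deterministic_given_seed(self, protocol):
        a, b = make_subject(protocol, 5), make_subject(protocol, 5)
        np.testing.assert_array_equal(a.activation_matrix, b.activation_matrix)
        np.testing.assert_array_equal(a.activity_level, b.activity_level)
        assert a.snr_db == b.snr_db and a.rng_seed == b.rng_seed

    def test_seed_sensitivity(self, protocol):
        a, b = make_subject(protocol, 1), make_subject(protocol, 2)
        assert not np.array_equal(a.activation_matrix, b.activation_matrix)

    def test_shape_and_silent_rest_row(self, protocol):
        s = make_subject(protocol, 0)
        assert s.activation_matrix.shape == (9, 6)
        np.testing.assert_array_equal(s.activation_matrix[-1], 0.0)
        np.testing.assert_array_equal(s.dynamic_activation_matrix[-1], 0.0)

    def test_rows_pairwise_distinct(self, protocol):
        act = make_subject(protocol, 11).activation_matrix[:-1]
        for i in range(len(act)):
            for j in range(i + 1, len(act)):
                assert np.abs(act[i] - act[j]).max() > 0.0

    def test_activity_levels_within_range(self, protocol):
        s = make_subject(protocol, 4)
        assert np.all(s.activity_level[:-1] >= 0.56)
        assert np.all(s.activity_level[:-1] <= 0.92)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(InvalidProtocolError):
            ProtocolSpec(n_classes=1)
        with pytest.raises(InvalidProtocolError):
            ProtocolSpec(n_channels=0)


class TestGenerateSession:
    def test_contraction_count_and_class_balance(self, session, protocol):
        contractions = session.contractions()
        assert len(contractions) == 18
        ids = [c.class_id for c in contractions]
        for class_id in range(1, 10):
            assert ids.count(class_id) == 2

    def test_54_contractions_per_subject(self, subject, protocol):
        total = sum(
            len(generate_session(subject, protocol, k).contractions())
            for k in range(1, 4)
        )
        assert total == 54

    def test_annotations_cover_signal_exactly(self, session):
        session.validate()
        assert sum(a.n_samples for a in session.annotations) == session.n_samples

    def test_signal_zero_mean_per_channel(self, session):
        rms = np.sqrt(np.mean(session.signal**2, axis=1))
        assert np.abs(session.signal.mean(axis=1)).max() < 1e-10 * rms.max()

    def test_rest_psd_concentrated_in_band(self, subject, protocol):
        session = generate_session(subject, protocol, 1)
        rest = session.annotations[0]
        assert rest.phase == "rest"
        x = session.signal[0, rest.start : rest.stop]
        f, p = sps.welch(x, fs=protocol.fs, nperseg=1024)
        in_band = p[(f >= 47) & (f <= 440)].sum() / p.sum()
        assert in_band >= 0.90

    def test_envelope_endpoints_and_hold_plateau(self):
        env = contraction_envelope(100, 50)
        assert env[0] == 0.0
        assert np.all(env[100:150] == 1.0)
        assert env[-1] < 0.05

    def test_ramp_amplitude_rises_along_the_ramp(self, protocol):
        # mean rectified amplitude over the second ramp half always
        # exceeds the first half (jitter disabled)
        subject = make_subject(protocol, 21)
        for k in range(1, 4):
            s = generate_session(subject, protocol, k, envelope_jitter=0.0)
            for c in s.contractions():
                if c.class_id == protocol.rest_class:
                    continue
                ramp = np.abs(s.signal[:, c.start : c.hold_start]).mean(axis=0)
                first, second = np.array_split(ramp, 2)
                assert second.mean() > first.mean()

    def test_session_index_validated(self, subject, protocol):
        with pytest.raises(ValueError):
            generate_session(subject, protocol, 0)


class TestGenerateDataset:
    def test_session_counts(self, small_protocol):
        data = generate_dataset(small_protocol, n_subjects=2, master_seed=0)
        assert len(data) == 2
        assert all(len(sessions) == 3 for _, sessions in data)

    def test_byte_identical_across_runs(self, small_protocol):
        a = generate_dataset(small_protocol, 1, master_seed=99)
        b = generate_dataset(small_protocol, 1, master_seed=99)
        np.testing.assert_array_equal(a[0][1][0].signal, b[0][1][0].signal)
        np.testing.assert_array_equal(a[0][1][2].signal, b[0][1][2].signal)

    def test_sessions_share_subject_model(self, small_protocol):
        (subject, sessions), = generate_dataset(small_protocol, 1, master_seed=5)
        # same subject, different realizations
        assert sessions[0].n_samples == sessions[1].n_samples
        assert not np.array_equal(sessions[0].signal, sessions[1].signal)


def test_nearest_centroid_sanity_oracle():
    """With orthogonal activation rows and high SNR, per-channel RMS of
    hold windows separates the classes perfectly (nearest centroid)."""
    p = ProtocolSpec(n_classes=4, n_channels=3, fs=512, reps_per_session=2,
                     n_sessions=2, ramp_s=1.0, hold_s=1.5,
                     inter_contraction_rest_s=1.0)
    act = np.zeros((4, 3))
    act[:3] = np.eye(3)
    subject = make_subject(p, 1, snr_db_range=(30.0, 30.0), activation_matrix=act)
    from emgdyn import WindowSpec, segment

    def hold_rms(session):
        series = segment(session, WindowSpec(fs=512))
        m = (series.phase_labels == "hold") & (series.class_labels != p.rest_class)
        rms = np.sqrt(np.mean(series.data[m] ** 2, axis=2))
        return rms, series.class_labels[m]

    Xtr, ytr = hold_rms(generate_session(subject, p, 1))
    Xte, yte = hold_rms(generate_session(subject, p, 2))
    centroids = np.stack([Xtr[ytr == c].mean(axis=0) for c in (1, 2, 3)])
    pred = np.argmin(
        np.linalg.norm(Xte[:, None, :] - centroids[None], axis=2), axis=1
    ) + 1
    assert np.mean(pred != yte) == 0.0
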