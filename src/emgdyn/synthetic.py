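"""Protocol-faithful synthetic surface-EMG generator.

The generator emulates the recording protocol of :mod:`emgdyn.protocol`
with an amplitude-modulated, band-limited Gaussian carrier:

* each channel carries Gaussian noise band-passed to 47-440 Hz (the
  hardware analog filter band of typical bipolar sEMG amplifiers),
  zero-phase 4th-order Butterworth, normalized to unit RMS;
* class identity is encoded as a per-class, per-channel activation
  pattern (a direction in channel-amplitude space), scaled by a per-class
  peak activity level drawn from 56-92% of full scale and a per-subject
  signal-to-rest-noise ratio;
* each class additionally has a distinct movement-phase pattern: during
  the ramps the channel pattern blends from the movement pattern into the
  posture-hold pattern, reflecting that anisotonic (moving) and isometric
  (holding) contractions recruit different muscle coordinations — this is
  what makes the dynamic portions carry class information of their own;
* the contraction envelope rises from rest to peak over the ramp
  (raised-cosine by default, linear optionally), stays at peak during the
  hold, and returns to rest symmetrically;
* a slow multiplicative jitter on the envelope emulates imperfect force
  tracking and gives within-class feature variance.

This is deliberately not a physiological motor-unit simulator: the
downstream methods depend only on amplitude and spectral statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .protocol import (
    Annotation,
    InvalidProtocolError,
    ProtocolSpec,
    RecordingSession,
)

#: Hardware band of the emulated acquisition chain, Hz.
BAND_HZ = (47.0, 440.0)


@dataclass
class SubjectModel:
    """Per-subject generative parameters.

    activation_matrix : (n_classes, n_channels) relative amplitudes in [0, 1];
        the rest-class row is all zeros and every active row peaks at 1 on
        its strongest channel.  Rows are pairwise distinct.
    dynamic_activation_matrix : same layout; the channel pattern expressed
        while the limb is moving (ramp phases).  The instantaneous pattern
        blends from this toward ``activation_matrix`` as the target
        posture is approached.
    snr_db : peak-signal-to-rest-noise ratio on the strongest channel, dB.
    activity_level : per-class peak normalized activity in [0.56, 0.92]
        (0 for the rest class).
    rng_seed : seed all of the subject's sessions derive from.
    """

    activation_matrix: np.ndarray
    snr_db: float
    activity_level: np.ndarray
    rng_seed: int
    dynamic_activation_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dynamic_activation_matrix is None:
            self.dynamic_activation_matrix = self.activation_matrix

    @property
    def n_classes(self) -> int:
        return int(self.activation_matrix.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.activation_matrix.shape[1])


def make_subject(
    protocol: ProtocolSpec,
    seed: int,
    snr_db_range: tuple[float, float] = (20.0, 30.0),
    activity_range: tuple[float, float] = (0.56, 0.92),
    activation_matrix: np.ndarray | None = None,
    movement_synergy_mix: float = 0.5,
    classes_per_direction: int = 1,
) -> SubjectModel:
    """Draw a deterministic subject model from ``seed``.

    ``activation_matrix`` may be supplied to construct subjects with a
    prescribed channel geometry (e.g. orthogonal rows for separability
    oracles); it is validated and the rest row forced to zero (the
    movement-phase patterns then equal the hold patterns, giving fully
    stationary class statistics).

    ``movement_synergy_mix`` blends a class-unspecific movement synergy
    (forearm stabilizers co-contracting at motion onset, common to all
    classes) into each class's movement-phase pattern: 0 makes the
    dynamic portions as class-specific as the holds, 1 makes movement
    onset look identical for every class.
    """
    if protocol.n_classes < 2 or protocol.n_channels < 1:
        raise InvalidProtocolError("invalid protocol for subject generation")
    rng = np.random.default_rng(seed)
    snr_db = float(rng.uniform(*snr_db_range))
    activity = np.zeros(protocol.n_classes)
    activity[:-1] = rng.uniform(*activity_range, size=protocol.n_classes - 1)

    if activation_matrix is None:
        act = _draw_activation(
            rng, protocol.n_classes, protocol.n_channels, classes_per_direction
        )
        dyn = _draw_activation(rng, protocol.n_classes, protocol.n_channels)
        synergy = rng.standard_normal(protocol.n_channels) ** 2
        synergy /= synergy.max()
        dyn = movement_synergy_mix * synergy + (1.0 - movement_synergy_mix) * dyn
        dyn /= dyn.max(axis=1, keepdims=True)
    else:
        act = np.asarray(activation_matrix, dtype=float).copy()
        if act.shape != (protocol.n_classes, protocol.n_channels):
            raise ValueError("activation_matrix shape mismatch with protocol")
        dyn = act.copy()
    act[-1, :] = 0.0
    dyn[-1, :] = 0.0
    _check_rows_distinct(act[:-1])
    return SubjectModel(
        activation_matrix=act,
        snr_db=snr_db,
        activity_level=activity,
        rng_seed=int(rng.integers(0, 2**31 - 1)),
        dynamic_activation_matrix=dyn,
    )


def _draw_activation(
    rng: np.random.Generator,
    n_classes: int,
    n_channels: int,
    classes_per_direction: int = 1,
    direction_spread: float = 0.15,
) -> np.ndarray:
    """Random, pairwise-distinct activation rows normalized to max 1.

    With ``classes_per_direction > 1``, groups of classes share a base
    channel direction perturbed by ``direction_spread`` — emulating the
    near-collinear patterns that related motions produce on a small
    electrode montage, where classes are told apart as much by activation
    level as by pattern shape.
    """
    act = np.zeros((n_classes, n_channels))
    base = None
    for c in range(n_classes - 1):
        for _ in range(100):
            if c % classes_per_direction == 0 or base is None:
                base = rng.standard_normal(n_channels) ** 2
                row = base.copy()
            else:
                row = base + direction_spread * rng.standard_normal(n_channels) ** 2
            row /= row.max()
            if all(np.abs(act[j] - row).max() > 0.05 for j in range(c)):
                act[c] = row
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not draw distinct activation rows")
    return act


def _check_rows_distinct(rows: np.ndarray) -> None:
    n = rows.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if np.allclose(rows[i], rows[j]):
                raise ValueError(f"activation rows {i} and {j} are identical")


def band_limited_noise(
    rng: np.random.Generator, n_channels: int, n_samples: int, fs: int
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to 47-440 Hz, zero-phase.

    At sampling rates where 440 Hz is not representable the upper edge is
    clipped to 90% of Nyquist.
    """
    white = rng.standard_normal((n_channels, n_samples))
    band = (BAND_HZ[0], min(BAND_HZ[1], 0.45 * fs))
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / rms


def contraction_envelope(
    ramp_n: int, hold_n: int, shape: str = "raised_cosine"
) -> np.ndarray:
    """Normalized 0->1->0 envelope of one contraction, sample domain."""
    t = np.arange(ramp_n) / ramp_n
    if shape == "raised_cosine":
        up = 0.5 * (1.0 - np.cos(np.pi * t))
    elif shape == "linear":
        up = t
    else:
        raise ValueError(f"unknown envelope shape {shape!r}")
    return np.concatenate([up, np.ones(hold_n), up[::-1]])


def generate_session(
    subject: SubjectModel,
    protocol: ProtocolSpec,
    session_index: int,
    seed: int | None = None,
    envelope_shape: str = "raised_cosine",
    envelope_jitter: float = 0.25,
    ramp_exponent: float = 0.35,
) -> RecordingSession:
    """Generate one recording session for ``subject``.

    The session holds ``reps_per_session`` contractions of every class
    (including contraction-shaped rest-class segments) in a seed-determined
    random order, separated — and book-ended — by rest gaps.

    ``ramp_exponent`` maps the kinematic ramp profile to EMG amplitude:
    values below 1 make the EMG envelope lead the movement, reflecting
    that muscle activity during an unloaded reach rises well before the
    target posture is approached.  ``envelope_jitter`` is the coefficient
    of variation of a slow multiplicative amplitude modulation emulating
    force-tracking variability (subjects received no feedback to regulate
    the contraction level).
    """
    if not 1 <= session_index <= protocol.n_sessions:
        raise ValueError("session_index out of range")
    if seed is None:
        ss = np.random.SeedSequence([subject.rng_seed, session_index])
    else:
        ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    fs = protocol.fs
    ramp_n = round(protocol.ramp_s * fs)
    hold_n = round(protocol.hold_s * fs)
    rest_n = round(protocol.inter_contraction_rest_s * fs)
    contr_n = 2 * ramp_n + hold_n
    n_contr = protocol.contractions_per_session
    n_samples = n_contr * contr_n + (n_contr + 1) * rest_n

    order = np.repeat(np.arange(1, protocol.n_classes + 1), protocol.reps_per_session)
    order = rng.permutation(order)

    gain = 10.0 ** (subject.snr_db / 20.0)
    kin = contraction_envelope(ramp_n, hold_n, envelope_shape)
    env = kin**ramp_exponent

    # per-channel amplitude profile; rest level is 1.0 per channel
    amp = np.ones((protocol.n_channels, n_samples))
    annotations: list[Annotation] = []
    pos = 0
    annotations.append(Annotation(0, rest_n, protocol.rest_class, "rest"))
    pos = rest_n
    for class_id in order:
        c = int(class_id)
        # channel pattern morphs from the movement coordination into the
        # posture-hold coordination as the target position is approached
        stat = subject.activation_matrix[c - 1][:, None]
        dyn = subject.dynamic_activation_matrix[c - 1][:, None]
        pattern = kin[None, :] * stat + (1.0 - kin)[None, :] * dyn
        e = env
        if envelope_jitter > 0:
            slow = gaussian_filter1d(rng.standard_normal(contr_n), sigma=0.25 * fs)
            sd = slow.std()
            if sd > 0:
                slow = 1.0 + envelope_jitter * slow / sd
                e = env * np.clip(slow, 0.2, None)
        target = gain * subject.activity_level[c - 1] * pattern * e[None, :]
        amp[:, pos : pos + contr_n] += np.maximum(target - 1.0, 0.0)
        annotations.append(Annotation(pos, pos + ramp_n, c, "ramp_up"))
        annotations.append(Annotation(pos + ramp_n, pos + ramp_n + hold_n, c, "hold"))
        annotations.append(Annotation(pos + ramp_n + hold_n, pos + contr_n, c, "ramp_down"))
        pos += contr_n
        annotations.append(Annotation(pos, pos + rest_n, protocol.rest_class, "rest"))
        pos += rest_n

    carrier = band_limited_noise(rng, protocol.n_channels, n_samples, fs)
    sig = carrier * amp
    sig -= sig.mean(axis=1, keepdims=True)
    session = RecordingSession(signal=sig, fs=fs, annotations=annotations)
    session.validate()
    return session


def generate_dataset(
    protocol: ProtocolSpec,
    n_subjects: int,
    master_seed: int,
    **session_kwargs,
) -> list[tuple[SubjectModel, list[RecordingSession]]]:
    """Generate ``n_subjects`` subjects with all their sessions.

    Per-subject seeds derive reproducibly from ``master_seed``; the same
    master seed yields a byte-identical dataset.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    seeds = np.random.SeedSequence(master_seed).generate_state(n_subjects) % (2**31 - 1)
    out = []
    for s in seeds:
        subject = make_subject(protocol, int(s))
        sessions = [
            generate_session(subject, protocol, k, **session_kwargs)
            for k in range(1, protocol.n_sessions + 1)
        ]
        out.append((subject, sessions))
    return out


def iter_dataset(
    protocol: ProtocolSpec, n_subjects: int, master_seed: int, **session_kwargs
):
    """Like :func:`generate_dataset` but yields one subject at a time.

    Keeps only one subject's raw signals in memory — convenient for
    experiment drivers that reduce each session to features immediately.
    """
    seeds = np.random.SeedSequence(master_seed).generate_state(n_subjects) % (2**31 - 1)
    for i, s in enumerate(seeds):
        subject = make_subject(protocol, int(s))
        sessions = [
            generate_session(subject, protocol, k, **session_kwargs)
            for k in range(1, protocol.n_sessions + 1)
        ]
        yield i, subject, sessions
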