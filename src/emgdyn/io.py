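"""Session I/O: EDF signal files with CSV annotation sidecars.

A recording session is written as a standard 16-bit EDF file (one per
session, one EDF signal per channel, one data record per second) plus a
plain-CSV sidecar ``start_sample,end_sample,class_id,phase`` with the
half-open annotation intervals.  The reader accepts the same pair, so
real recordings exported to EDF can replace synthetic sessions.

The EDF header fields are fixed (date, ids) so rewriting the same session
yields a byte-identical file.  Reading goes through ``mne`` and is robust
to EDF files produced by other software; amplitudes are returned in the
file's physical units (microvolt-labelled channels).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .protocol import Annotation, RecordingSession

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def write_edf(session: RecordingSession, path: str | os.PathLike) -> None:
    """Write a session as a 16-bit EDF file (one data record per second).

    The signal length must be a whole number of seconds; amplitudes are
    scaled per channel to the full digital range, so the quantization
    step is ``ptp(signal) / 65535`` per channel.
    """
    sig = np.asarray(session.signal, dtype=float)
    n_ch, n_samp = sig.shape
    fs = int(session.fs)
    if n_samp % fs != 0:
        raise ValueError("signal length must be an integer number of seconds")
    n_rec = n_samp // fs

    phys_max = np.maximum(np.abs(sig).max(axis=1), 1e-9)
    phys_min = -phys_max

    def f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            raise ValueError(f"EDF field too long: {text!r}")
        return b.ljust(width)

    header = b"".join(
        [
            f("0", 8),
            f("X X X X", 80),  # patient id (anonymous)
            f("Startdate 01-JAN-2001 X X X", 80),
            f("01.01.01", 8),
            f("00.00.00", 8),
            f(str(256 * (1 + n_ch)), 8),
            f("", 44),
            f(str(n_rec), 8),
            f("1", 8),  # record duration, s
            f(str(n_ch), 4),
        ]
    )
    labels = [f"EMG ch{c + 1}" for c in range(n_ch)]
    header += b"".join(f(lab, 16) for lab in labels)
    header += b"".join(f("AgAgCl bipolar", 80) for _ in range(n_ch))
    header += b"".join(f("uV", 8) for _ in range(n_ch))
    header += b"".join(f(f"{phys_min[c]:.6g}"[:8], 8) for c in range(n_ch))
    header += b"".join(f(f"{phys_max[c]:.6g}"[:8], 8) for c in range(n_ch))
    header += b"".join(f(str(_EDF_DIG_MIN), 8) for _ in range(n_ch))
    header += b"".join(f(str(_EDF_DIG_MAX), 8) for _ in range(n_ch))
    header += b"".join(f("BP 47-440 Hz", 80) for _ in range(n_ch))
    header += b"".join(f(str(fs), 8) for _ in range(n_ch))
    header += b"".join(f("", 32) for _ in range(n_ch))

    # digitize against the *written* (8-char ascii) physical range so the
    # round trip through any conforming reader is exact up to quantization
    pmin = np.array([float(f"{phys_min[c]:.6g}"[:8]) for c in range(n_ch)])
    pmax = np.array([float(f"{phys_max[c]:.6g}"[:8]) for c in range(n_ch)])
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (pmax - pmin)
    dig = np.round((sig - pmin[:, None]) * scale[:, None] + _EDF_DIG_MIN)
    dig = np.clip(dig, _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        # records: per second, channel-major within the record
        view = dig.reshape(n_ch, n_rec, fs).transpose(1, 0, 2)
        fh.write(np.ascontiguousarray(view).tobytes())


def read_edf(path: str | os.PathLike) -> tuple[np.ndarray, int]:
    """Read an EDF file -> (channels x samples array, sampling rate)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()  # volts for uV-labelled channels
    return data * 1e6, int(round(raw.info["sfreq"]))


def write_annotations(annotations: list[Annotation], path: str | os.PathLike) -> None:
    pd.DataFrame(
        [
            {
                "start_sample": a.start,
                "end_sample": a.stop,
                "class_id": a.class_id,
                "phase": a.phase,
            }
            for a in annotations
        ]
    ).to_csv(path, index=False)


def read_annotations(path: str | os.PathLike) -> list[Annotation]:
    df = pd.read_csv(path)
    return [
        Annotation(int(r.start_sample), int(r.end_sample), int(r.class_id), str(r.phase))
        for r in df.itertuples()
    ]


def session_paths(base: str | os.PathLike) -> tuple[str, str]:
    base = os.fspath(base)
    return base + ".edf", base + "_annotations.csv"


def write_session(session: RecordingSession, base: str | os.PathLike) -> tuple[str, str]:
    """Write ``<base>.edf`` and ``<base>_annotations.csv``."""
    edf, csv = session_paths(base)
    write_edf(session, edf)
    write_annotations(session.annotations, csv)
    return edf, csv


def read_session(base: str | os.PathLike) -> RecordingSession:
    """Read a session written by :func:`write_session` (or compatible)."""
    edf, csv = session_paths(base)
    if not os.path.exists(edf):
        raise FileNotFoundError(f"missing EDF file {edf}")
    if not os.path.exists(csv):
        raise FileNotFoundError(f"missing annotation sidecar {csv}")
    signal, fs = read_edf(edf)
    session = RecordingSession(signal=signal, fs=fs, annotations=read_annotations(csv))
    session.validate()
    return session
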