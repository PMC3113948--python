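"""Recording protocol and in-memory data model for multichannel surface EMG.

The protocol describes a multi-session gesture-recording experiment for
myoelectric prosthesis control: in each session a subject performs every
motion class a fixed number of times, in random order.  Each contraction
lasts ``2*ramp_s + hold_s`` seconds — the subject moves from rest to the
target posture (ramp up), holds it (the static portion), and returns to
rest (ramp down) — with a rest period between consecutive contractions.
The last class index is the rest / "no motion" class and is realized as a
contraction-shaped segment of rest-level signal.

Class identifiers are 1-based; class ``n_classes`` is rest.  All sample
intervals are half-open ``[start, stop)`` and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Phase labels a sample can carry.  ``rest`` is the inter-contraction gap;
#: the three others partition every contraction (including rest-class ones,
#: whose "ramps" and "hold" stay at the rest signal level).
PHASES = ("rest", "ramp_up", "hold", "ramp_down")


class InvalidProtocolError(ValueError):
    """Raised when a :class:`ProtocolSpec` is structurally impossible."""


@dataclass(frozen=True)
class ProtocolSpec:
    """Structure of the recording protocol.

    Defaults follow a 9-class (8 active motions + rest), 6-channel,
    1024 Hz protocol with 3 s ramps, a 4 s hold, 2 repetitions per class
    per session and 3 sessions, i.e. 54 contractions (6 per class) per
    subject in total.
    """

    n_classes: int = 9
    n_channels: int = 6
    fs: int = 1024
    reps_per_session: int = 2
    n_sessions: int = 3
    ramp_s: float = 3.0
    hold_s: float = 4.0
    inter_contraction_rest_s: float = 3.0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise InvalidProtocolError("need at least one active class plus rest")
        if self.n_channels < 1:
            raise InvalidProtocolError("need at least one channel")
        if self.fs <= 0 or self.ramp_s < 0 or self.hold_s <= 0:
            raise InvalidProtocolError("fs and phase durations must be positive")
        if self.reps_per_session < 1 or self.n_sessions < 1:
            raise InvalidProtocolError("repetitions and sessions must be >= 1")

    @property
    def rest_class(self) -> int:
        """Identifier of the rest / no-motion class."""
        return self.n_classes

    @property
    def active_classes(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_classes))

    @property
    def contraction_s(self) -> float:
        return 2.0 * self.ramp_s + self.hold_s

    @property
    def contractions_per_session(self) -> int:
        return self.n_classes * self.reps_per_session

    @property
    def contractions_per_subject(self) -> int:
        return self.n_sessions * self.contractions_per_session


@dataclass(frozen=True)
class Annotation:
    """Half-open sample interval ``[start, stop)`` with class and phase."""

    start: int
    stop: int
    class_id: int
    phase: str

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("annotation interval must be non-empty")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class Contraction:
    """One full contraction: ramp-up, hold and ramp-down of a single class."""

    start: int
    stop: int
    class_id: int
    hold_start: int
    hold_stop: int

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.stop)


@dataclass
class RecordingSession:
    """Multichannel raw EMG with exhaustive class/phase annotations.

    ``signal`` is a ``(n_channels, n_samples)`` float array in arbitrary
    amplitude units; ``annotations`` are sorted, non-overlapping and cover
    every sample exactly once.
    """

    signal: np.ndarray
    fs: int
    annotations: list[Annotation] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return int(self.signal.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.signal.shape[1])

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        """Check the annotation bookkeeping invariants."""
        if self.signal.ndim != 2:
            raise ValueError("signal must be (channels, samples)")
        pos = 0
        for ann in self.annotations:
            if ann.start != pos:
                raise ValueError(
                    f"annotation gap/overlap at sample {pos} (next starts {ann.start})"
                )
            pos = ann.stop
        if pos != self.n_samples:
            raise ValueError(
                f"annotations cover {pos} samples, signal has {self.n_samples}"
            )

    def contractions(self) -> list[Contraction]:
        """Group ramp-up/hold/ramp-down annotation triples into contractions."""
        return group_contractions(self.annotations)


def group_contractions(annotations: list[Annotation]) -> list[Contraction]:
    """Group sorted annotations into ramp-up/hold/ramp-down contractions."""
    out: list[Contraction] = []
    i = 0
    while i < len(annotations):
        if annotations[i].phase == "ramp_up":
            up, hold, down = annotations[i], annotations[i + 1], annotations[i + 2]
            if hold.phase != "hold" or down.phase != "ramp_down":
                raise ValueError("malformed contraction annotation triple")
            out.append(
                Contraction(
                    start=up.start,
                    stop=down.stop,
                    class_id=hold.class_id,
                    hold_start=hold.start,
                    hold_stop=hold.stop,
                )
            )
            i += 3
        else:
            i += 1
    return out
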