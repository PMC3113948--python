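"""Decision pipeline: training-section selection, gating, vote fusion.

The classifier can be trained on five different portions of each 10 s
contraction: a centered time interval of 4 s (the static hold only),
6 s, 8 s or 10 s (the whole contraction, ramps included), or a
threshold-based selection that keeps exactly the windows whose activity
exceeds the calibrated Teager-Kaiser threshold.  The time sections are
nested: 4 s subset of 6 s subset of 8 s subset of 10 s within every
contraction.

At test time each window is first gated: an inactive window is labelled
rest outright, an active one is passed to the classifier.  The stream of
raw per-window labels is then fused causally by majority vote over the
most recent 6 decisions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import TrainedModel
from .onset import ThresholdModel, active_mask
from .protocol import group_contractions
from .windowing import WindowSeries

#: The five training sections evaluated by the study design, with the
#: length (s) of the centered interval (None = threshold-based).
SECTIONS: dict[str, float | None] = {
    "static_4s": 4.0,
    "dynamic1_6s": 6.0,
    "dynamic2_8s": 8.0,
    "all_10s": 10.0,
    "threshold_based": None,
}


@dataclass(frozen=True)
class TrainingSection:
    """Window-selection rule for classifier training."""

    name: str
    seconds: float | None  # None -> threshold-based

    @classmethod
    def named(cls, name: str) -> "TrainingSection":
        if name not in SECTIONS:
            raise ValueError(f"unknown training section {name!r}")
        return cls(name=name, seconds=SECTIONS[name])

    @classmethod
    def for_protocol(cls, name: str, protocol) -> "TrainingSection":
        """Named section scaled to a protocol's contraction geometry.

        The static section is the hold; the two intermediate sections
        extend it by one and two thirds of each ramp; the full section is
        the whole contraction.  Under the default protocol (3 s ramps,
        4 s hold) these are exactly the 4 / 6 / 8 / 10 s intervals.
        """
        if name not in SECTIONS:
            raise ValueError(f"unknown training section {name!r}")
        seconds = {
            "static_4s": protocol.hold_s,
            "dynamic1_6s": protocol.hold_s + 2 * protocol.ramp_s / 3,
            "dynamic2_8s": protocol.hold_s + 4 * protocol.ramp_s / 3,
            "all_10s": protocol.contraction_s,
            "threshold_based": None,
        }[name]
        return cls(name=name, seconds=seconds)


def standard_sections(protocol=None) -> list[TrainingSection]:
    if protocol is None:
        return [TrainingSection.named(n) for n in SECTIONS]
    return [TrainingSection.for_protocol(n, protocol) for n in SECTIONS]


def select_training_windows(
    series: WindowSeries,
    section: TrainingSection,
    model: ThresholdModel | None = None,
    activities: np.ndarray | None = None,
    classes: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the windows of ``series`` that ``section`` selects.

    Time sections keep windows lying fully inside the interval centered on
    each contraction's midpoint; the threshold-based section keeps windows
    inside contractions whose activity crosses the calibrated threshold
    (``model`` required; ``activities`` are the precomputed per-window
    Teager-Kaiser activities, computed on the fly when omitted).
    ``classes`` optionally restricts to contractions of those classes.
    """
    contractions = group_contractions(series.annotations)
    if classes is not None:
        keep = set(int(c) for c in np.atleast_1d(classes))
        contractions = [c for c in contractions if c.class_id in keep]

    starts = series.starts
    stops = starts + series.spec.length_samples
    fs = series.spec.fs
    selected: list[np.ndarray] = []

    if section.seconds is not None:
        half = 0.5 * section.seconds * fs
        for c in contractions:
            if section.seconds * fs > (c.stop - c.start) + 1e-6:
                raise ValueError(
                    f"section {section.name} longer than the contraction"
                )
            lo, hi = c.midpoint - half, c.midpoint + half
            selected.append(np.flatnonzero((starts >= lo) & (stops <= hi)))
    else:
        if model is None:
            raise ValueError("threshold-based section requires a calibrated model")
        if activities is None:
            from .onset import _activity_batch

            activities = _activity_batch(np.asarray(series.data, dtype=float),
                                         model.statistic)
        mask = active_mask(activities, model)
        for c in contractions:
            inside = (starts >= c.start) & (stops <= c.stop)
            selected.append(np.flatnonzero(inside & mask))

    if not selected:
        return np.array([], dtype=np.int64)
    return np.unique(np.concatenate(selected))


def majority_vote(labels: np.ndarray, depth: int = 6) -> np.ndarray:
    """Causal majority vote over the most recent ``depth`` raw labels.

    Before ``depth`` labels exist the vote runs over what is available.
    Ties go to the tied label that occurred most recently in the history.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    labels = np.asarray(labels)
    fused = np.empty_like(labels)
    counts: Counter = Counter()
    for k in range(len(labels)):
        counts[labels[k]] += 1
        if k >= depth:
            old = labels[k - depth]
            counts[old] -= 1
            if counts[old] == 0:
                del counts[old]
        top = max(counts.values())
        tied = {lab for lab, n in counts.items() if n == top}
        if len(tied) == 1:
            fused[k] = tied.pop()
        else:
            for j in range(k, k - depth, -1):  # most recent tied label wins
                if labels[j] in tied:
                    fused[k] = labels[j]
                    break
    return fused


@dataclass
class DecisionStream:
    """Per-window raw and vote-fused decisions of one test session."""

    starts: np.ndarray
    raw: np.ndarray
    fused: np.ndarray
    truth: np.ndarray | None = None
    vote_depth: int = 6

    def to_frame(self) -> pd.DataFrame:
        d = {"start_sample": self.starts, "raw": self.raw, "fused": self.fused}
        if self.truth is not None:
            d["truth"] = self.truth
        return pd.DataFrame(d)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def error_rate(self) -> float:
        if self.truth is None:
            raise ValueError("no ground truth attached")
        return float(np.mean(self.fused != self.truth))

    def raw_error_rate(self) -> float:
        if self.truth is None:
            raise ValueError("no ground truth attached")
        return float(np.mean(self.raw != self.truth))


def classify_stream(
    X: np.ndarray,
    model: TrainedModel,
    rest_label: int,
    gate_mask: np.ndarray | None = None,
    vote_depth: int = 6,
    starts: np.ndarray | None = None,
    truth: np.ndarray | None = None,
) -> DecisionStream:
    """Run the full per-window decision rule over a feature stream.

    ``gate_mask`` flags the windows whose activity crossed the threshold;
    inactive windows are labelled rest without consulting the classifier.
    With ``gate_mask=None`` the gate is disabled and every window is
    classified (used to expose where errors cluster without onset
    detection).
    """
    X = np.asarray(X)
    n = X.shape[0]
    raw = np.full(n, rest_label, dtype=np.int64)
    if gate_mask is None:
        raw[:] = model.predict(X)
    else:
        gate_mask = np.asarray(gate_mask, dtype=bool)
        if gate_mask.shape != (n,):
            raise ValueError("gate mask length mismatch")
        if gate_mask.any():
            raw[gate_mask] = model.predict(X[gate_mask])
    fused = majority_vote(raw, vote_depth)
    if starts is None:
        starts = np.arange(n, dtype=np.int64)
    return DecisionStream(
        starts=np.asarray(starts),
        raw=raw,
        fused=fused,
        truth=None if truth is None else np.asarray(truth),
        vote_depth=vote_depth,
    )


def boundary_mask(series: WindowSeries, margin_s: float = 1.0) -> np.ndarray:
    """Windows whose centers lie within ``margin_s`` of a contraction edge.

    This is where classification errors concentrate when no onset gate is
    used: near the start and end of each contraction the signal is close
    to the rest level while the ground-truth label is the motion class.
    """
    centers = series.starts + series.spec.length_samples / 2.0
    m = np.zeros(series.n_windows, dtype=bool)
    margin = margin_s * series.spec.fs
    for c in group_contractions(series.annotations):
        for edge in (c.start, c.stop):
            m |= np.abs(centers - edge) <= margin
    return m
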