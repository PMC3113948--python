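"""Factorial experiment driver: feature set x classifier x training section.

Every subject is evaluated by three-fold, leave-one-session-out
cross-validation: two sessions form the learning data (36 contractions,
4 per class under the default protocol) on which the activity threshold
is calibrated and the classifier trained; the held-out session is scored
on the vote-fused decision of *every* window, rest windows included.

Per-subject section errors are additionally normalized by the subject's
ability index — the mean of the five section errors — so relative section
performance is comparable across subjects of different overall skill:
``eta_x = e_x / sigma_i`` with ``sigma_i = mean_x e_x``, which makes the
mean of the five normalized errors exactly 1 for every subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import ClassifierSpec, train
from .features import FEATURE_SETS, FeatureExtractor
from .onset import ThresholdModel, _activity_batch, active_mask, calibrate_from_activities
from .pipeline import (
    SECTIONS,
    TrainingSection,
    boundary_mask,
    classify_stream,
    select_training_windows,
)
from .protocol import ProtocolSpec, RecordingSession
from .synthetic import iter_dataset
from .windowing import WindowSeries, WindowSpec, segment


@dataclass
class SessionView:
    """A session reduced to windows, labels, activities and features.

    The raw signal is dropped once features and activities are computed,
    so a whole multi-subject experiment fits comfortably in memory.
    """

    series: WindowSeries
    activities: np.ndarray
    features: dict[str, np.ndarray]

    @property
    def class_labels(self) -> np.ndarray:
        return self.series.class_labels

    @property
    def phase_labels(self) -> np.ndarray:
        return self.series.phase_labels


def prepare_session(
    session: RecordingSession,
    wspec: WindowSpec,
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    statistic: str = "mean",
    **feature_kwargs,
) -> SessionView:
    """Segment, featurize and drop the raw signal of one session."""
    series = segment(session, wspec)
    data = np.ascontiguousarray(series.data, dtype=float)
    feats = {
        fs: FeatureExtractor(feature_set=fs, **feature_kwargs).transform(data)
        for fs in feature_sets
    }
    acts = _activity_batch(data, statistic)
    series.data = None  # free the signal view; provenance stays
    return SessionView(series=series, activities=acts, features=feats)


@dataclass(frozen=True)
class Combo:
    """One cell of the factorial design."""

    feature_set: str
    classifier: ClassifierSpec
    section: str


def full_factorial(
    feature_sets: tuple[str, ...] = FEATURE_SETS,
    classifier_kinds: tuple[str, ...] = ("lda", "svm_ovo", "svm_ovr"),
    sections: tuple[str, ...] = tuple(SECTIONS),
    hyperparams: tuple | str = (10.0, "scale"),
    seed: int = 0,
) -> list[Combo]:
    return [
        Combo(fs, ClassifierSpec(kind=k, hyperparams=hyperparams, seed=seed), s)
        for fs in feature_sets
        for k in classifier_kinds
        for s in sections
    ]


def _fold_gate(
    train_views: list[SessionView],
    rest_label: int,
    **gate_kwargs,
) -> ThresholdModel:
    """Calibrate the threshold on the learning folds only: rest windows set
    the per-channel reference, active-class hold windows the coverage."""
    act, lab, rest = [], [], []
    for v in train_views:
        is_rest = v.class_labels == rest_label
        is_hold = (v.phase_labels == "hold") & ~is_rest
        act.append(v.activities[is_hold])
        lab.append(v.class_labels[is_hold])
        rest.append(v.activities[is_rest])
    return calibrate_from_activities(
        np.concatenate(act), np.concatenate(lab), np.concatenate(rest), **gate_kwargs
    )


def run_subject(
    subject_id: int,
    views: list[SessionView],
    protocol: ProtocolSpec,
    combos: list[Combo],
    vote_depth: int = 6,
    train_decimation: int | None = None,
    boundary_combos: set[tuple[str, str, str]] | None = None,
    boundary_margin_s: float = 1.0,
    gate_kwargs: dict | None = None,
    include_rest_in_training: bool = True,
) -> list[dict]:
    """Leave-one-session-out evaluation of all ``combos`` for one subject.

    With ``include_rest_in_training`` (default) the rest class is a
    regular classifier class: the training sections also select windows
    from the contraction-shaped rest-class segments, so the learning set
    holds 4 contractions of each of the 9 classes.  The activity gate
    still assigns rest to every sub-threshold window at test time.
    """
    rest = protocol.rest_class
    train_classes = np.arange(1, protocol.n_classes + 1) \
        if include_rest_in_training else np.array(protocol.active_classes)
    rows: list[dict] = []
    spec0 = views[0].series.spec
    if train_decimation is None:
        train_decimation = max(1, spec0.length_samples // spec0.step_samples)

    for k, test in enumerate(views):
        train_views = [v for j, v in enumerate(views) if j != k]
        gate = _fold_gate(train_views, rest, **(gate_kwargs or {}))
        test_mask = active_mask(test.activities, gate)
        truth = test.class_labels
        b_mask = (
            boundary_mask(test.series, boundary_margin_s) if boundary_combos else None
        )

        for section_name in dict.fromkeys(c.section for c in combos):
            section = (
                section_name
                if isinstance(section_name, TrainingSection)
                else TrainingSection.for_protocol(section_name, protocol)
            )
            idxs = [
                select_training_windows(
                    v.series, section, model=gate, activities=v.activities,
                    classes=train_classes,
                )[::train_decimation]
                for v in train_views
            ]
            y = np.concatenate([v.class_labels[i] for v, i in zip(train_views, idxs)])
            for combo in (c for c in combos if c.section == section_name):
                X = np.concatenate(
                    [v.features[combo.feature_set][i] for v, i in zip(train_views, idxs)]
                )
                model = train(X, y, combo.classifier)
                stream = classify_stream(
                    test.features[combo.feature_set],
                    model,
                    rest,
                    gate_mask=test_mask,
                    vote_depth=vote_depth,
                    starts=test.series.starts,
                    truth=truth,
                )
                row = {
                    "subject": subject_id,
                    "fold": k,
                    "feature_set": combo.feature_set,
                    "classifier": combo.classifier.kind,
                    "section": section_name,
                    "error": stream.error_rate(),
                    "raw_error": stream.raw_error_rate(),
                    "n_train": len(y),
                    "n_test": len(truth),
                    "gate_coefficient": gate.coefficient,
                }
                key = (combo.feature_set, combo.classifier.kind, section_name)
                if boundary_combos and key in boundary_combos:
                    # the gate's mechanism is isolated with a rest-free
                    # classifier (rest assigned by the threshold alone):
                    # with the gate off, every window gets a motion label
                    active_sel = y != rest
                    bmodel = train(X[active_sel], y[active_sel], combo.classifier)
                    gated = classify_stream(
                        test.features[combo.feature_set],
                        bmodel,
                        rest,
                        gate_mask=test_mask,
                        vote_depth=vote_depth,
                        truth=truth,
                    )
                    ungated = classify_stream(
                        test.features[combo.feature_set],
                        bmodel,
                        rest,
                        gate_mask=None,
                        vote_depth=vote_depth,
                        truth=truth,
                    )
                    row["boundary_error_gated"] = float(
                        np.mean(gated.fused[b_mask] != truth[b_mask])
                    )
                    row["boundary_error_ungated"] = float(
                        np.mean(ungated.fused[b_mask] != truth[b_mask])
                    )
                    row["overall_error_ungated"] = ungated.error_rate()
                rows.append(row)
    return rows


def run_experiment(
    protocol: ProtocolSpec,
    n_subjects: int,
    master_seed: int,
    combos: list[Combo],
    wspec: WindowSpec | None = None,
    vote_depth: int = 6,
    train_decimation: int | None = None,
    boundary_combos: set[tuple[str, str, str]] | None = None,
    gate_kwargs: dict | None = None,
    include_rest_in_training: bool = True,
    progress=None,
) -> pd.DataFrame:
    """Run ``combos`` over a freshly generated synthetic dataset.

    Returns a tidy frame with one row per (subject, fold, combo).
    """
    wspec = wspec or WindowSpec(fs=protocol.fs)
    needed = tuple(dict.fromkeys(c.feature_set for c in combos))
    rows: list[dict] = []
    for i, subject, sessions in iter_dataset(protocol, n_subjects, master_seed):
        views = [prepare_session(s, wspec, needed) for s in sessions]
        del sessions
        rows += run_subject(
            i,
            views,
            protocol,
            combos,
            vote_depth=vote_depth,
            train_decimation=train_decimation,
            boundary_combos=boundary_combos,
            gate_kwargs=gate_kwargs,
            include_rest_in_training=include_rest_in_training,
        )
        if progress is not None:
            progress(i)
    return pd.DataFrame(rows)


def cross_validate(
    protocol: ProtocolSpec,
    n_subjects: int,
    master_seed: int,
    feature_set: str,
    classifier: ClassifierSpec,
    section: str,
    **kwargs,
) -> pd.Series:
    """Per-subject cross-validated error of a single design cell."""
    df = run_experiment(
        protocol, n_subjects, master_seed, [Combo(feature_set, classifier, section)],
        **kwargs,
    )
    return df.groupby("subject")["error"].mean()


# ---------------------------------------------------------------------------
# ability index and normalized errors


def ability_index(errors) -> float:
    """Per-subject ability index: the mean of the five section errors."""
    e = _as_error_vector(errors)
    return float(np.mean(e))


def normalized_errors(errors) -> np.ndarray:
    """Section errors divided by the subject's ability index.

    Undefined (all-NaN) when the ability index is zero; by construction
    the mean of the returned values is exactly 1 otherwise.
    """
    e = _as_error_vector(errors)
    sigma = np.mean(e)
    if sigma == 0:
        return np.full_like(e, np.nan)
    return e / sigma


def _as_error_vector(errors) -> np.ndarray:
    if isinstance(errors, dict):
        missing = [s for s in SECTIONS if s not in errors]
        if missing:
            raise ValueError(f"missing section errors: {missing}")
        e = np.array([errors[s] for s in SECTIONS], dtype=float)
    else:
        e = np.asarray(errors, dtype=float)
        if e.shape != (len(SECTIONS),):
            raise ValueError(f"expected {len(SECTIONS)} section errors")
    if np.any(e < 0) or np.any(e > 1):
        raise ValueError("error rates must lie in [0, 1]")
    return e


def subject_errors(df: pd.DataFrame) -> pd.DataFrame:
    """Fold-averaged error per (subject, feature_set, classifier, section)."""
    return (
        df.groupby(["subject", "feature_set", "classifier", "section"])["error"]
        .mean()
        .reset_index()
    )


def add_normalized(df: pd.DataFrame) -> pd.DataFrame:
    """Attach ability index and normalized error to fold-averaged results.

    Rows of combos without all five sections get NaN normalized errors.
    """
    out = subject_errors(df)
    sigma = (
        out.groupby(["subject", "feature_set", "classifier"])["error"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "ability_index"})
    )
    out = out.join(
        sigma, on=["subject", "feature_set", "classifier"]
    )
    complete = out["count"] == len(SECTIONS)
    nonzero = out["ability_index"] > 0
    out["normalized_error"] = np.where(
        complete & nonzero, out["error"] / out["ability_index"], np.nan
    )
    return out.drop(columns="count")


def summarize(df: pd.DataFrame, percent: bool = True) -> pd.DataFrame:
    """Mean +/- SD across subjects per (section, classifier, feature set).

    The layout mirrors the study's summary table: 5 section rows by
    (classifier x feature set) columns.
    """
    per_subj = subject_errors(df)
    scale = 100.0 if percent else 1.0
    g = per_subj.groupby(["section", "classifier", "feature_set"])["error"]
    stats = g.agg(["mean", "std"]) * scale
    cells = stats.apply(
        lambda r: f"{r['mean']:.2f} ± {r['std']:.2f}", axis=1
    )
    table = cells.unstack(["classifier", "feature_set"])
    order = [s for s in SECTIONS if s in table.index]
    return table.loc[order]


def summary_stats(df: pd.DataFrame, percent: bool = True) -> pd.DataFrame:
    """Numeric mean/SD per cell (tidy), for programmatic consumption."""
    per_subj = subject_errors(df)
    scale = 100.0 if percent else 1.0
    g = per_subj.groupby(["section", "classifier", "feature_set"])["error"]
    out = g.agg(mean="mean", sd="std", n_subjects="count").reset_index()
    out[["mean", "sd"]] *= scale
    return out
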