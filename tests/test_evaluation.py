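"""Cross-validation driver, ability index and result summaries."""

import numpy as np
import pandas as pd
import pytest

from emgdyn import ClassifierSpec, Combo, WindowSpec, ability_index, normalized_errors
from emgdyn.evaluation import (
    add_normalized,
    full_factorial,
    prepare_session,
    run_subject,
    subject_errors,
    summarize,
    summary_stats,
)
from emgdyn.pipeline import SECTIONS


class TestAbilityIndex:
    def test_equal_errors(self):
        e = dict.fromkeys(SECTIONS, 0.10)
        assert ability_index(e) == pytest.approx(0.10)
        np.testing.assert_allclose(normalized_errors(e), 1.0)

    def test_hand_computed_vector(self):
        e = [0.05, 0.10, 0.10, 0.10, 0.15]
        assert ability_index(e) == pytest.approx(0.10)
        np.testing.assert_allclose(
            normalized_errors(e), [0.5, 1.0, 1.0, 1.0, 1.5]
        )

    def test_mean_of_normalized_errors_is_one(self, rng):
        for _ in range(20):
            e = rng.uniform(0.01, 0.6, size=5)
            assert normalized_errors(e).mean() == pytest.approx(1.0)

    def test_zero_ability_undefined(self):
        eta = normalized_errors(np.zeros(5))
        assert np.all(np.isnan(eta))

    def test_missing_section_rejected(self):
        with pytest.raises(ValueError):
            ability_index({"static_4s": 0.1})
        with pytest.raises(ValueError):
            ability_index([0.1, 0.2])

    def test_error_range_validated(self):
        with pytest.raises(ValueError):
            ability_index([0.1, 0.2, 0.3, 0.4, 1.2])


def _toy_results():
    rows = []
    for subj in (0, 1):
        for i, sec in enumerate(SECTIONS):
            rows.append(
                dict(subject=subj, fold=0, feature_set="td_ar", classifier="lda",
                     section=sec, error=0.1 + 0.02 * i + 0.05 * subj)
            )
    return pd.DataFrame(rows)


class TestSummaries:
    def test_add_normalized_identity(self):
        out = add_normalized(_toy_results())
        means = out.groupby("subject")["normalized_error"].mean()
        np.testing.assert_allclose(means.to_numpy(), 1.0)

    def test_summary_table_shape_full_factorial(self):
        rows = []
        for fs in ("td_ar", "wt"):
            for clf in ("lda", "svm_ovo", "svm_ovr"):
                for sec in SECTIONS:
                    rows.append(dict(subject=0, fold=0, feature_set=fs,
                                     classifier=clf, section=sec, error=0.1))
        table = summarize(pd.DataFrame(rows))
        assert table.shape == (5, 6)  # 5 sections x (3 classifiers x 2 feature sets)
        assert list(table.index) == list(SECTIONS)

    def test_sd_zero_for_identical_subjects(self):
        df = _toy_results()
        df["error"] = 0.2
        stats = summary_stats(df)
        np.testing.assert_allclose(stats["sd"], 0.0)
        np.testing.assert_allclose(stats["mean"], 20.0)

    def test_cell_means_match_raw_recomputation(self):
        df = _toy_results()
        stats = summary_stats(df, percent=False)
        raw = subject_errors(df)
        for _, r in stats.iterrows():
            m = raw[(raw.section == r.section)]["error"].mean()
            assert r["mean"] == pytest.approx(m)

    def test_full_factorial_count(self):
        assert len(full_factorial()) == 30


class TestRandomGuessBaseline:
    def test_uniform_guessing_error_close_to_eight_ninths(self, rng):
        n = 20000
        truth = rng.integers(1, 10, size=n)
        guess = rng.integers(1, 10, size=n)
        err = np.mean(guess != truth)
        # binomial 99.9% interval around 8/9
        assert abs(err - 8 / 9) < 3.3 * np.sqrt((8 / 9) * (1 / 9) / n)


@pytest.fixture(scope="module")
def small_views(small_sessions, small_protocol):
    _, sessions = small_sessions
    wspec = WindowSpec(fs=small_protocol.fs)
    return [prepare_session(s, wspec, ("td_ar",)) for s in sessions]


class TestCrossValidationStructure:
    def test_training_folds_hold_four_contractions_per_class(
        self, small_sessions, small_protocol
    ):
        # leave-one-session-out: remaining sessions supply
        # (n_sessions - 1) * reps_per_session contractions of every class
        _, sessions = small_sessions
        per_class = (small_protocol.n_sessions - 1) * small_protocol.reps_per_session
        for k in range(3):
            train_sessions = [s for j, s in enumerate(sessions) if j != k]
            ids = [c.class_id for s in train_sessions for c in s.contractions()]
            total = len(ids)
            assert total == per_class * small_protocol.n_classes
            for cid in range(1, small_protocol.n_classes + 1):
                assert ids.count(cid) == per_class

    def test_default_protocol_training_fold_is_36_contractions(self, protocol):
        per_fold = (protocol.n_sessions - 1) * protocol.reps_per_session
        assert per_fold * protocol.n_classes == 36
        assert per_fold == 4  # contractions per class in the learning data

    def test_run_subject_produces_row_per_fold_and_combo(
        self, small_views, small_protocol
    ):
        combos = [
            Combo("td_ar", ClassifierSpec("lda"), "static_4s"),
            Combo("td_ar", ClassifierSpec("lda"), "all_10s"),
        ]
        rows = run_subject(0, small_views, small_protocol, combos)
        df = pd.DataFrame(rows)
        assert len(df) == 3 * len(combos)
        assert set(df.fold) == {0, 1, 2}
        assert np.all((df.error >= 0) & (df.error <= 1))

    def test_near_perfect_pipeline_on_separable_subject(
        self, small_views, small_protocol
    ):
        """High-SNR miniature protocol: the full gated pipeline commits
        few errors when trained on entire contractions."""
        combos = [Combo("td_ar", ClassifierSpec("lda"), "all_10s")]
        rows = run_subject(0, small_views, small_protocol, combos)
        assert pd.DataFrame(rows)["error"].mean() < 0.35

    def test_no_leakage_into_gate(self, small_views, small_protocol):
        """Perturbing the held-out session's activities must not change
        the calibrated coefficient (gate sees training folds only)."""
        from emgdyn.evaluation import _fold_gate

        views = small_views
        gate1 = _fold_gate(views[1:], small_protocol.rest_class)
        views[0].activities *= 100.0
        gate2 = _fold_gate(views[1:], small_protocol.rest_class)
        views[0].activities /= 100.0
        assert gate1.coefficient == gate2.coefficient
        np.testing.assert_array_equal(gate1.rest_activity, gate2.rest_activity)
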