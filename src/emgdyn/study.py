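"""The headline synthetic study: training-section effects at desk scale.

Runs the design cells the study's conclusions rest on — TD+AR/LDA and
WT/SVM-OVO over all five training sections, TD+AR/SVM-OVR over the five
sections, plus the boundary-error comparison with and without the
activity gate — over a cohort of synthetic subjects under the default
protocol.  Used by the acceptance machinery and reproducible from the
command line through :mod:`emgdyn.cli`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classification import ClassifierSpec
from .evaluation import Combo, add_normalized, run_experiment
from .pipeline import SECTIONS
from .protocol import ProtocolSpec

#: The (feature set, classifier) pairs the study's headline comparisons use.
HEADLINE_PAIRS = (("td_ar", "lda"), ("wt", "svm_ovo"), ("td_ar", "svm_ovr"))

BOUNDARY_CELL = ("td_ar", "lda", "static_4s")


def headline_combos(hyperparams=(10.0, "scale"), seed: int = 0) -> list[Combo]:
    return [
        Combo(fs, ClassifierSpec(kind=kind, hyperparams=hyperparams, seed=seed), sec)
        for fs, kind in HEADLINE_PAIRS
        for sec in SECTIONS
    ]


def run_headline_study(
    master_seed: int,
    n_subjects: int = 8,
    protocol: ProtocolSpec | None = None,
    progress=None,
) -> pd.DataFrame:
    """Run the headline cells; returns the tidy per-(subject, fold) frame."""
    protocol = protocol or ProtocolSpec()
    return run_experiment(
        protocol,
        n_subjects,
        master_seed,
        headline_combos(seed=master_seed % (2**31 - 1)),
        boundary_combos={BOUNDARY_CELL},
        progress=progress,
    )


def section_means(df: pd.DataFrame, feature_set: str, classifier: str) -> pd.Series:
    """Across-subject mean error per section for one (feature, classifier)
    pair, ordered static -> threshold-based."""
    sub = df[(df.feature_set == feature_set) & (df.classifier == classifier)]
    per_subject = sub.groupby(["subject", "section"])["error"].mean()
    return per_subject.groupby("section").mean().reindex(list(SECTIONS))


def boundary_effect(df: pd.DataFrame) -> pd.Series:
    """Mean boundary-region error with and without the activity gate,
    plus the ungated overall error, for the rest-free boundary cell."""
    cols = [
        "boundary_error_gated",
        "boundary_error_ungated",
        "overall_error_ungated",
    ]
    sub = df.dropna(subset=cols)
    return sub.groupby("subject")[cols].mean().mean()


def normalized_section_means(
    df: pd.DataFrame, feature_set: str, classifier: str
) -> pd.Series:
    norm = add_normalized(df)
    sub = norm[(norm.feature_set == feature_set) & (norm.classifier == classifier)]
    return sub.groupby("section")["normalized_error"].mean().reindex(list(SECTIONS))
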