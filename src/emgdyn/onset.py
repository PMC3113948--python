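"""Teager-Kaiser energy activity detection and threshold calibration.

Contraction onset is detected per analysis window: every channel receives
an activity value (mean absolute Teager-Kaiser energy over the window)
and the window counts as *active* when at least one channel's activity
strictly exceeds ``coefficient x rest_activity`` for that channel, where
the per-channel rest activities are measured on rest windows of the
learning data.

The multiplicative coefficient is calibrated per subject on the static
(hold) portions of the learning data: it is the *largest* value on a
log-spaced search grid such that more than 97% of all active-class hold
windows are flagged active and at least 85% of each individual class's
hold windows are.  Because the set of active windows shrinks monotonically
as the coefficient grows, the feasible set is a down-set on the grid and
the maximizer is exact up to grid resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from sklearn.base import BaseEstimator

DEFAULT_GRID = ("log", -1.0, 3.0, 400)  # 10^-1 .. 10^3, 400 points


class CalibrationError(RuntimeError):
    """No coefficient on the grid satisfies the coverage constraints."""

    def __init__(self, msg: str, best_overall: float = np.nan, best_per_class: float = np.nan):
        super().__init__(msg)
        self.best_overall = best_overall
        self.best_per_class = best_per_class


def default_grid() -> np.ndarray:
    _, lo, hi, n = DEFAULT_GRID
    return np.logspace(lo, hi, n)


def tkeo(x: np.ndarray) -> np.ndarray:
    """Teager-Kaiser energy psi[n] = x[n]^2 - x[n-1]*x[n+1] (interior samples).

    Output is 2 samples shorter than the input.  For a pure sinusoid
    ``A*sin(w*n)`` the output is the constant ``A^2 * sin(w)^2``, which is
    what makes the operator an instantaneous energy estimator.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 3:
        raise ValueError("need at least 3 samples")
    return x[..., 1:-1] ** 2 - x[..., :-2] * x[..., 2:]


def window_activity(window: np.ndarray, statistic: str = "mean") -> np.ndarray:
    """Per-channel activity of one ``(channels, samples)`` window.

    The aggregation of the rectified Teager-Kaiser output over the window
    is configurable (mean by default; max and sum behave similarly up to
    scale on stationary windows).
    """
    w = np.atleast_2d(np.asarray(window, dtype=float))
    return _activity_batch(w[None, ...], statistic)[0]


def _activity_batch(windows: np.ndarray, statistic: str = "mean") -> np.ndarray:
    """Activities of a (n, channels, samples) stack -> (n, channels)."""
    psi = np.abs(tkeo(windows))
    if statistic == "mean":
        return psi.mean(axis=-1)
    if statistic == "max":
        return psi.max(axis=-1)
    if statistic == "sum":
        return psi.sum(axis=-1)
    raise ValueError(f"unknown activity statistic {statistic!r}")


@dataclass
class ThresholdModel:
    """Calibrated per-subject activity threshold."""

    rest_activity: np.ndarray
    coefficient: float
    overall_min: float = 0.97
    per_class_min: float = 0.85
    statistic: str = "mean"

    def __post_init__(self) -> None:
        self.rest_activity = np.asarray(self.rest_activity, dtype=float)
        if self.coefficient <= 0:
            raise ValueError("coefficient must be positive")
        if np.any(self.rest_activity < 0):
            raise ValueError("rest activities must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "rest_activity": self.rest_activity.tolist(),
                    "coefficient": self.coefficient,
                    "overall_min": self.overall_min,
                    "per_class_min": self.per_class_min,
                    "statistic": self.statistic,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "ThresholdModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            rest_activity=np.array(d["rest_activity"]),
            coefficient=d["coefficient"],
            overall_min=d["overall_min"],
            per_class_min=d["per_class_min"],
            statistic=d["statistic"],
        )


def is_active(window: np.ndarray, model: ThresholdModel) -> bool:
    """True iff at least one channel strictly crosses its threshold."""
    act = window_activity(window, model.statistic)
    return bool(np.any(act > model.coefficient * model.rest_activity))


def active_mask(activities: np.ndarray, model: ThresholdModel) -> np.ndarray:
    """Vectorized :func:`is_active` from precomputed (n, channels) activities."""
    return np.any(activities > model.coefficient * model.rest_activity, axis=1)


def calibrate_from_activities(
    active_activities: np.ndarray,
    labels: np.ndarray,
    rest_activities: np.ndarray,
    grid: np.ndarray | None = None,
    overall_min: float = 0.97,
    per_class_min: float = 0.85,
    statistic: str = "mean",
) -> ThresholdModel:
    """Calibrate the coefficient from precomputed window activities.

    ``active_activities``/``labels`` are the hold windows of the active
    classes in the learning data; ``rest_activities`` the rest windows.
    """
    active_activities = np.asarray(active_activities, dtype=float)
    labels = np.asarray(labels)
    rest_activities = np.asarray(rest_activities, dtype=float)
    if active_activities.ndim != 2 or rest_activities.ndim != 2:
        raise ValueError("activities must be (n_windows, n_channels)")
    if len(labels) != len(active_activities):
        raise ValueError("labels/activities length mismatch")
    if len(active_activities) == 0 or len(rest_activities) == 0:
        raise ValueError("need both active-class and rest windows")
    grid = default_grid() if grid is None else np.sort(np.asarray(grid, dtype=float))

    rest_ref = rest_activities.mean(axis=0)
    pos = rest_ref > 0
    if not np.any(pos):
        raise CalibrationError("all-zero rest reference activity")
    # a window is active at coefficient c iff max_ch activity/rest > c;
    # a zero-rest channel crosses any threshold as soon as it shows activity
    per_ch = np.where(
        pos,
        active_activities / np.where(pos, rest_ref, 1.0),
        np.where(active_activities > 0, np.inf, -np.inf),
    )
    ratio = np.max(per_ch, axis=1)
    classes = np.unique(labels)
    # feasibility is monotone non-increasing in c: take the largest feasible
    coefficient = None
    best_overall, best_per_class = -np.inf, -np.inf
    for c in grid[::-1]:
        flag = ratio > c
        overall = flag.mean()
        per_class = min(flag[labels == k].mean() for k in classes)
        best_overall = max(best_overall, overall)
        best_per_class = max(best_per_class, per_class)
        if overall > overall_min and per_class >= per_class_min:
            coefficient = float(c)
            break
    if coefficient is None:
        raise CalibrationError(
            "no grid coefficient satisfies the coverage constraints "
            f"(best overall {best_overall:.3f}, best per-class {best_per_class:.3f})",
            best_overall,
            best_per_class,
        )
    return ThresholdModel(
        rest_activity=rest_ref,
        coefficient=coefficient,
        overall_min=overall_min,
        per_class_min=per_class_min,
        statistic=statistic,
    )


def calibrate(
    active_windows: np.ndarray,
    labels: np.ndarray,
    rest_windows: np.ndarray,
    grid: np.ndarray | None = None,
    overall_min: float = 0.97,
    per_class_min: float = 0.85,
    statistic: str = "mean",
) -> ThresholdModel:
    """Calibrate a :class:`ThresholdModel` from raw training windows.

    ``active_windows``: ``(n, channels, samples)`` hold windows of the
    active classes; ``rest_windows``: rest windows of the learning data.
    """
    return calibrate_from_activities(
        _activity_batch(np.asarray(active_windows, dtype=float), statistic),
        labels,
        _activity_batch(np.asarray(rest_windows, dtype=float), statistic),
        grid=grid,
        overall_min=overall_min,
        per_class_min=per_class_min,
        statistic=statistic,
    )


class TkeoGate(BaseEstimator):
    """Sklearn-style activity gate: fit = calibrate, predict = is_active.

    ``fit(W, y)`` expects a window stack with labels where ``rest_label``
    marks rest windows and all other labels are active-class hold windows.
    """

    def __init__(
        self,
        rest_label: int = 9,
        overall_min: float = 0.97,
        per_class_min: float = 0.85,
        statistic: str = "mean",
        grid: np.ndarray | None = None,
    ):
        self.rest_label = rest_label
        self.overall_min = overall_min
        self.per_class_min = per_class_min
        self.statistic = statistic
        self.grid = grid

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TkeoGate":
        y = np.asarray(y)
        rest = np.asarray(X)[y == self.rest_label]
        act = np.asarray(X)[y != self.rest_label]
        self.model_ = calibrate(
            act,
            y[y != self.rest_label],
            rest,
            grid=self.grid,
            overall_min=self.overall_min,
            per_class_min=self.per_class_min,
            statistic=self.statistic,
        )
        self.rest_activity_ = self.model_.rest_activity
        self.coefficient_ = self.model_.coefficient
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("gate is not fitted")
        return active_mask(
            _activity_batch(np.asarray(X, dtype=float), self.statistic), self.model_
        )
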