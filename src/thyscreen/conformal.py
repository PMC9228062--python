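"""Aggregated Mondrian inductive conformal classification.

The central estimator wraps a random-forest classifier in the inductive
conformal prediction (ICP) framework with class-conditional (Mondrian)
calibration.  For a binary activity endpoint the workflow is:

1. set aside a stratified validation partition (20% by default, handled by
   :func:`split_data` / :func:`fit_aggregated`);
2. build ``n_models`` (default 50) ICP members, each on its own stratified
   70/30 split of the working training set into a proper training part
   (random forest fit, 300 trees) and a calibration part;
3. for each calibration compound store the nonconformity score
   ``alpha = 1 - P_hat(true class | x)`` in its true class's list;
4. at prediction time compute, per class ``c``, the Mondrian p-value

       p_c(x) = (#{alpha_cal_c >= alpha_c(x)} + 1) / (n_cal_c + 1)

   for every member and aggregate by the member-wise median;
5. at a user-chosen significance level ``sl`` the prediction set is
   ``{c : p_c > sl}``, reported as one of four regions: a single class
   label, ``both`` (uncertain) or ``empty`` (outside the applicability
   domain).  The decidability score ``p_active - p_inactive`` ranks how
   confidently a compound separates the classes.

Under exchangeability a single Mondrian ICP guarantees, per class, an error
rate (true label excluded from the prediction set) of at most ``sl``; the
median aggregation trades the finite-sample guarantee for lower variance and
is conservative in practice.

p-values are non-smoothed (ties counted with >=, +1 correction), so outputs
are deterministic; label inclusion uses the strict rule ``p > sl``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "SplitPlan",
    "PValuePair",
    "PredictionRecord",
    "p_value",
    "assign_region",
    "AggregatedConformalClassifier",
    "split_data",
    "fit_aggregated",
]

REGION_BOTH = "both"
REGION_EMPTY = "empty"


@dataclass(frozen=True)
class SplitPlan:
    """How an endpoint dataset is partitioned for aggregated ICP training.

    ``proper_training_fraction`` and ``calibration_fraction`` refer to the
    working training set left after removing the validation partition and
    must sum to 1.  All splits are stratified by class.
    """

    validation_fraction: float = 0.20
    proper_training_fraction: float = 0.70
    calibration_fraction: float = 0.30
    stratified: bool = True
    base_seed: int = 0

    def __post_init__(self):
        for name in ("validation_fraction", "proper_training_fraction",
                     "calibration_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if abs(self.proper_training_fraction + self.calibration_fraction - 1.0) > 1e-9:
            raise ValueError(
                "proper_training_fraction + calibration_fraction must equal 1"
            )


@dataclass(frozen=True)
class PValuePair:
    """Median-aggregated conformal p-values for the two activity classes.

    The two values are separate class-conditional tests and do not sum to 1.
    """

    p_active: float
    p_inactive: float


@dataclass(frozen=True)
class PredictionRecord:
    """Per-compound conformal prediction at one significance level."""

    compound_id: str
    p_values: PValuePair
    region: str  # "active" | "inactive" | "both" | "empty"
    decidability: float
    significance_level: float


def p_value(calibration_scores: Sequence[float], test_score: float) -> float:
    """Non-smoothed conformal p-value of one test nonconformity score.

    ``(#{calibration scores >= test_score} + 1) / (n + 1)`` — the rank of
    the test score among the calibration scores of its class, so values lie
    in ``(0, 1]`` and a score stranger than everything seen in calibration
    gets the minimal p-value ``1/(n+1)``.
    """
    scores = np.asarray(calibration_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("calibration_scores must be non-empty")
    if not np.all(np.isfinite(scores)) or not np.isfinite(test_score):
        raise ValueError("nonconformity scores must be finite")
    return (float(np.sum(scores >= test_score)) + 1.0) / (scores.size + 1.0)


def assign_region(
    p_active: float, p_inactive: float, significance_level: float
) -> tuple[str, float]:
    """Map a p-value pair to a prediction region and decidability score.

    A label is included in the prediction set iff its p-value is strictly
    greater than the significance level.  Both labels -> ``both``; neither
    -> ``empty`` (outside the applicability domain).  Decidability is
    ``p_active - p_inactive``.
    """
    if not 0.0 < significance_level < 1.0:
        raise ValueError("significance_level must be in (0, 1)")
    act = p_active > significance_level
    ina = p_inactive > significance_level
    if act and ina:
        region = REGION_BOTH
    elif act:
        region = "active"
    elif ina:
        region = "inactive"
    else:
        region = REGION_EMPTY
    return region, p_active - p_inactive


class _ICPMember:
    """One inductive conformal member: a fitted forest plus sorted
    class-conditional calibration nonconformity scores."""

    __slots__ = ("forest", "calibration_scores", "classes", "seed")

    def __init__(self, forest, calibration_scores, classes, seed):
        self.forest = forest
        self.calibration_scores = calibration_scores  # {class: sorted array}
        self.classes = classes
        self.seed = seed

    def p_values(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, n_classes) Mondrian p-values, columns per classes."""
        proba = self.forest.predict_proba(X)
        # forest class order may differ from the aggregate's
        col = {c: j for j, c in enumerate(self.forest.classes_)}
        out = np.empty((X.shape[0], len(self.classes)))
        for k, c in enumerate(self.classes):
            alpha = 1.0 - proba[:, col[c]]
            cal = self.calibration_scores[c]  # sorted ascending
            # #{cal >= alpha} = n - first index with cal >= alpha
            ge = cal.size - np.searchsorted(cal, alpha, side="left")
            out[:, k] = (ge + 1.0) / (cal.size + 1.0)
        return out


class AggregatedConformalClassifier(ClassifierMixin, BaseEstimator):
    """Aggregated class-conditional inductive conformal classifier.

    Fits ``n_models`` ICP members on different stratified splits of the
    training data and aggregates their Mondrian p-values by the median.

    Parameters
    ----------
    n_models : int, default=50
        Number of aggregated ICP members.
    n_estimators : int, default=300
        Trees per underlying random forest; all other forest
        hyperparameters are library defaults.
    calibration_fraction : float, default=0.3
        Fraction of the training data each member reserves for calibration
        (the rest trains its forest).
    significance_level : float, default=0.1
        Default acceptable error rate used by :meth:`predict`.
    pos_label : object, default="active"
        Label treated as the active class for decidability scores.  If it
        is not among the fitted classes and the classes are {0, 1}, 1 is
        used.
    random_state : int, default=0
        Base seed; member ``i`` uses ``random_state + i`` for both its
        train/calibration split and its forest.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Class labels seen during fit.
    members_ : list of fitted ICP members.
    pos_label_ : resolved active-class label.
    n_invalid_members_ : members discarded because their calibration part
        lost a class (refused and refit counted against the 10% abort
        threshold).
    """

    _parameter_constraints: dict = {}

    def __init__(self, n_models: int = 50, n_estimators: int = 300,
                 calibration_fraction: float = 0.3,
                 significance_level: float = 0.1,
                 pos_label="active", random_state: int = 0):
        self.n_models = n_models
        self.n_estimators = n_estimators
        self.calibration_fraction = calibration_fraction
        self.significance_level = significance_level
        self.pos_label = pos_label
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X, y):
        X, y = validate_data(self, X, y, dtype=float, ensure_min_samples=4)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"expected exactly 2 classes, got {list(self.classes_)}"
            )
        counts = {c: int(np.sum(y == c)) for c in self.classes_}
        for c, n in counts.items():
            if n == 0:
                raise ValueError(f"class {c!r} has no training compounds")
            if n < 5:
                warnings.warn(
                    f"class {c!r} has only {n} training compounds; "
                    "conformal calibration will be coarse", UserWarning)
        self.pos_label_ = self._resolve_pos_label()

        members: list[_ICPMember] = []
        invalid = 0
        for i in range(int(self.n_models)):
            seed = int(self.random_state) + i
            member = self._fit_member(X, y, seed)
            if member is None:
                invalid += 1
            else:
                members.append(member)
        self.n_invalid_members_ = invalid
        if invalid > 0.1 * int(self.n_models):
            raise ValueError(
                f"{invalid}/{self.n_models} conformal members invalid "
                "(calibration part lost a class); dataset too small or "
                "too imbalanced for the requested splits"
            )
        self.members_ = members
        return self

    def _resolve_pos_label(self):
        if self.pos_label in set(self.classes_.tolist()):
            return self.pos_label
        if set(self.classes_.tolist()) == {0, 1}:
            return 1
        raise ValueError(
            f"pos_label {self.pos_label!r} not among classes "
            f"{list(self.classes_)}"
        )

    def _fit_member(self, X, y, seed: int) -> _ICPMember | None:
        try:
            X_tr, X_cal, y_tr, y_cal = train_test_split(
                X, y, test_size=self.calibration_fraction,
                stratify=y, random_state=seed)
        except ValueError:
            return None
        if len(np.unique(y_cal)) < 2 or len(np.unique(y_tr)) < 2:
            return None
        forest = RandomForestClassifier(
            n_estimators=int(self.n_estimators), random_state=seed)
        forest.fit(X_tr, y_tr)
        proba = forest.predict_proba(X_cal)
        col = {c: j for j, c in enumerate(forest.classes_)}
        cal_scores = {}
        for c in self.classes_:
            mask = y_cal == c
            # nonconformity of a calibration compound under its TRUE class
            alpha = 1.0 - proba[mask, col[c]]
            cal_scores[c] = np.sort(alpha)
        return _ICPMember(forest, cal_scores, self.classes_, seed)

    # -------------------------------------------------------------- predict
    def predict_p(self, X) -> np.ndarray:
        """Median-aggregated Mondrian p-values.

        Returns an ``(n_samples, 2)`` array with columns ordered as
        ``classes_``.  With an even member count the median is the mean of
        the two central order statistics.
        """
        check_is_fitted(self, "members_")
        X = validate_data(self, X, dtype=float, reset=False)
        stack = np.stack([m.p_values(X) for m in self.members_], axis=0)
        return np.median(stack, axis=0)

    def p_value_pairs(self, X) -> list[PValuePair]:
        """Aggregated p-values as (p_active, p_inactive) pairs."""
        p = self.predict_p(X)
        ia = int(np.flatnonzero(self.classes_ == self.pos_label_)[0])
        ii = 1 - ia
        return [PValuePair(float(r[ia]), float(r[ii])) for r in p]

    def predict_region(self, X, significance_level: float | None = None
                       ) -> np.ndarray:
        """Four-region predictions at a significance level.

        Returns an object array over {active-label, inactive-label,
        ``"both"``, ``"empty"``}.
        """
        sl = self.significance_level if significance_level is None \
            else significance_level
        p = self.predict_p(X)
        include = p > sl
        n_inc = include.sum(axis=1)
        out = np.empty(len(p), dtype=object)
        out[n_inc == 2] = REGION_BOTH
        out[n_inc == 0] = REGION_EMPTY
        single = n_inc == 1
        out[single] = self.classes_[np.argmax(include[single], axis=1)]
        return out

    def predict(self, X) -> np.ndarray:
        """Region predictions at the estimator's ``significance_level``."""
        return self.predict_region(X, None)

    def decidability(self, X) -> np.ndarray:
        """p_active - p_inactive, in [-1, 1]; higher = more confidently
        active."""
        p = self.predict_p(X)
        ia = int(np.flatnonzero(self.classes_ == self.pos_label_)[0])
        return p[:, ia] - p[:, 1 - ia]

    def predict_records(
        self, X, compound_ids: Sequence[str] | None = None,
        significance_level: float | None = None,
    ) -> list[PredictionRecord]:
        """Full per-compound records (p-values, region, decidability)."""
        sl = self.significance_level if significance_level is None \
            else significance_level
        pairs = self.p_value_pairs(X)
        if compound_ids is None:
            compound_ids = [str(i) for i in range(len(pairs))]
        records = []
        for cid, pair in zip(compound_ids, pairs):
            region, dec = assign_region(pair.p_active, pair.p_inactive, sl)
            if region not in (REGION_BOTH, REGION_EMPTY):
                # map generic single-label back to this model's label set
                region = self.pos_label_ if region == "active" else \
                    next(c for c in self.classes_ if c != self.pos_label_)
                region = str(region)
            records.append(PredictionRecord(str(cid), pair, str(region),
                                            float(dec), float(sl)))
        return records

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.classifier_tags.poor_score = True
        return tags


def split_data(X, y, plan: SplitPlan = SplitPlan()):
    """Stratified validation split of an endpoint dataset.

    Returns ``(X_work, X_val, y_work, y_val)`` with the validation
    partition holding ``plan.validation_fraction`` of the compounds and
    class proportions preserved; deterministic given ``plan.base_seed``.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("dataset must contain both classes")
    for c, n in zip(classes, counts):
        if n < 5:
            warnings.warn(f"class {c!r} has only {n} compounds", UserWarning)
    return train_test_split(
        X, y, test_size=plan.validation_fraction,
        stratify=y if plan.stratified else None,
        random_state=plan.base_seed)


def fit_aggregated(
    X, y, plan: SplitPlan = SplitPlan(), n_models: int = 50,
    n_estimators: int = 300, pos_label="active",
):
    """Split off a validation partition and fit the aggregated model.

    Returns ``(model, X_val, y_val)``; the validation partition is never
    seen by any member.  Member seeds are ``plan.base_seed + index``.
    """
    X_work, X_val, y_work, y_val = split_data(X, y, plan)
    model = AggregatedConformalClassifier(
        n_models=n_models, n_estimators=n_estimators,
        calibration_fraction=plan.calibration_fraction,
        pos_label=pos_label, random_state=plan.base_seed)
    model.fit(X_work, y_work)
    return model, X_val, y_val
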