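"""Imbalance-aware cross-validation protocol for ideation classification.

The cohort's non-ideation subjects (healthy controls HC plus depressed
non-ideation NS, 112 at reference scale) outnumber ideation subjects (SI,
41) by 2.73:1.  To blunt that imbalance the protocol splits the non-ideation
subjects into two stratified halves (29 HC + 27 NS each), concatenates each
half with all SI subjects, and runs a stratified 4:1 train/test split
followed by 5-fold cross-validation on the training portion (an overall
4:1:1 train/validation/test proportion).  The whole scheme is repeated for
10 random states and the per-iteration metrics are averaged; the single
iteration with the highest test AUC is reported separately.

Classifiers: extreme gradient boosting (max_depth 5, 1000 estimators,
optional ``scale_pos_weight``) and logistic regression at library defaults.
Metrics: accuracy, sensitivity, specificity at a 0.5 probability threshold,
and the threshold-free AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "SplitPlan",
    "ClassifierSpec",
    "BinaryMetrics",
    "MetricsReport",
    "split_nonideation_halves",
    "imbalance_ratio",
    "make_split_plan",
    "compute_binary_metrics",
    "fit_and_evaluate",
    "aggregate_iterations",
    "run_iterations",
]

METRIC_NAMES = ("ACC", "SEN", "SPE", "AUC")


# ---------------------------------------------------------------------------
# splitting


def split_nonideation_halves(subjects: Sequence[tuple[str, str]], seed: int):
    """Randomly split (id, group) pairs into two halves, stratified by group.

    Only non-ideation groups (HC, NS) are legal input.  With an odd group
    count the surplus subject goes to half 1.  Each half is later
    concatenated with all SI subjects to form one classification task.
    """
    subjects = list(subjects)
    if not subjects:
        raise ValueError("subjects must be non-empty")
    groups = {g for _, g in subjects}
    if not groups <= {"HC", "NS"}:
        raise ValueError(f"only HC/NS subjects may be halved, got groups {sorted(groups)}")
    rng = np.random.default_rng(seed)
    half1, half2 = [], []
    for group in sorted(groups):
        members = [s for s in subjects if s[1] == group]
        order = rng.permutation(len(members))
        cut = (len(members) + 1) // 2  # surplus to half 1
        half1 += [members[i] for i in order[:cut]]
        half2 += [members[i] for i in order[cut:]]
    return half1, half2


def imbalance_ratio(labels: Sequence[int]) -> float:
    """Negative:positive count ratio (the ``scale_pos_weight`` convention)."""
    y = np.asarray(labels).astype(int)
    pos = int((y == 1).sum())
    if pos == 0:
        raise ValueError("imbalance ratio undefined without positive labels")
    return (y.size - pos) / pos


@dataclass(frozen=True)
class SplitPlan:
    """Stratified 4:1 train/test indices plus a 5-fold partition of train."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: tuple[np.ndarray, ...]  # validation indices, absolute
    random_state: int
    half_id: int = 1

    def __post_init__(self) -> None:
        all_idx = np.sort(np.concatenate([self.train_idx, self.test_idx]))
        if np.unique(all_idx).size != all_idx.size:
            raise ValueError("train and test partitions must be disjoint")
        fold_union = np.sort(np.concatenate(self.folds))
        if not np.array_equal(fold_union, np.sort(self.train_idx)):
            raise ValueError("folds must partition the training set")


def make_split_plan(
    labels: Sequence[int],
    random_state: int,
    n_folds: int = 5,
    half_id: int = 1,
) -> SplitPlan:
    """Stratified 1/(n_folds) test holdout, then stratified n-fold CV on the
    rest."""
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    idx = np.arange(y.size)
    train_idx, test_idx = train_test_split(
        idx, test_size=1.0 / n_folds, stratify=y, random_state=random_state
    )
    for cls in classes:
        n_cls = int((y[train_idx] == cls).sum())
        if n_cls < n_folds:
            raise ValueError(
                f"class {cls} has only {n_cls} training members (< {n_folds} folds)"
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    folds = tuple(train_idx[val] for _, val in skf.split(train_idx, y[train_idx]))
    return SplitPlan(
        train_idx=np.sort(train_idx),
        test_idx=np.sort(test_idx),
        folds=folds,
        random_state=random_state,
        half_id=half_id,
    )


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class BinaryMetrics:
    acc: float
    sen: float
    spe: float
    auc: float
    roc: tuple[np.ndarray, np.ndarray] | None = None  # (fpr, tpr)

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "SEN": self.sen, "SPE": self.spe, "AUC": self.auc}


def compute_binary_metrics(
    truth: Sequence[int],
    scores: Sequence[float],
    threshold: float = 0.5,
) -> BinaryMetrics:
    """Accuracy/sensitivity/specificity at ``threshold`` plus threshold-free
    AUC and the ROC threshold sweep."""
    y = np.asarray(truth).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("truth and scores must have equal length")
    if np.unique(y).size < 2:
        raise ValueError("AUC undefined for single-class truth")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return BinaryMetrics(
        acc=(tp + tn) / y.size,
        sen=tp / (tp + fn),
        spe=tn / (tn + fp),
        auc=auc,
        roc=(fpr, tpr),
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """Which model to fit and with what settings.

    ``kind`` is "xgb" (gradient-boosted trees; max_depth 5, 1000 estimators
    by default, remaining settings at library defaults) or "lr" (logistic
    regression entirely at library defaults).  ``scale_pos_weight`` weights
    positive examples in the tree model; setting it to the negative:positive
    ratio is the conventional imbalance correction.
    """

    kind: str = "xgb"
    max_depth: int = 5
    n_estimators: int = 1000
    scale_pos_weight: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("xgb", "lr"):
            raise ValueError("kind must be 'xgb' or 'lr'")
        if self.max_depth < 1 or self.n_estimators < 1:
            raise ValueError("max_depth and n_estimators must be >= 1")

    def build(self, random_state: int = 0):
        if self.kind == "xgb":
            from xgboost import XGBClassifier

            kwargs = {}
            if self.scale_pos_weight is not None:
                kwargs["scale_pos_weight"] = self.scale_pos_weight
            return XGBClassifier(
                max_depth=self.max_depth,
                n_estimators=self.n_estimators,
                random_state=random_state,
                n_jobs=1,
                **kwargs,
            )
        return LogisticRegression(random_state=random_state)


@dataclass(frozen=True)
class MetricsReport:
    """Cross-validation and test metrics for one iteration of one task."""

    cv: BinaryMetrics
    test: BinaryMetrics
    labels: dict = field(default_factory=dict)  # model/index_type/half_id/random_state
    params: dict = field(default_factory=dict)

    def row(self) -> dict:
        out = dict(self.labels)
        out.update({f"CV_{k}": v for k, v in self.cv.as_dict().items()})
        out.update({f"Test_{k}": v for k, v in self.test.as_dict().items()})
        return out


def _fit(est, X, y):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def fit_and_evaluate(
    features: np.ndarray,
    labels: Sequence[int],
    plan: SplitPlan,
    spec: ClassifierSpec,
    threshold: float = 0.5,
    extra_labels: dict | None = None,
) -> MetricsReport:
    """Run one iteration: 5-fold CV on the training portion (fold-mean
    metrics), then refit on the full training set and score the held-out
    test partition."""
    X = np.asarray(features)
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("feature rows must match label count")
    fold_metrics = []
    train_set = set(plan.train_idx.tolist())
    for val_idx in plan.folds:
        tr_idx = np.array(sorted(train_set - set(val_idx.tolist())))
        if np.unique(y[val_idx]).size < 2 or np.unique(y[tr_idx]).size < 2:
            raise ValueError("degenerate single-class fold")
        est = _fit(spec.build(plan.random_state), X[tr_idx], y[tr_idx])
        scores = est.predict_proba(X[val_idx])[:, 1]
        fold_metrics.append(compute_binary_metrics(y[val_idx], scores, threshold))
    cv = BinaryMetrics(
        acc=float(np.mean([m.acc for m in fold_metrics])),
        sen=float(np.mean([m.sen for m in fold_metrics])),
        spe=float(np.mean([m.spe for m in fold_metrics])),
        auc=float(np.mean([m.auc for m in fold_metrics])),
    )
    est = _fit(spec.build(plan.random_state), X[plan.train_idx], y[plan.train_idx])
    test_scores = est.predict_proba(X[plan.test_idx])[:, 1]
    test = compute_binary_metrics(y[plan.test_idx], test_scores, threshold)
    labels_out = {
        "model": spec.kind,
        "half_id": plan.half_id,
        "random_state": plan.random_state,
    }
    if extra_labels:
        labels_out.update(extra_labels)
    params = {"kind": spec.kind}
    if spec.kind == "xgb":
        params.update(
            max_depth=spec.max_depth,
            n_estimators=spec.n_estimators,
            scale_pos_weight=spec.scale_pos_weight,
        )
    return MetricsReport(cv=cv, test=test, labels=labels_out, params=params)


# ---------------------------------------------------------------------------
# iteration scheme


def run_iterations(
    features: np.ndarray,
    labels: Sequence[int],
    spec: ClassifierSpec,
    random_states: Iterable[int] = range(10),
    half_id: int = 1,
    extra_labels: dict | None = None,
) -> list[MetricsReport]:
    """Repeat the 4:1:1 split + CV + test evaluation for each random state."""
    reports = []
    for rs in random_states:
        plan = make_split_plan(labels, random_state=rs, half_id=half_id)
        reports.append(
            fit_and_evaluate(features, labels, plan, spec, extra_labels=extra_labels)
        )
    return reports


def aggregate_iterations(
    reports: Sequence[MetricsReport],
) -> tuple[MetricsReport, MetricsReport]:
    """Arithmetic mean across iterations, and the iteration with the highest
    test AUC (ties broken by the lowest random state)."""
    if not reports:
        raise ValueError("need at least one report")

    def mean_metrics(pick) -> BinaryMetrics:
        return BinaryMetrics(
            acc=float(np.mean([pick(r).acc for r in reports])),
            sen=float(np.mean([pick(r).sen for r in reports])),
            spe=float(np.mean([pick(r).spe for r in reports])),
            auc=float(np.mean([pick(r).auc for r in reports])),
        )

    labels = {k: v for k, v in reports[0].labels.items() if k != "random_state"}
    averaged = MetricsReport(
        cv=mean_metrics(lambda r: r.cv),
        test=mean_metrics(lambda r: r.test),
        labels=labels,
        params=dict(reports[0].params),
    )
    best = min(
        reports,
        key=lambda r: (-r.test.auc, r.labels.get("random_state", 0)),
    )
    return averaged, best
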