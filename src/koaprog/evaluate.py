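"""Model evaluation: patient-level cross-validation, one-vs-rest ROC/AUC,
permutation importance, and classical baseline comparators.

Folds are assigned at the *patient* level (all visits of a patient share
a fold) and stratified by the patient's final KL grade, so evaluation
never sees a patient present in training.  Multi-class performance is
reported as one ROC curve and AUC per KL grade (one-vs-rest), with the
AUC computed as the Mann-Whitney statistic (ties count one half).
"Mean decrease in accuracy" importance permutes one feature column at a
time and measures the drop in accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .cohort import Cohort


class UndefinedAUCError(ValueError):
    pass


# ---------------------------------------------------------------------------
# folds


@dataclass
class CVPlan:
    """Patient-level fold assignment."""

    assignment: dict[str, int]  # patient_id -> fold
    k: int
    seed: int

    def fold_of(self, pid: str) -> int:
        return self.assignment[pid]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for f in self.assignment.values():
            sizes[f] += 1
        return sizes

    def split(self, cohort: Cohort, fold: int) -> tuple[Cohort, Cohort]:
        df = cohort.data
        in_fold = df["patient_id"].map(self.assignment) == fold
        train = Cohort(df[~in_fold].reset_index(drop=True), dict(cohort.schema))
        test = Cohort(df[in_fold].reset_index(drop=True), dict(cohort.schema))
        return train, test


def make_folds(cohort: Cohort, k: int = 10, seed: int = 0) -> CVPlan:
    """Stratified (by final KL grade) patient-level fold assignment.

    Patients are shuffled within each stratum and dealt round-robin
    with a running counter across strata, so overall fold sizes differ
    by at most one.  A stratum with fewer than ``k`` patients cannot be
    represented in every fold; a warning is emitted and its patients
    are simply dealt into the rotation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    df = cohort.data.sort_values(["patient_id", "visit"], kind="stable")
    final_kl = df.groupby("patient_id", sort=True)["kl"].last()
    if cohort.n_patients < k:
        raise ValueError(f"need at least k={k} patients, have {cohort.n_patients}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 19]))
    assignment: dict[str, int] = {}
    counter = 0
    for grade in sorted(final_kl.dropna().unique()) + (
        [np.nan] if final_kl.isna().any() else []
    ):
        if np.isnan(grade) if isinstance(grade, float) else False:
            members = final_kl[final_kl.isna()].index.to_numpy()
        else:
            members = final_kl[final_kl == grade].index.to_numpy()
        if len(members) < k:
            warnings.warn(
                f"stratum KL={grade} has {len(members)} (<k) patients; "
                "falling back to unstratified assignment for it",
                stacklevel=2,
            )
        members = members[rng.permutation(len(members))]
        for pid in members:
            assignment[pid] = counter % k
            counter += 1
    return CVPlan(assignment, k, seed)


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    positive_class: object
    n_pos: int
    n_neg: int

    def __post_init__(self):
        if not (0 <= self.auc <= 1):
            raise ValueError("AUC outside [0, 1]")


def roc_auc(scores: np.ndarray, labels: np.ndarray, positive_class) -> ROCCurve:
    """One-vs-rest ROC curve and Mann-Whitney AUC.

    The AUC equals the number of (positive, negative) pairs in which
    the positive sample scores higher, ties counting one half, divided
    by n_pos * n_neg — i.e. the rank-sum statistic.  The curve itself
    sweeps thresholds over the unique scores (ties collapse to single
    points; the trapezoid through them reproduces the same AUC).
    """
    scores = np.asarray(scores, float)
    y = (np.asarray(labels) == positive_class).astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError(
            f"both classes required after binarization on {positive_class!r}"
        )
    ranks = rankdata(scores)  # average ranks handle ties as half-wins
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    ss = scores[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    last_of_tie = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tp[last_of_tie] / n_pos]
    fpr = np.r_[0.0, fp[last_of_tie] / n_neg]
    return ROCCurve(fpr, tpr, float(auc), positive_class, n_pos, n_neg)


def roc_auc_per_class(prob_frame: pd.DataFrame, labels: np.ndarray) -> dict:
    """One curve per class present in ``labels``; probability columns
    are named ``p_kl{g}``."""
    out = {}
    for grade in sorted(np.unique(labels)):
        col = f"p_kl{int(grade)}"
        if col not in prob_frame.columns:
            continue
        try:
            out[int(grade)] = roc_auc(prob_frame[col].to_numpy(), labels, grade)
        except UndefinedAUCError:
            continue
    return out


# ---------------------------------------------------------------------------
# permutation importance


def permutation_importance(
    model,
    cohort: Cohort,
    truth: pd.Series,
    metric: str = "accuracy",
    n_repeats: int = 5,
    seed: int = 0,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Mean decrease in accuracy per feature.

    ``model`` must expose a predict contract: either a callable or an
    object with ``predict(cohort)`` returning a frame with
    ``patient_id`` and ``predicted_kl``.  For each feature the column
    is permuted (seeded, within the whole table) ``n_repeats`` times
    and the mean drop of the metric relative to intact data is
    reported, ranked descending.
    """
    if metric != "accuracy":
        raise ValueError("only the accuracy metric is supported")
    predict = model if callable(model) else model.predict
    features = features or cohort.covariates
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))

    def score(c: Cohort) -> float:
        pred = predict(c).set_index("patient_id")["predicted_kl"]
        aligned = truth.reindex(pred.index)
        return float((pred.to_numpy() == aligned.to_numpy()).mean())

    base = score(cohort)
    rows = []
    for feat in features:
        drops = []
        for _ in range(n_repeats):
            shuffled = cohort.copy()
            col = shuffled.data[feat].to_numpy().copy()
            shuffled.data[feat] = col[rng.permutation(len(col))]
            drops.append(base - score(shuffled))
        rows.append(
            {
                "feature": feat,
                "mean_decrease_accuracy": float(np.mean(drops)),
                "sd": float(np.std(drops, ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    out = pd.DataFrame(rows).sort_values(
        "mean_decrease_accuracy", ascending=False, kind="stable"
    )
    out.attrs["baseline_accuracy"] = base
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# baseline comparators


def _one_step_task(cohort: Cohort):
    """Features at the penultimate visit, label = final-visit KL: the
    flattened version of the one-step-ahead prediction task."""
    df = cohort.data.sort_values(["patient_id", "visit"], kind="stable")
    last = df.groupby("patient_id").tail(1).set_index("patient_id")
    penult = df.groupby("patient_id").nth(-2)
    penult = penult.set_index("patient_id") if "patient_id" in penult.columns else penult
    feats = cohort.covariates
    X = penult[feats]
    y = last["kl"].reindex(X.index)
    keep = ~(X.isna().any(axis=1) | y.isna())
    return X[keep], y[keep].astype(int)


def run_baselines(
    cohort: Cohort,
    plan: CVPlan,
    models: tuple[str, ...] = ("rf", "svm", "nb"),
    seed: int = 0,
) -> dict[str, dict[int, ROCCurve]]:
    """Cross-validated RF / SVM / naive-Bayes comparators.

    The comparators themselves are established scikit-learn estimators
    (they are reference baselines, not this package's contribution);
    fold orchestration and the ROC/AUC computation are this module's
    own.  Returns per-model, per-class ROC curves from out-of-fold
    probability scores.
    """
    X, y = _one_step_task(cohort)
    folds = np.array([plan.fold_of(p) for p in X.index])
    def _svc():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            return SVC(probability=True, random_state=seed)

    factories = {
        "rf": lambda: RandomForestClassifier(n_estimators=200, random_state=seed),
        "svm": _svc,
        "nb": lambda: GaussianNB(),
    }
    out: dict[str, dict[int, ROCCurve]] = {}
    for name in models:
        if name not in factories:
            raise ValueError(f"unknown baseline {name!r}")
        scores = np.zeros((len(y), 5))
        for f in range(plan.k):
            tr, te = folds != f, folds == f
            if te.sum() == 0:
                continue
            est = factories[name]()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                est.fit(X[tr].to_numpy(), y[tr].to_numpy())
            if hasattr(est, "predict_proba"):
                p = est.predict_proba(X[te].to_numpy())
            else:
                p = np.atleast_2d(est.decision_function(X[te].to_numpy()))
                if p.shape[0] == 1 and te.sum() > 1:
                    p = p.T
                if p.shape[1] == 1:  # binary decision function
                    p = np.column_stack([-p[:, 0], p[:, 0]])
            for j, cls in enumerate(est.classes_):
                scores[te, int(cls)] = p[:, j]
        prob_frame = pd.DataFrame({f"p_kl{g}": scores[:, g] for g in range(5)})
        out[name] = roc_auc_per_class(prob_frame, y.to_numpy())
    return out


def auc_table(curves: dict[str, dict[int, ROCCurve]]) -> pd.DataFrame:
    rows = [
        {"model": m, "kl_grade": g, "auc": c.auc, "n_pos": c.n_pos, "n_neg": c.n_neg}
        for m, per_class in curves.items()
        for g, c in per_class.items()
    ]
    return pd.DataFrame(rows)


def cross_validate(cohort: Cohort, plan: CVPlan, fit_fn, predict_fn) -> pd.DataFrame:
    """Generic patient-level CV loop: ``fit_fn(train_cohort)`` returns a
    fitted object, ``predict_fn(fitted, test_cohort)`` a frame with
    ``patient_id``, ``predicted_kl`` and ``p_kl*`` columns."""
    frames = []
    for f in range(plan.k):
        train, test = plan.split(cohort, f)
        fitted = fit_fn(train)
        pred = predict_fn(fitted, test)
        pred = pred.copy()
        pred["fold"] = f
        frames.append(pred)
    return pd.concat(frames, ignore_index=True)
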