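"""Linear SVM classification protocols and metrics.

Two small-sample evaluation protocols:

* **A1** — train a scalar-product-kernel (linear) SVM on syndrome vs SCD,
  replace the intercept with the one maximizing *training specificity*
  (targeting 100 %) subject to training sensitivity >= 50 %, report the
  training-set confusion ("vs SCD") and then apply the frozen hyperplane to
  syndrome vs everyone else ("vs all").
* **A2** — Monte Carlo cross-validation of syndrome vs pooled others:
  repeated stratified 70:30 splits (1000 runs by default), plain SVM per
  run, metrics aggregated as mean +- SD.

Accuracy is n/N pooled over both classes of the evaluated set; the decision
rule is positive iff the decision value is strictly greater than 0 (a tie
goes to the negative class, which favors specificity).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC

from .errors import (
    ConstraintInfeasibleError,
    DegenerateTrainingError,
    InsufficientDataError,
    InvalidParameterError,
)

log = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class ConfusionSummary:
    """Integer confusion counts with the rates they summarize.

    accuracy = (tp + tn) / (tp + fn + tn + fp) exactly; percentages are the
    same rates scaled by 100.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise InvalidParameterError("confusion counts must be non-negative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_pos if self.n_pos else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / self.n_neg if self.n_neg else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")

    def as_percent(self) -> dict:
        return {"sensitivity": 100.0 * self.sensitivity,
                "specificity": 100.0 * self.specificity,
                "accuracy": 100.0 * self.accuracy}

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionSummary":
        return confusion_metrics(y_true, y_pred)

    @classmethod
    def from_rates(cls, sensitivity_pct: float, specificity_pct: float,
                   n_pos: int, n_neg: int) -> "ConfusionSummary":
        """Reconstruct integer counts from printed percentage rates.

        tp = round(sens * n_pos), tn = round(spec * n_neg) with round half
        up — the arithmetic identity used to validate published accuracy
        cells against their printed sensitivity/specificity and group sizes.
        """
        if n_pos <= 0 or n_neg < 0:
            raise InvalidParameterError("n_pos must be positive, n_neg >= 0")
        tp = _round_half_up(sensitivity_pct / 100.0 * n_pos)
        tn = _round_half_up(specificity_pct / 100.0 * n_neg)
        return cls(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)


def confusion_metrics(y_true, y_pred) -> ConfusionSummary:
    """Confusion counts from boolean (or 0/1) label sequences."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.size == 0 or yt.shape != yp.shape:
        raise InvalidParameterError("label sequences must be equal-length and non-empty")
    for arr in (yt, yp):
        vals = np.unique(arr)
        if not np.all(np.isin(vals, [0, 1, True, False])):
            raise InvalidParameterError(f"labels must be binary, got {vals}")
    yt = yt.astype(bool)
    yp = yp.astype(bool)
    return ConfusionSummary(
        tp=int(np.sum(yt & yp)), fn=int(np.sum(yt & ~yp)),
        tn=int(np.sum(~yt & ~yp)), fp=int(np.sum(~yt & yp)))


@dataclass
class LinearModel:
    """Standardized-feature linear decision function d(x) = w . z(x) + b with
    z(x) = (x - center) / scale; positive class iff d(x) > 0."""

    weights: np.ndarray
    bias: float
    center: np.ndarray
    scale: np.ndarray
    feature_order: tuple[str, ...] = ()

    def decision_values(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = (X - self.center) / self.scale
        return z @ self.weights + self.bias

    def predict(self, X) -> np.ndarray:
        return self.decision_values(X) > 0.0

    def with_bias(self, bias: float) -> "LinearModel":
        return LinearModel(self.weights.copy(), float(bias), self.center.copy(),
                           self.scale.copy(), self.feature_order)


def train_linear_svm(X, y, regularization: float = 1.0,
                     feature_order: tuple[str, ...] = ()) -> LinearModel:
    """Soft-margin linear SVM on per-feature standardized inputs.

    The slack penalty weights the *mean* hinge loss (per-sample C is
    ``regularization / n_samples``), so the fitted hyperplane is invariant
    to duplicating the data set — the objective depends on the empirical
    distribution, not the sample count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise InvalidParameterError("X must be (n_samples, n_features) matching y")
    if not np.isfinite(X).all():
        raise InvalidParameterError("features contain missing values")
    if y.all() or (~y).all():
        raise DegenerateTrainingError("training requires both classes")
    if regularization <= 0:
        raise InvalidParameterError("regularization must be positive")
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    scale = np.where(sd > 0, sd, 1.0)
    z = (X - center) / scale
    svc = SVC(kernel="linear", C=regularization / X.shape[0])
    svc.fit(z, y.astype(int))
    return LinearModel(weights=svc.coef_[0].copy(), bias=float(svc.intercept_[0]),
                       center=center, scale=scale, feature_order=tuple(feature_order))


def tune_max_specificity(model: LinearModel, X, y, min_sensitivity: float = 0.5,
                         target_specificity: float = 1.0) -> LinearModel:
    """Replace the intercept by the one maximizing training specificity
    subject to training sensitivity >= ``min_sensitivity``.

    Candidate thresholds are the midpoints between consecutive sorted
    decision values (plus one below the minimum and one above the maximum),
    so the search is finite and brute-force verifiable. Ties in specificity
    are broken toward higher sensitivity. If the best feasible specificity
    falls short of ``target_specificity`` a
    :class:`~mmnds.errors.ConstraintInfeasibleError` is raised carrying the
    best attainable operating point.
    """
    y = np.asarray(y).astype(bool)
    d = model.decision_values(X)
    uniq = np.unique(d)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.array([])
    thresholds = np.concatenate([[uniq[0] - 1.0], mids, [uniq[-1] + 1.0]])
    best = None     # (spec, sens, threshold)
    for th in thresholds:
        pred = d > th
        cs = confusion_metrics(y, pred)
        if cs.sensitivity + 1e-12 < min_sensitivity:
            continue
        cand = (cs.specificity, cs.sensitivity, th)
        if best is None or cand[:2] > best[:2]:
            best = cand
    if best is None:
        # unreachable for min_sensitivity <= 1: the lowest threshold predicts
        # everything positive (sensitivity 1); kept for defensive clarity
        raise ConstraintInfeasibleError(
            f"no threshold attains sensitivity >= {min_sensitivity}", 0.0, 1.0,
            model.bias)
    spec, sens, th = best
    new_bias = model.bias - th
    if spec + 1e-12 < target_specificity:
        raise ConstraintInfeasibleError(
            f"best attainable specificity {spec:.3f} < target {target_specificity} "
            f"under sensitivity >= {min_sensitivity}", spec, sens, new_bias)
    return model.with_bias(new_bias)


@dataclass
class A1Result:
    entity: str
    model: LinearModel
    vs_scd: ConfusionSummary
    vs_all: ConfusionSummary
    achieved_training_specificity: float
    specificity_target_met: bool


def run_a1(entity: str, X, groups, feature_order: tuple[str, ...] = (),
           regularization: float = 1.0, min_sensitivity: float = 0.5,
           control_group: str = "SCD") -> A1Result:
    """Maximum-specificity hyperplane-transfer protocol.

    Train on entity vs SCD only; tune the intercept for maximum training
    specificity (sensitivity >= 50 %); ``vs_scd`` is the confusion of the
    tuned hyperplane on its own training set, ``vs_all`` applies the frozen
    hyperplane to entity (positives) vs all remaining subjects including SCD
    (negatives). When 100 % specificity is unreachable the best-effort
    operating point is used with a warning, mirroring reference cohorts
    where a few separations top out below 100 %.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    pos = groups == entity
    ctrl = groups == control_group
    if not pos.any() or not ctrl.any():
        raise InsufficientDataError(f"need both {entity} and {control_group} subjects")
    train_idx = pos | ctrl
    y_train = pos[train_idx]
    model = train_linear_svm(X[train_idx], y_train, regularization, feature_order)
    target_met = True
    try:
        model = tune_max_specificity(model, X[train_idx], y_train, min_sensitivity)
    except ConstraintInfeasibleError as err:
        log.warning("A1 %s: specificity target unreachable (best %.1f%% at "
                    "sensitivity %.1f%%); using best-effort hyperplane",
                    entity, 100 * err.best_specificity, 100 * err.best_sensitivity)
        model = model.with_bias(err.best_bias)
        target_met = False
    pred_train = model.predict(X[train_idx])
    vs_scd = confusion_metrics(y_train, pred_train)
    vs_all = confusion_metrics(pos, model.predict(X))
    return A1Result(entity=entity, model=model, vs_scd=vs_scd, vs_all=vs_all,
                    achieved_training_specificity=vs_scd.specificity,
                    specificity_target_met=target_met)


@dataclass
class A2Result:
    entity: str
    n_runs: int
    split_fraction: float
    per_run: list                       # (train, validation, summary) confusions
    aggregates: dict = field(default_factory=dict)   # split -> metric -> (mean, sd)
    n_skipped: int = 0


def _aggregate(per_run, which: int) -> dict:
    out = {}
    for metric in ("sensitivity", "specificity", "accuracy"):
        vals = np.array([100.0 * getattr(runs[which], metric) for runs in per_run])
        vals = vals[np.isfinite(vals)]
        out[metric] = (float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0)
    return out


def run_a2(entity: str, X, groups, n_runs: int = 1000, split_fraction: float = 0.7,
           seed: int = 0, regularization: float = 1.0) -> A2Result:
    """Monte Carlo cross-validation: entity vs pooled others, stratified
    70:30 splits, plain (untuned) SVM per run.

    Per run three confusions are recorded: training set, validation set, and
    the pooled "summary" over all subjects of the run (train and validation
    predictions combined). Aggregates are mean +- SD over runs, in percent.
    """
    if not 0 < split_fraction <= 1:
        raise InvalidParameterError("split_fraction must be in (0, 1]")
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    y = groups == entity
    idx_pos = np.nonzero(y)[0]
    idx_neg = np.nonzero(~y)[0]
    n_tr_pos = _round_half_up(split_fraction * idx_pos.size)
    n_tr_neg = _round_half_up(split_fraction * idx_neg.size)
    if min(idx_pos.size, idx_neg.size) < 2:
        raise InsufficientDataError("need >=2 subjects per class")
    ss = np.random.SeedSequence(seed)
    per_run = []
    n_skipped = 0
    for child in ss.spawn(n_runs):
        rng = np.random.default_rng(child)
        tr = np.concatenate([rng.permutation(idx_pos)[:n_tr_pos],
                             rng.permutation(idx_neg)[:n_tr_neg]])
        tr_mask = np.zeros(y.size, dtype=bool)
        tr_mask[tr] = True
        va_mask = ~tr_mask
        y_tr, y_va = y[tr_mask], y[va_mask]
        if (split_fraction < 1.0
                and (y_tr.all() or not y_tr.any() or y_va.all() or not y_va.any())):
            n_skipped += 1
            continue
        model = train_linear_svm(X[tr_mask], y_tr, regularization)
        pred_tr = model.predict(X[tr_mask])
        train_cs = confusion_metrics(y_tr, pred_tr)
        if split_fraction == 1.0:
            # degenerate split: validation empty, summary equals training
            per_run.append((train_cs, train_cs, train_cs))
            continue
        val_cs = confusion_metrics(y_va, model.predict(X[va_mask]))
        pooled_pred = np.empty(y.size, dtype=bool)
        pooled_pred[tr_mask] = pred_tr
        pooled_pred[va_mask] = model.predict(X[va_mask])
        summary_cs = confusion_metrics(y, pooled_pred)
        per_run.append((train_cs, val_cs, summary_cs))
    if n_skipped > 0.05 * n_runs:
        raise InsufficientDataError(
            f"{n_skipped}/{n_runs} Monte Carlo runs emptied a class after splitting")
    if n_skipped:
        log.info("run_a2 %s: skipped %d/%d runs", entity, n_skipped, n_runs)
    result = A2Result(entity=entity, n_runs=n_runs, split_fraction=split_fraction,
                      per_run=per_run, n_skipped=n_skipped)
    for which, name in enumerate(("training", "validation", "summary")):
        result.aggregates[name] = _aggregate(per_run, which)
    return result


def composite_categorization(correct_flags) -> float:
    """Composite percentage C = 100 * N_TRUE / (N_TRUE + N_FALSE)."""
    flags = np.asarray(correct_flags).astype(bool)
    if flags.size == 0:
        raise InvalidParameterError("need at least one subject")
    return 100.0 * float(flags.mean())


def categorize_subjects(a1_results: dict, X, groups,
                        feature_columns: dict) -> np.ndarray:
    """Model-based categorization correctness flags (one per subject).

    Each subject is offered to every entity's A1 hyperplane (on that
    entity's feature subset); a subject is correctly categorized when their
    clinical label is among the accepting models, or, for SCD, when no model
    accepts them. Ties between accepting models are informational only —
    correctness asks for membership, with margins available for tie-breaks.
    """
    groups = np.asarray(groups)
    n = groups.size
    accepted = {e: a1_results[e].model.predict(X[cols])
                for e, cols in feature_columns.items()}
    correct = np.zeros(n, dtype=bool)
    for i in range(n):
        accepting = [e for e in a1_results if accepted[e][i]]
        if groups[i] == "SCD":
            correct[i] = not accepting
        else:
            correct[i] = groups[i] in accepting
    return correct


def roc_curve_auc(decision_values, labels):
    """ROC points and AUC via the rank (Mann-Whitney) formula, ties counted half.

    Returns (points, auc) where points is an (n+1, 2) array of (FPR, TPR)
    swept from the highest threshold down.
    """
    d = np.asarray(decision_values, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise InsufficientDataError("ROC needs both classes")
    ranks = rankdata(d)                      # average ranks handle ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    order = np.argsort(-d, kind="stable")
    tps = np.concatenate([[0], np.cumsum(y[order])])
    fps = np.concatenate([[0], np.cumsum(~y[order])])
    # collapse runs of tied scores to single curve points
    keep = np.concatenate([[True], np.diff(d[order]) != 0, [True]])
    points = np.column_stack([fps[keep] / n_neg, tps[keep] / n_pos])
    return points, float(auc)
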