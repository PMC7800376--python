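"""Landing prediction, trial labeling and the logistic decision model.

The analysis centres on the forepaw in swing at whisker contact.  A
per-session linear model (step length vs wheel speed, fit on control steps)
predicts where that paw would land if the step were not modified; the signed
distance of that predicted landing from the obstacle is ``dpred`` (negative =
in front).  Trials are labeled ``shortened`` or ``lengthened`` by whether the
paw landed short of or beyond its predicted landing position; steps that land
in front of the obstacle within +-2.5 mm of the prediction are ``unmodified``
and excluded from model fitting, while steps over the obstacle are always
considered modified.  A class-weighted logistic model with 15-fold stratified
cross-validation predicts the label from eight features measured at contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier

from .config import DECISION_FEATURES
from .errors import AnalysisError

__all__ = [
    "LandingModel", "DecisionModelResult", "SelectionPath", "MatchedTrialSet",
    "fit_landing_model", "predict_landing_distance", "label_modification",
    "assemble_decision_dataset", "fit_decision_glm", "forward_select",
    "shuffled_baseline", "conditional_landing_heatmap", "match_trials",
    "fit_contact_model", "impute_contact_position", "impute_contact_frame",
    "fit_decision_mlp",
]

UNMODIFIED_BAND = 2.5  # mm around the predicted landing position


@dataclass
class LandingModel:
    """Per-session, per-paw linear model: step length = a + b * wheel speed."""

    intercept: float          # mm
    slope: float              # mm per (m/s)
    mae: float                # mm, in-sample by default
    n_steps: int
    session: object = None
    paw: str = ""

    def predict_length(self, speed):
        return self.intercept + self.slope * np.asarray(speed, float)


def fit_landing_model(steps: pd.DataFrame, session=None, paw: str = "",
                      min_steps: int = 10, holdout: bool = False,
                      seed: int = 0) -> LandingModel:
    """Ordinary least squares of step length on mean wheel speed.

    ``steps`` needs ``speed`` and ``length`` columns (control steps).  The
    MAE equals the mean absolute landing-position error because lift-off
    positions are shared between prediction and observation.  ``holdout``
    reports a 5-fold cross-validated MAE instead of the in-sample one.
    """
    if len(steps) < max(2, min_steps):
        raise AnalysisError(
            f"session {session!r} paw {paw!r}: {len(steps)} control steps, "
            f"need >= {min_steps}")
    v = steps["speed"].to_numpy(float)
    length = steps["length"].to_numpy(float)
    slope, intercept = np.polyfit(v, length, 1)
    if holdout:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(v))
        errs = []
        for part in np.array_split(idx, 5):
            train = np.setdiff1d(idx, part)
            s, a = np.polyfit(v[train], length[train], 1)
            errs.append(np.abs(a + s * v[part] - length[part]))
        mae = float(np.mean(np.concatenate(errs)))
    else:
        mae = float(np.mean(np.abs(intercept + slope * v - length)))
    return LandingModel(intercept=float(intercept), slope=float(slope),
                        mae=mae, n_steps=len(steps), session=session, paw=paw)


def predict_landing_distance(lift_off_x, wheel_speed, obstacle_x,
                             model: LandingModel):
    """Signed predicted landing distance relative to the obstacle (mm).

    ``dpred = (lift_off_x + a + b*speed) - obstacle_x``; negative values mean
    the paw would land in front of the obstacle.
    """
    return (np.asarray(lift_off_x, float) + model.predict_length(wheel_speed)
            - np.asarray(obstacle_x, float))


def label_modification(predicted, actual):
    """Label trials from predicted and actual landing distances (rel. obstacle).

    ``unmodified`` requires landing in front of the obstacle *and* within
    +-2.5 mm of the prediction; steps over the obstacle are modified
    regardless of landing position.  Otherwise the sign of
    ``actual - predicted`` decides shortened vs lengthened.
    """
    predicted = np.atleast_1d(np.asarray(predicted, float))
    actual = np.atleast_1d(np.asarray(actual, float))
    diff = actual - predicted
    in_front = actual < 0
    labels = np.where(diff < 0, "shortened", "lengthened").astype(object)
    labels[in_front & (np.abs(diff) <= UNMODIFIED_BAND)] = "unmodified"
    return labels if labels.size > 1 else labels[0]


def assemble_decision_dataset(trials: pd.DataFrame,
                              control_steps: pd.DataFrame,
                              min_control_steps: int = 10) -> pd.DataFrame:
    """Attach model-predicted landing distances and labels to cohort trials.

    ``trials``/``control_steps`` are the outputs of
    :func:`obstride.sim.generate_decision_cohort` (or equivalently shaped
    tables extracted from sessions).  Per (mouse, session) a landing model is
    fit on the control steps; each trial's ``dpred`` combines it with the
    trial's lift-off position, wheel speed and obstacle position.  Trials are
    labeled and exclusion reasons recorded in ``exclusion``.
    """
    out = trials.copy()
    out["dpred"] = np.nan
    for (mouse, session), grp in trials.groupby(["mouse", "session"]):
        cs = control_steps[(control_steps["mouse"] == mouse)
                           & (control_steps["session"] == session)]
        model = fit_landing_model(
            cs.rename(columns={"wheel_velocity": "speed"}),
            session=(mouse, session), min_steps=min_control_steps)
        dpred = predict_landing_distance(
            grp["lift_off_x"], grp["wheel_velocity"], grp["obstacle_x"], model)
        out.loc[grp.index, "dpred"] = dpred
    ok = out["exclusion"] == ""
    out["label"] = ""
    out.loc[ok, "label"] = label_modification(
        out.loc[ok, "dpred"].to_numpy(), out.loc[ok, "actual_landing"].to_numpy())
    out.loc[out["label"] == "unmodified", "exclusion"] = "UNMODIFIED"
    return out


@dataclass
class DecisionModelResult:
    features: tuple
    weights: np.ndarray        # per feature, standardized scale
    intercept: float
    fold_accuracies: np.ndarray
    mean_accuracy: float
    class_counts: dict
    class_weights: dict


def _prepare_xy(dataset: pd.DataFrame, features, standardize=True):
    X = dataset.loc[:, list(features)].to_numpy(float)
    y = (dataset["label"] == "lengthened").to_numpy(int)
    if standardize:
        mu, sd = X.mean(0), X.std(0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    return X, y


def fit_decision_glm(dataset: pd.DataFrame, features=DECISION_FEATURES,
                     folds: int = 15, seed: int = 0, standardize: bool = True,
                     C: float = 1e4) -> DecisionModelResult:
    """Class-weighted logistic model with stratified, seeded k-fold CV.

    ``dataset`` holds modified trials only (labels ``shortened`` /
    ``lengthened``).  Accuracy is the unweighted mean of the per-fold
    accuracies; the final weights come from a fit on all trials.  ``C`` is
    large by default (effectively unregularized maximum likelihood).
    """
    labs = set(dataset["label"])
    if not labs <= {"shortened", "lengthened"}:
        raise AnalysisError(f"unexpected labels in dataset: {labs}")
    if len(labs) < 2:
        raise AnalysisError("dataset contains a single class")
    counts = dataset["label"].value_counts().to_dict()
    if min(counts.values()) < folds:
        raise AnalysisError(
            f"need >= {folds} trials per class for {folds}-fold CV; "
            f"have {counts}")
    X, y = _prepare_xy(dataset, features, standardize)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in cv.split(X, y):
        clf = LogisticRegression(C=C, class_weight="balanced", max_iter=5000)
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    final = LogisticRegression(C=C, class_weight="balanced", max_iter=5000)
    final.fit(X, y)
    n = len(y)
    class_w = {lab: n / (2.0 * cnt) for lab, cnt in counts.items()}
    return DecisionModelResult(
        features=tuple(features), weights=final.coef_[0].copy(),
        intercept=float(final.intercept_[0]),
        fold_accuracies=np.asarray(accs),
        mean_accuracy=float(np.mean(accs)),
        class_counts=counts, class_weights=class_w)


@dataclass
class SelectionPath:
    features: list            # in order of inclusion
    accuracies: list          # mean across mice after each addition


def forward_select(datasets: list, seed: int = 0,
                   features=DECISION_FEATURES, folds: int = 15,
                   max_features: int | None = None) -> SelectionPath:
    """Greedy forward feature selection over per-mouse datasets.

    At each round, each remaining feature is added to the current set, models
    are fit per mouse, and the feature with the greatest mean accuracy across
    mice is kept.  Ties break by the canonical feature order.  Returns the
    full inclusion path (or the first ``max_features`` rounds).
    """
    chosen: list[str] = []
    path_acc: list[float] = []
    remaining = list(features)
    while remaining and (max_features is None or len(chosen) < max_features):
        best_feat, best_acc = None, -np.inf
        for f in remaining:           # canonical order -> deterministic ties
            trial_feats = chosen + [f]
            accs = [fit_decision_glm(d, trial_feats, folds=folds,
                                     seed=seed).mean_accuracy
                    for d in datasets]
            acc = float(np.mean(accs))
            if acc > best_acc:
                best_feat, best_acc = f, acc
        chosen.append(best_feat)
        remaining.remove(best_feat)
        path_acc.append(best_acc)
    return SelectionPath(features=chosen, accuracies=path_acc)


def shuffled_baseline(dataset: pd.DataFrame, n_shuffles: int, seed: int = 0,
                      features=DECISION_FEATURES, folds: int = 15
                      ) -> np.ndarray:
    """Accuracy distribution of the full model on permuted labels."""
    if n_shuffles < 1:
        raise AnalysisError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_shuffles):
        shuffled = dataset.copy()
        shuffled["label"] = rng.permutation(dataset["label"].to_numpy())
        if shuffled["label"].value_counts().min() < folds:
            continue
        out.append(fit_decision_glm(shuffled, features, folds=folds,
                                    seed=seed + s).mean_accuracy)
    return np.asarray(out)


def conditional_landing_heatmap(predicted, actual, bin_edges) -> pd.DataFrame:
    """2D histogram of actual landing distance conditioned on predicted.

    Columns are predicted-landing bins and are normalized to sum to one
    (all-zero where empty); rows are actual-landing bins.
    """
    edges = np.asarray(bin_edges, float)
    if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
        raise AnalysisError("bin edges must be strictly increasing")
    hist, _, _ = np.histogram2d(np.asarray(actual, float),
                                np.asarray(predicted, float),
                                bins=[edges, edges])
    col_sum = hist.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(col_sum > 0, hist / col_sum, 0.0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame(norm, index=centers, columns=centers)


@dataclass
class MatchedTrialSet:
    pairs: list               # (control index, manipulated index)
    features: tuple
    fraction: float
    distances: np.ndarray = field(default_factory=lambda: np.empty(0))


def match_trials(control: pd.DataFrame, manipulated: pd.DataFrame,
                 features=("wheel_velocity", "body_angle", "tail_height"),
                 fraction: float = 0.20, method: str = "greedy"
                 ) -> MatchedTrialSet:
    """Pair manipulated with control trials matched on locomotor state.

    Features are z-scored over the pooled trials; candidate pairs are scored
    by Euclidean distance and selected greedily (lowest distance first, each
    trial used once) until ``floor(fraction * min(n_control, n_manip))``
    pairs are retained.  ``method="optimal"`` solves the assignment problem
    instead and keeps the lowest-distance pairs.
    """
    if len(control) == 0 or len(manipulated) == 0:
        raise AnalysisError("both conditions must contain trials")
    feats = list(features)
    pooled = pd.concat([control[feats], manipulated[feats]])
    mu, sd = pooled.mean(), pooled.std(ddof=0).replace(0, 1.0)
    zc = ((control[feats] - mu) / sd).to_numpy()
    zm = ((manipulated[feats] - mu) / sd).to_numpy()
    dist = np.linalg.norm(zc[:, None, :] - zm[None, :, :], axis=2)
    n_keep = int(np.floor(fraction * min(len(control), len(manipulated))))
    n_keep = max(n_keep, 1)
    pairs: list[tuple[int, int]] = []
    if method == "optimal":
        ri, ci = linear_sum_assignment(dist)
        order = np.argsort(dist[ri, ci], kind="stable")
        sel = order[:n_keep]
        pairs = [(int(control.index[ri[i]]), int(manipulated.index[ci[i]]))
                 for i in sel]
        dists = dist[ri[sel], ci[sel]]
    else:
        flat = np.argsort(dist, axis=None, kind="stable")
        used_c, used_m = set(), set()
        dists_l = []
        for f in flat:
            i, j = divmod(int(f), dist.shape[1])
            if i in used_c or j in used_m:
                continue
            used_c.add(i)
            used_m.add(j)
            pairs.append((int(control.index[i]), int(manipulated.index[j])))
            dists_l.append(dist[i, j])
            if len(pairs) == n_keep:
                break
        dists = np.asarray(dists_l)
    return MatchedTrialSet(pairs=pairs, features=tuple(feats),
                           fraction=fraction, distances=np.asarray(dists))


# --- whiskerless sessions: imputing the moment of contact ------------------

def fit_contact_model(speeds, contact_positions) -> tuple[float, float]:
    """Linear model of whisker-contact position (mm rel. nose) vs speed."""
    speeds = np.asarray(speeds, float)
    pos = np.asarray(contact_positions, float)
    if speeds.size < 2:
        raise AnalysisError("need >= 2 whisker-present trials to fit")
    slope, intercept = np.polyfit(speeds, pos, 1)
    return float(intercept), float(slope)


def impute_contact_position(speed, model: tuple[float, float],
                            training_range: tuple[float, float] | None = None):
    """Predicted contact position for a whiskerless trial; warns outside the
    training speed range."""
    intercept, slope = model
    speed = np.asarray(speed, float)
    if training_range is not None:
        lo, hi = training_range
        if np.any((speed < lo) | (speed > hi)):
            import warnings
            warnings.warn("speed outside the contact-model training range; "
                          "extrapolating", stacklevel=2)
    return intercept + slope * speed


def impute_contact_frame(displacement: np.ndarray, obstacle_x_world: float,
                         contact_position: float) -> int:
    """Frame at which the obstacle reaches the imputed position ahead of the
    nose (nose world x = wheel displacement)."""
    target = obstacle_x_world - contact_position
    idx = np.searchsorted(displacement, target)
    if idx >= displacement.size:
        raise AnalysisError("obstacle never reaches the imputed position")
    return int(idx)


def fit_decision_mlp(dataset: pd.DataFrame, features=DECISION_FEATURES,
                     folds: int = 15, seed: int = 0) -> float:
    """Single-hidden-layer (100 unit) network benchmark under the same CV
    protocol; returns the mean fold accuracy."""
    X, y = _prepare_xy(dataset, features)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in cv.split(X, y):
        clf = MLPClassifier(hidden_layer_sizes=(100,), max_iter=800,
                            random_state=seed)
        clf.fit(X[tr], y[tr])
        accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
    return float(np.mean(accs))
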