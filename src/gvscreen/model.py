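"""LOSO-trained L1 logistic composite score, healthy reference, distances.

Pre-stimulation feature vectors from every subject are used to train an
L1-regularized logistic classifier under leave-one-subject-out
cross-validation; each outer fold selects its regularization strength with
the 1SE rule from an inner subject-grouped CV on binomial deviance.  The
fold coefficients (mapped back to the original feature scale) are averaged
into a single linear scoring axis.

Regularization is expressed per-sample (penalty relative to the mean
log-loss), so duplicating every trial leaves the fitted weights unchanged.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

PD_LABEL = 1  # positive class


@dataclass
class FoldModel:
    held_out: str
    weights: np.ndarray  # original feature scale
    intercept: float
    lambda_1se: float
    accuracy: float  # on the held-out subject's pre-stim trials


@dataclass
class CompositeModel:
    weights: np.ndarray          # (n_features,) averaged, original scale terms
    intercept: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    per_fold_weights: np.ndarray  # (n_folds, n_features)
    lambda_per_fold: np.ndarray
    fold_models: list[FoldModel] = field(default_factory=list)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Linear predictor for (n, n_features) or (n_features,) input."""
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.weights.size:
            raise ValueError(
                f"expected {self.weights.size} features, got {X.shape[-1]}")
        z = (X - self.feature_means) / self.feature_sds
        return self.intercept + z @ self.weights

    def to_json(self, path) -> None:
        d = {
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "feature_means": self.feature_means.tolist(),
            "feature_sds": self.feature_sds.tolist(),
            "per_fold_weights": self.per_fold_weights.tolist(),
            "lambda_per_fold": self.lambda_per_fold.tolist(),
            "folds": [
                {"held_out": f.held_out, "weights": f.weights.tolist(),
                 "intercept": f.intercept, "lambda_1se": f.lambda_1se,
                 "accuracy": f.accuracy}
                for f in self.fold_models
            ],
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CompositeModel":
        with open(path) as fh:
            d = json.load(fh)
        folds = [FoldModel(held_out=f["held_out"],
                           weights=np.array(f["weights"]),
                           intercept=f["intercept"],
                           lambda_1se=f["lambda_1se"],
                           accuracy=f["accuracy"]) for f in d["folds"]]
        return cls(weights=np.array(d["weights"]), intercept=d["intercept"],
                   feature_means=np.array(d["feature_means"]),
                   feature_sds=np.array(d["feature_sds"]),
                   per_fold_weights=np.array(d["per_fold_weights"]),
                   lambda_per_fold=np.array(d["lambda_per_fold"]),
                   fold_models=folds)


def _accuracy(scores: np.ndarray, y: np.ndarray) -> float:
    """Accuracy at probability threshold 0.5 (linear predictor 0); exact
    ties, which arise from the fully-regularized null model, get half
    credit, matching the expectation of a random tie-break."""
    pred = np.sign(scores)
    correct = np.where(pred == 0, 0.5, (pred > 0).astype(float) == y)
    return float(np.mean(correct))


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float) -> LogisticRegression:
    # per-sample penalty (mean logloss + lam*||w||_1), balanced class
    # weights so the fully-regularized null model is exactly zero rather
    # than a training-majority intercept
    clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                             C=1.0 / (lam * X.shape[0]), tol=1e-10,
                             class_weight="balanced", max_iter=20000,
                             random_state=0)
    clf.fit(X, y)
    return clf


def _lambda_path(X: np.ndarray, y: np.ndarray, n_lambdas: int = 30) -> np.ndarray:
    # lambda_max: smallest penalty that zeroes all coefficients of the
    # per-sample-normalized logistic loss
    p = y.mean()
    grad0 = np.abs(X.T @ (y - p)) / X.shape[0]
    lam_max = max(grad0.max(), 1e-6) * 1.05
    return np.geomspace(lam_max, lam_max * 1e-3, n_lambdas)


def _inner_cv_folds(subject_ids: np.ndarray, labels_by_subject: dict,
                    n_folds: int) -> list[np.ndarray]:
    """Subject-grouped folds, assigned round-robin within each class so every
    fold mixes both classes when possible; deterministic."""
    subs = sorted(set(subject_ids))
    n_folds = min(n_folds, len(subs))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    i = 0
    for cls in ("HC", "PD"):
        for s in [s for s in subs if labels_by_subject[s] == cls]:
            folds[i % n_folds].append(s)
            i += 1
    return [np.isin(subject_ids, f) for f in folds if f]


def select_lambda_1se(X: np.ndarray, y: np.ndarray, subject_ids: np.ndarray,
                      labels_by_subject: dict, lambdas: np.ndarray,
                      n_folds: int = 5) -> float:
    """1SE rule on inner-CV binomial deviance over a descending lambda path."""
    masks = _inner_cv_folds(subject_ids, labels_by_subject, n_folds)
    dev = np.full((len(masks), lambdas.size), np.nan)
    for i, val_mask in enumerate(masks):
        tr = ~val_mask
        if len(np.unique(y[tr])) < 2:
            continue
        for j, lam in enumerate(lambdas):
            clf = _fit_l1(X[tr], y[tr], lam)
            p = clf.predict_proba(X[val_mask])[:, list(clf.classes_).index(1)]
            dev[i, j] = _binomial_deviance(y[val_mask], p)
    dev = dev[~np.isnan(dev).all(axis=1)]
    mean = np.nanmean(dev, axis=0)
    se = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(dev.shape[0])
    j_min = int(np.nanargmin(mean))
    threshold = mean[j_min] + se[j_min]
    # lambdas descend: the first (largest) lambda within one SE of the best
    for j in range(lambdas.size):
        if mean[j] <= threshold:
            return float(lambdas[j])
    return float(lambdas[j_min])


def train_loso_lasso(features: np.ndarray, subject_ids: list[str],
                     groups: list[str], n_lambdas: int = 30,
                     inner_folds: int = 5) -> CompositeModel:
    """Train the composite model.

    ``features`` is (n_subjects, n_trials, n_features) of pre-stimulation
    vectors; ``groups`` gives "HC"/"PD" per subject.
    """
    F = np.asarray(features, dtype=float)
    n_subj, n_trials, n_feat = F.shape
    if len(subject_ids) != n_subj or len(groups) != n_subj:
        raise ValueError("subject_ids/groups must match the feature array")
    for cls in ("HC", "PD"):
        if sum(g == cls for g in groups) < 2:
            raise ValueError(f"need at least 2 subjects of class {cls}")
    labels_by_subject = dict(zip(subject_ids, groups))
    y_subj = np.array([1 if g == "PD" else 0 for g in groups])

    X_all = F.reshape(-1, n_feat)
    sub_all = np.repeat(subject_ids, n_trials)
    y_all = np.repeat(y_subj, n_trials)

    folds: list[FoldModel] = []
    for held_out in subject_ids:
        val = sub_all == held_out
        Xtr_raw, ytr = X_all[~val], y_all[~val]
        mu = Xtr_raw.mean(axis=0)
        sd = Xtr_raw.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr = (Xtr_raw - mu) / sd
        lambdas = _lambda_path(Xtr, ytr, n_lambdas)
        lam = select_lambda_1se(Xtr, ytr, sub_all[~val], labels_by_subject,
                                lambdas, inner_folds)
        clf = _fit_l1(Xtr, ytr, lam)
        w_std = clf.coef_.ravel()
        b_std = float(clf.intercept_[0])
        if list(clf.classes_) != [0, 1]:  # pragma: no cover
            w_std, b_std = -w_std, -b_std
        w_orig = w_std / sd
        b_orig = b_std - float(np.sum(w_std * mu / sd))
        acc = _accuracy(b_orig + X_all[val] @ w_orig, y_all[val])
        folds.append(FoldModel(held_out=held_out, weights=w_orig,
                               intercept=b_orig, lambda_1se=lam, accuracy=acc))

    w_avg = np.mean([f.weights for f in folds], axis=0)
    b_avg = float(np.mean([f.intercept for f in folds]))
    mu_all = X_all.mean(axis=0)
    sd_all = X_all.std(axis=0, ddof=0)
    sd_all = np.where(sd_all > 0, sd_all, 1.0)
    # re-express the averaged original-scale predictor in standardized form
    weights = w_avg * sd_all
    intercept = b_avg + float(np.sum(w_avg * mu_all))
    return CompositeModel(
        weights=weights, intercept=intercept,
        feature_means=mu_all, feature_sds=sd_all,
        per_fold_weights=np.stack([f.weights * sd_all for f in folds]),
        lambda_per_fold=np.array([f.lambda_1se for f in folds]),
        fold_models=folds,
    )


def score_features(model: CompositeModel, features: np.ndarray) -> np.ndarray:
    """Composite scores for an (..., n_features) array."""
    return model.score(features)


def healthy_reference(hc_prestim_scores: np.ndarray) -> float:
    """Mean pre-stimulation score over all trials of all healthy subjects."""
    s = np.asarray(hc_prestim_scores, dtype=float)
    if s.size == 0 or np.isnan(s).any():
        raise ValueError("healthy reference requires complete HC scores")
    return float(s.mean())


def distances(stim_scores: np.ndarray, reference: float) -> np.ndarray:
    """|score - reference| for each (stimulus, subject) entry."""
    return np.abs(np.asarray(stim_scores, dtype=float) - reference)


def interval_accuracy(model: CompositeModel,
                      features_by_interval: dict[str, np.ndarray],
                      subject_ids: list[str],
                      groups: list[str]) -> dict[str, float]:
    """Held-out classification accuracy per interval using the per-fold
    models (each subject's trials predicted by the fold that excluded them)."""
    y_subj = {s: (1 if g == "PD" else 0) for s, g in zip(subject_ids, groups)}
    fold_by_subject = {f.held_out: f for f in model.fold_models}
    out = {}
    for interval, F in features_by_interval.items():
        F = np.asarray(F, dtype=float)
        accs = []
        for i, subj in enumerate(subject_ids):
            f = fold_by_subject[subj]
            scores = f.intercept + F[i] @ f.weights
            accs.append(_accuracy(scores, np.full(scores.size, y_subj[subj])))
        out[interval] = float(np.mean(accs))
    return out
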