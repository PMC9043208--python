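"""SVM classification of per-lead feature vectors with Platt scaling.

Each lead is an independent sample. Training standardizes features with
training-set statistics, tunes the SVM by seeded cross-validated grid
search, and fits a Platt sigmoid on out-of-fold decision values so the
model emits a calibrated probability of the fragmented class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from fqrs.errors import ScoringError, TrainingError
from fqrs.features import FEATURE_NAMES

KERNELS = ("linear", "poly", "rbf")

_C_GRID = [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]
_GAMMA_GRID = [1e-3, 1e-2, 1e-1, 1.0, 1e1]
_DEGREE_GRID = [2, 3, 4]


@dataclass
class LabeledLeadSet:
    """Feature matrix + binary labels + recording id per lead-sample."""

    features: np.ndarray  # n x 10
    labels: np.ndarray  # n, in {0, 1}
    group_id: np.ndarray  # n, recording identifiers
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.group_id = np.asarray(self.group_id)
        n = len(self.labels)
        if self.features.shape[0] != n or len(self.group_id) != n:
            raise TrainingError("features, labels and group_id lengths differ")
        if not np.isin(self.labels, [0, 1]).all():
            raise TrainingError("labels must be binary")

    def subset(self, idx: np.ndarray) -> "LabeledLeadSet":
        return LabeledLeadSet(
            self.features[idx], self.labels[idx], self.group_id[idx], list(self.feature_names)
        )

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class FQRSModel:
    """Trained SVM + standardization statistics + Platt coefficients.

    The decision function is reconstructed from stored support vectors, so
    a persisted model is self-contained. The Platt score is
    ``sigmoid(A * decision + B)`` with A > 0, i.e. strictly monotone in
    the decision value.
    """

    kernel: str
    params: dict
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    # -- decision machinery -------------------------------------------------

    def _kernel_matrix(self, x: np.ndarray) -> np.ndarray:
        sv = self.support_vectors
        if self.kernel == "linear":
            return x @ sv.T
        gamma = self.params["gamma"]
        if self.kernel == "rbf":
            d2 = ((x[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
            return np.exp(-gamma * d2)
        if self.kernel == "poly":
            return (gamma * (x @ sv.T) + self.params["coef0"]) ** self.params["degree"]
        raise ScoringError(f"unknown kernel {self.kernel!r}")

    def decision_value(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != len(self.feature_names):
            raise ScoringError(
                f"expected {len(self.feature_names)} features, got {x.shape[1]}"
            )
        bad = ~np.isfinite(x)
        if bad.any():
            name = self.feature_names[int(np.argwhere(bad)[0][1])]
            raise ScoringError(f"non-finite value in feature {name!r}")
        z = (x - self.feature_mean) / self.feature_sd
        return self._kernel_matrix(z) @ self.dual_coef + self.intercept

    def score(self, features: np.ndarray) -> np.ndarray:
        """Calibrated probability of the fragmented class, in [0, 1]."""
        d = self.decision_value(features)
        return 1.0 / (1.0 + np.exp(-(self.platt_a * d + self.platt_b)))

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        blob = {
            "kernel": self.kernel,
            "params": self.params,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "feature_names": self.feature_names,
        }
        Path(path).write_text(json.dumps(blob))

    @classmethod
    def load(cls, path: str | Path) -> "FQRSModel":
        blob = json.loads(Path(path).read_text())
        return cls(
            kernel=blob["kernel"],
            params=blob["params"],
            feature_mean=np.array(blob["feature_mean"]),
            feature_sd=np.array(blob["feature_sd"]),
            support_vectors=np.array(blob["support_vectors"]),
            dual_coef=np.array(blob["dual_coef"]),
            intercept=float(blob["intercept"]),
            platt_a=float(blob["platt_a"]),
            platt_b=float(blob["platt_b"]),
            feature_names=list(blob["feature_names"]),
        )


def _fit_platt(decision: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Platt's sigmoid fit P(y=1|d) = 1/(1+exp(-(a*d+b))) by Newton descent
    on the cross-entropy with Platt's target smoothing."""
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    # smoothed targets avoid saturation on separable data
    t = np.where(labels == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    a, b = 1.0, 0.0
    for _ in range(100):
        z = a * decision + b
        p = 1.0 / (1.0 + np.exp(-z))
        g = p - t
        grad = np.array([np.dot(g, decision), g.sum()])
        w = p * (1 - p) + 1e-12
        h11 = np.dot(w, decision**2)
        h12 = np.dot(w, decision)
        h22 = w.sum()
        hess = np.array([[h11, h12], [h12, h22]]) + 1e-9 * np.eye(2)
        step = np.linalg.solve(hess, grad)
        a, b = a - step[0], b - step[1]
        if np.abs(step).max() < 1e-10:
            break
    if a <= 0:  # orientation guard: score must increase with the decision value
        a = 1e-6
    return float(a), float(b)


def train(data: LabeledLeadSet, kernel: str = "linear", seed: int = 0) -> FQRSModel:
    """Train an SVM on a labeled lead set and Platt-calibrate its output.

    Hyperparameters are tuned by 5-fold stratified cross-validated grid
    search (regularization 1e-3..1e3; RBF bandwidth 1e-3..1e1; polynomial
    degree 2-4); the Platt sigmoid is fit on out-of-fold decision values.
    """
    if kernel not in KERNELS:
        raise TrainingError(f"kernel must be one of {KERNELS}")
    if len(data) < 20:
        raise TrainingError("need at least 20 samples")
    classes = np.unique(data.labels)
    if len(classes) < 2:
        raise TrainingError("training data contains a single class")
    # deterministic ordering regardless of input row order
    order = np.lexsort((data.features[:, 0], data.labels, data.group_id.astype(str)))
    x_raw, y = data.features[order], data.labels[order]
    if not np.isfinite(x_raw).all():
        raise TrainingError("non-finite feature values in training data")

    mean = x_raw.mean(axis=0)
    sd = x_raw.std(axis=0)
    sd[sd == 0] = 1.0
    x = (x_raw - mean) / sd

    grid: dict[str, list] = {"C": list(_C_GRID)}
    if kernel == "rbf":
        grid["gamma"] = list(_GAMMA_GRID)
    elif kernel == "poly":
        grid["degree"] = list(_DEGREE_GRID)
        grid["gamma"] = ["scale"]
    cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel=kernel), grid, scoring="roc_auc", cv=cv, n_jobs=1, refit=True
    )
    search.fit(x, y)
    svc: SVC = search.best_estimator_

    decision_oof = cross_val_predict(
        SVC(kernel=kernel, **search.best_params_), x, y, cv=cv, method="decision_function"
    )
    platt_a, platt_b = _fit_platt(decision_oof, y)

    params = dict(search.best_params_)
    gamma = params.get("gamma", "scale")
    if gamma == "scale":  # sklearn's convention
        gamma = 1.0 / (x.shape[1] * x.var())
    params["gamma"] = float(gamma)
    params["coef0"] = float(svc.coef0)
    params.setdefault("degree", int(svc.degree))
    return FQRSModel(
        kernel=kernel,
        params=params,
        feature_mean=mean,
        feature_sd=sd,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        platt_a=platt_a,
        platt_b=platt_b,
        feature_names=list(data.feature_names),
    )


def score(model: FQRSModel, features: np.ndarray) -> np.ndarray:
    """Calibrated fQRS score(s) in [0, 1] for one or more feature vectors."""
    return model.score(features)


def binarize(score_value: float | np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """1 iff score >= threshold (boundary inclusive)."""
    return (np.asarray(score_value) >= threshold).astype(int)


def split_by_recording(
    data: LabeledLeadSet,
    train_frac: float = 0.8,
    n_repeats: int = 10,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Recording-level train/test splits: no recording contributes leads to
    both sides. Returns ``n_repeats`` (train_idx, test_idx) pairs."""
    recordings = np.unique(data.group_id)
    if len(recordings) < 2:
        raise TrainingError("need at least 2 recordings to split")
    rng = np.random.default_rng(seed)
    n_train = max(1, int(round(train_frac * len(recordings))))
    n_train = min(n_train, len(recordings) - 1)
    splits = []
    for _ in range(n_repeats):
        perm = rng.permutation(recordings)
        train_rec = set(perm[:n_train])
        mask = np.array([g in train_rec for g in data.group_id])
        splits.append((np.flatnonzero(mask), np.flatnonzero(~mask)))
    return splits


def balance_classes(data: LabeledLeadSet, seed: int = 0) -> LabeledLeadSet:
    """All fragmented samples + an equal-size random subset of
    non-fragmented ones."""
    pos = np.flatnonzero(data.labels == 1)
    neg = np.flatnonzero(data.labels == 0)
    if len(pos) == 0:
        raise TrainingError("no fragmented samples to balance against")
    if len(neg) <= len(pos):
        return data
    rng = np.random.default_rng(seed)
    keep_neg = rng.choice(neg, size=len(pos), replace=False)
    idx = np.sort(np.concatenate([pos, keep_neg]))
    return data.subset(idx)
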