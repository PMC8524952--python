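"""One-vs-rest kernel SVM assigning natural products to their origin class.

The classifier operates on a precomputed similarity (kernel) matrix. For
MAP4 fingerprints the kernel is the MinHash index-match fraction (an
estimator of shingle-set Jaccard similarity); the comparator models use
Tanimoto or Dice kernels on folded binary fingerprints, or an RBF kernel
on standardized physico-chemical property vectors. One binary SVM is
trained per class against the rest, with class weights inversely
proportional to class frequency and the regularization constant C selected
by maximizing cross-validated balanced accuracy on the training data. Each
sub-model's margin is mapped to a probability by Platt scaling (a logistic
fit on out-of-fold decision values); class probabilities are normalized to
sum to one.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import metrics
from .chem import parse_smiles, strip_stereo
from .errors import ConfigurationError, DegenerateTrainingError, DimensionError
from .fingerprints import (
    DEFAULT_DIMENSIONS,
    DEFAULT_HASH_SEED,
    DEFAULT_RADII,
    featurize,
)
from rdkit import Chem

#: Default C grid (the systematic-comparison grid).
DEFAULT_C_GRID: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)

#: Which molecular representation each kernel runs on.
KERNEL_REPRESENTATION = {
    "map4_match": "map4",
    "tanimoto": "circular",
    "dice": "atom_pair",
    "rbf": "properties",
}


@dataclass(frozen=True)
class KernelSpec:
    """Kernel kind plus its parameters.

    kind: "map4_match" (MinHash index-match fraction), "tanimoto" or
    "dice" (binary fingerprints), or "rbf" (property vectors; requires
    gamma). ``representation`` may override the default encoding, e.g.
    ``KernelSpec("tanimoto", representation="atom_pair")`` for the
    atom-pair comparator.
    """

    kind: str
    gamma: float | None = None
    representation: str | None = None

    def __post_init__(self):
        if self.kind not in KERNEL_REPRESENTATION:
            raise ConfigurationError(f"unknown kernel kind: {self.kind!r}")
        if self.kind == "rbf":
            if self.gamma is None or self.gamma <= 0:
                raise ConfigurationError("rbf kernel requires gamma > 0")
        elif self.gamma is not None:
            raise ConfigurationError(f"gamma is only valid for rbf, not {self.kind}")

    @property
    def feature_representation(self) -> str:
        return self.representation or KERNEL_REPRESENTATION[self.kind]


def compute_kernel_matrix(X, Y, spec: KernelSpec) -> np.ndarray:
    """Similarity matrix K[i, j] between rows of X and rows of Y.

    X, Y: (n, d) arrays in the representation the kernel expects —
    MinHash integer vectors (map4_match), binary fingerprints
    (tanimoto/dice) or already-standardized property vectors (rbf).
    """
    X = np.asarray(X)
    Y = np.asarray(Y)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[1] != Y.shape[1]:
        raise DimensionError(f"incompatible shapes {X.shape} and {Y.shape}")
    if spec.kind == "map4_match":
        d = X.shape[1]
        out = np.empty((X.shape[0], Y.shape[0]))
        # chunk rows so the (chunk, m, d) boolean temporary stays ~64 MB
        chunk = max(1, (64 << 20) // max(Y.shape[0] * d, 1))
        for start in range(0, X.shape[0], chunk):
            stop = min(start + chunk, X.shape[0])
            out[start:stop] = (X[start:stop, None, :] == Y[None, :, :]).mean(axis=2)
        return out
    if spec.kind in ("tanimoto", "dice"):
        Xf = X.astype(float)
        Yf = Y.astype(float)
        inter = Xf @ Yf.T
        na = Xf.sum(axis=1)[:, None]
        nb = Yf.sum(axis=1)[None, :]
        if spec.kind == "tanimoto":
            denom = na + nb - inter
        else:
            denom = na + nb
            inter = 2.0 * inter
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(denom > 0, inter / denom, 0.0)
        return k
    if spec.kind == "rbf":
        return rbf_kernel(X, Y, gamma=spec.gamma)
    raise ConfigurationError(f"unknown kernel kind: {spec.kind!r}")


# ---------------------------------------------------------------------------
# One-vs-rest sub-model
# ---------------------------------------------------------------------------

@dataclass
class _SubModel:
    """One binary (class vs rest) SVM over the precomputed kernel."""

    support_idx: np.ndarray   # indices into the training set
    dual_coef: np.ndarray     # (n_support,)
    intercept: float
    platt_slope: float
    platt_intercept: float

    def decision(self, K_test: np.ndarray) -> np.ndarray:
        """Margin for each row of K_test (kernel vs the full training set)."""
        return K_test[:, self.support_idx] @ self.dual_coef + self.intercept

    def probability(self, K_test: np.ndarray) -> np.ndarray:
        f = self.decision(K_test)
        return 1.0 / (1.0 + np.exp(-(self.platt_slope * f + self.platt_intercept)))


def _fit_binary(K: np.ndarray, y_bin: np.ndarray, C: float,
                sample_weight: np.ndarray, seed: int,
                platt_folds: int = 3) -> _SubModel:
    svc = SVC(kernel="precomputed", C=C, random_state=seed)
    svc.fit(K, y_bin, sample_weight=sample_weight)
    sub = _SubModel(
        support_idx=svc.support_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]),
        platt_slope=1.0,
        platt_intercept=0.0,
    )
    # Platt scaling on out-of-fold decision values
    n_min = min(int(y_bin.sum()), int((~y_bin.astype(bool)).sum()))
    k = min(platt_folds, n_min)
    if k >= 2:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        f_oof = np.empty(len(y_bin))
        for tr, te in cv.split(K, y_bin):
            inner = SVC(kernel="precomputed", C=C, random_state=seed)
            inner.fit(K[np.ix_(tr, tr)], y_bin[tr], sample_weight=sample_weight[tr])
            f_oof[te] = (
                K[np.ix_(te, tr)][:, inner.support_] @ inner.dual_coef_.ravel()
                + inner.intercept_[0]
            )
    else:  # too few positives for out-of-fold margins: calibrate in-sample
        f_oof = sub.decision(K)
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(f_oof.reshape(-1, 1), y_bin.astype(int), sample_weight=sample_weight)
    sub.platt_slope = float(lr.coef_[0, 0])
    sub.platt_intercept = float(lr.intercept_[0])
    return sub


# ---------------------------------------------------------------------------
# Trained classifier
# ---------------------------------------------------------------------------

@dataclass
class TrainedOriginClassifier:
    classes: tuple[str, ...]
    spec: KernelSpec
    C: float
    class_weights: dict[str, float]
    submodels: list[_SubModel]
    X_train: np.ndarray
    scaler_mean: np.ndarray | None = None   # property-kernel standardization
    scaler_scale: np.ndarray | None = None
    fingerprint_d: int = DEFAULT_DIMENSIONS
    fingerprint_radii: tuple[int, ...] = DEFAULT_RADII
    fingerprint_seed: int = DEFAULT_HASH_SEED

    @property
    def platt_params(self) -> list[tuple[float, float]]:
        return [(m.platt_slope, m.platt_intercept) for m in self.submodels]

    # -- feature plumbing ---------------------------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_mean is not None:
            return (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        return np.asarray(X)

    def _featurize_smiles(self, smiles_list) -> np.ndarray:
        X = featurize(
            smiles_list,
            self.spec.feature_representation,
            d=self.fingerprint_d,
            radii=self.fingerprint_radii,
            seed=self.fingerprint_seed,
            strip_stereochemistry=True,
        )
        return self._prepare(X)

    # -- prediction ---------------------------------------------------------

    def predict_proba_features(self, X: np.ndarray, prepared: bool = False) -> np.ndarray:
        """(n, n_classes) normalized class probabilities from feature rows."""
        Xp = X if prepared else self._prepare(X)
        K = compute_kernel_matrix(Xp, self.X_train, self.spec)
        raw = np.column_stack([m.probability(K) for m in self.submodels])
        return raw / raw.sum(axis=1, keepdims=True)

    def predict_features(self, X: np.ndarray, prepared: bool = False) -> np.ndarray:
        proba = self.predict_proba_features(X, prepared=prepared)
        return np.array([self.classes[i] for i in proba.argmax(axis=1)])

    def predict(self, smiles: str) -> tuple[str, dict[str, float]]:
        """Predict the origin of one molecule given as SMILES.

        The query is canonicalized and stripped of stereochemistry before
        fingerprinting, so equivalent SMILES give identical output.
        Returns the winning class and the per-class percentages.
        """
        mol = strip_stereo(parse_smiles(smiles))
        X = self._featurize_smiles([Chem.MolToSmiles(mol)])
        proba = self.predict_proba_features(X, prepared=True)[0]
        percentages = {c: float(100.0 * p) for c, p in zip(self.classes, proba)}
        return self.classes[int(proba.argmax())], percentages

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Persist as a single .npz archive (JSON manifest + arrays)."""
        manifest = {
            "classes": list(self.classes),
            "kernel": {"kind": self.spec.kind, "gamma": self.spec.gamma,
                       "representation": self.spec.representation},
            "C": self.C,
            "class_weights": self.class_weights,
            "platt_params": self.platt_params,
            "fingerprint": {"d": self.fingerprint_d,
                            "radii": list(self.fingerprint_radii),
                            "seed": self.fingerprint_seed},
            "intercepts": [m.intercept for m in self.submodels],
        }
        arrays = {"X_train": self.X_train}
        for i, m in enumerate(self.submodels):
            arrays[f"support_idx_{i}"] = m.support_idx
            arrays[f"dual_coef_{i}"] = m.dual_coef
        if self.scaler_mean is not None:
            arrays["scaler_mean"] = self.scaler_mean
            arrays["scaler_scale"] = self.scaler_scale
        np.savez(path, manifest=np.frombuffer(
            json.dumps(manifest).encode("utf-8"), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedOriginClassifier":
        with np.load(path) as data:
            manifest = json.loads(bytes(data["manifest"]).decode("utf-8"))
            submodels = []
            for i in range(len(manifest["classes"])):
                slope, intercept = manifest["platt_params"][i]
                submodels.append(_SubModel(
                    support_idx=data[f"support_idx_{i}"],
                    dual_coef=data[f"dual_coef_{i}"],
                    intercept=manifest["intercepts"][i],
                    platt_slope=slope,
                    platt_intercept=intercept,
                ))
            kern = manifest["kernel"]
            return cls(
                classes=tuple(manifest["classes"]),
                spec=KernelSpec(kern["kind"], kern["gamma"], kern["representation"]),
                C=manifest["C"],
                class_weights=manifest["class_weights"],
                submodels=submodels,
                X_train=data["X_train"],
                scaler_mean=data["scaler_mean"] if "scaler_mean" in data else None,
                scaler_scale=data["scaler_scale"] if "scaler_scale" in data else None,
                fingerprint_d=manifest["fingerprint"]["d"],
                fingerprint_radii=tuple(manifest["fingerprint"]["radii"]),
                fingerprint_seed=manifest["fingerprint"]["seed"],
            )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def inverse_frequency_weights(labels) -> dict[str, float]:
    """Class weights inversely proportional to class frequency,
    normalized so a balanced dataset gets weight 1 per class."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    n, k = len(labels), len(classes)
    return {str(c): float(n / (k * cnt)) for c, cnt in zip(classes, counts)}


def _ovr_fit(K: np.ndarray, labels: np.ndarray, classes, C: float,
             weights: dict[str, float], seed: int) -> list[_SubModel]:
    sample_weight = np.array([weights[str(l)] for l in labels])
    return [
        _fit_binary(K, (labels == c).astype(int), C, sample_weight, seed)
        for c in classes
    ]


def _ovr_predict(K_test: np.ndarray, submodels, classes) -> np.ndarray:
    raw = np.column_stack([m.probability(K_test) for m in submodels])
    return np.array([classes[i] for i in raw.argmax(axis=1)])


def fit(
    X,
    labels,
    spec: KernelSpec = KernelSpec("map4_match"),
    C_grid=DEFAULT_C_GRID,
    selection_folds: int = 5,
    seed: int = 0,
    fingerprint_d: int = DEFAULT_DIMENSIONS,
    fingerprint_radii: tuple[int, ...] = DEFAULT_RADII,
    fingerprint_seed: int = DEFAULT_HASH_SEED,
) -> TrainedOriginClassifier:
    """Train the one-vs-rest kernel SVM on featurized molecules.

    X: (n, d) feature matrix in the kernel's representation (raw property
    vectors for rbf; standardization is fitted here on the training data).
    C is selected from ``C_grid`` by maximizing mean balanced accuracy over
    an inner stratified cross-validation, then the model is refitted on the
    full training set with the winning C (ties go to the smallest C).
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise DegenerateTrainingError("training data contains a single class")
    if counts.min() < 2:
        raise DegenerateTrainingError("every class needs >= 2 training samples")

    scaler_mean = scaler_scale = None
    X = np.asarray(X)
    if spec.kind == "rbf":
        scaler = StandardScaler().fit(X.astype(float))
        scaler_mean, scaler_scale = scaler.mean_, scaler.scale_
        X = scaler.transform(X.astype(float))

    weights = inverse_frequency_weights(labels)
    K = compute_kernel_matrix(X, X, spec)

    C_grid = list(C_grid)
    if len(C_grid) > 1:
        folds = int(min(selection_folds, counts.min()))
        cv = StratifiedKFold(n_splits=max(folds, 2), shuffle=True, random_state=seed)
        scores = np.zeros(len(C_grid))
        for tr, va in cv.split(X, labels):
            K_tr = K[np.ix_(tr, tr)]
            K_va = K[np.ix_(va, tr)]
            for ci, C in enumerate(C_grid):
                subs = _ovr_fit(K_tr, labels[tr], classes, C, weights, seed)
                pred = _ovr_predict(K_va, subs, classes)
                conf = metrics.confusion_matrix(labels[va], pred, classes)
                scores[ci] += metrics.balanced_accuracy(conf)
        best_C = float(C_grid[int(np.argmax(scores))])  # argmax: first best => smallest C
    else:
        best_C = float(C_grid[0])

    submodels = _ovr_fit(K, labels, classes, best_C, weights, seed)
    return TrainedOriginClassifier(
        classes=tuple(str(c) for c in classes),
        spec=spec,
        C=best_C,
        class_weights=weights,
        submodels=submodels,
        X_train=X,
        scaler_mean=scaler_mean,
        scaler_scale=scaler_scale,
        fingerprint_d=fingerprint_d,
        fingerprint_radii=fingerprint_radii,
        fingerprint_seed=fingerprint_seed,
    )


def fit_smiles(smiles_list, labels, spec: KernelSpec = KernelSpec("map4_match"),
               **kwargs) -> TrainedOriginClassifier:
    """Featurize SMILES (stereo stripped) in the kernel's representation
    and train."""
    d = kwargs.get("fingerprint_d", DEFAULT_DIMENSIONS)
    radii = kwargs.get("fingerprint_radii", DEFAULT_RADII)
    fseed = kwargs.get("fingerprint_seed", DEFAULT_HASH_SEED)
    X = featurize(smiles_list, spec.feature_representation, d=d, radii=radii,
                  seed=fseed, strip_stereochemistry=True)
    return fit(X, labels, spec, **kwargs)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EvalReport:
    """k-fold evaluation summary (mean +/- std across folds)."""

    balanced_accuracy: tuple[float, float]
    mcc: tuple[float, float]
    f1: tuple[float, float]
    per_class_recall: dict[str, float]
    confusion: np.ndarray        # summed over folds
    folds: int
    per_fold: pd.DataFrame = field(repr=False, compare=False, default=None)

    def summary_dict(self) -> dict:
        return {
            "folds": self.folds,
            "balanced_accuracy_mean": self.balanced_accuracy[0],
            "balanced_accuracy_std": self.balanced_accuracy[1],
            "mcc_mean": self.mcc[0],
            "mcc_std": self.mcc[1],
            "f1_mean": self.f1[0],
            "f1_std": self.f1[1],
            "per_class_recall": self.per_class_recall,
            "confusion": self.confusion.tolist(),
        }


def cross_validate(
    X,
    labels,
    spec: KernelSpec = KernelSpec("map4_match"),
    k: int = 5,
    seed: int = 0,
    C_grid=DEFAULT_C_GRID,
    selection_folds: int = 5,
) -> EvalReport:
    """Stratified k-fold evaluation of the origin classifier.

    Each molecule appears in exactly one test fold; the model (including
    C selection, class weights, Platt calibration and, for the property
    kernel, descriptor standardization) is fitted on the k-1 remaining
    folds only.
    """
    labels = np.asarray(labels)
    X = np.asarray(X)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise DegenerateTrainingError(
            f"smallest class ({counts.min()}) cannot be stratified into {k} folds"
        )
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    total_conf = np.zeros((len(classes), len(classes)), dtype=int)
    for fold, (tr, te) in enumerate(cv.split(X, labels)):
        model = fit(X[tr], labels[tr], spec, C_grid=C_grid,
                    selection_folds=selection_folds, seed=seed)
        pred = model.predict_features(X[te])
        conf = metrics.confusion_matrix(labels[te], pred, classes)
        total_conf += conf
        rows.append({
            "fold": fold,
            "C": model.C,
            "balanced_accuracy": metrics.balanced_accuracy(conf),
            "mcc": metrics.mcc(conf),
            "f1": metrics.f1_score(conf),
        })
    per_fold = pd.DataFrame(rows)
    recall = metrics.per_class_recall(total_conf)

    def _ms(col):
        return (float(per_fold[col].mean()), float(per_fold[col].std(ddof=0)))

    return EvalReport(
        balanced_accuracy=_ms("balanced_accuracy"),
        mcc=_ms("mcc"),
        f1=_ms("f1"),
        per_class_recall={str(c): float(r) for c, r in zip(classes, recall)},
        confusion=total_conf,
        folds=k,
        per_fold=per_fold,
    )


def cross_validate_smiles(smiles_list, labels,
                          spec: KernelSpec = KernelSpec("map4_match"),
                          **kwargs) -> EvalReport:
    X = featurize(smiles_list, spec.feature_representation,
                  strip_stereochemistry=True)
    return cross_validate(X, labels, spec, **kwargs)
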