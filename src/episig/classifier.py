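"""Feature selection and the three-class epi-signature classifier.

From the epi-signature probes, feature selection keeps probes that fully
separate patients from controls (ROC AUC = 1, folded for direction) and then
greedily prunes redundant probes whose pairwise Pearson correlation exceeds
|r| > sqrt(0.8).  A multi-class support vector machine with a radial basis
function kernel is trained on the surviving probes; hyperparameters are
chosen by stratified tenfold cross-validation over a small (C, gamma) grid,
and the model emits three probability scores per sample (patient / carrier /
control, one-vs-one decision values coupled through sigmoid calibration) that
sum to one.  The predicted class is the argmax; samples whose top score falls
below 0.5 are flagged as ambiguous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.svm import SVC

from .io_formats import BetaMatrix

__all__ = [
    "CLASS_ORDER",
    "SCORE_CUTOFF",
    "probe_auc",
    "FeatureSelection",
    "select_features",
    "SignatureModel",
    "train_svm",
    "predict_scores",
    "SpecificityResult",
    "evaluate_specificity",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

CLASS_ORDER = ("patient", "carrier", "control")
SCORE_CUTOFF = 0.5

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = ("scale_p", 0.01, 0.001)  # "scale_p" -> 1 / n_features


def probe_auc(values: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve of one probe (case > control, ties half).

    Equivalent to the normalized Mann-Whitney U statistic:
    (#{case_i > control_j} + 0.5 #ties) / (n_case * n_control).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = int(labels.sum()), int((~labels).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be non-empty")
    ranks = rankdata(values)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


@dataclass
class FeatureSelection:
    """Outcome of the AUC filter and the correlation-pruning step."""

    auc: pd.Series  # folded AUC per signature probe (patients vs controls)
    retained_after_auc: list
    retained_after_pruning: list
    pruning_threshold: float  # on |Pearson r|


def _greedy_prune(corr: pd.DataFrame, threshold: float) -> list:
    """Drop one member of the most-correlated pair until all |r| <= threshold.

    The dropped member is the one with the larger mean absolute correlation
    to the other remaining probes; ties break toward keeping the earlier
    probe id.
    """
    keep = list(corr.index)
    c = corr.abs().to_numpy().astype(float)
    np.fill_diagonal(c, 0.0)
    alive = np.ones(len(keep), dtype=bool)
    while True:
        sub = np.where(np.outer(alive, alive), c, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold:
            break
        denom = max(alive.sum() - 1, 1)
        mean_i = sub[i].sum() / denom
        mean_j = sub[j].sum() / denom
        if mean_i > mean_j:
            drop = i
        elif mean_j > mean_i:
            drop = j
        else:  # tie: drop the later probe id
            drop = max(i, j, key=lambda k: keep[k])
        alive[drop] = False
    return [p for p, a in zip(keep, alive) if a]


def select_features(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    signature_probes: Sequence[str],
    auc_tol: float = 1e-9,
    r2_cut: float = 0.8,
) -> FeatureSelection:
    """AUC filter then correlation pruning over the epi-signature probes.

    Step 1 keeps probes whose direction-folded AUC (patients vs controls;
    carriers excluded) is 1 within ``auc_tol``.  Step 2 prunes redundant
    probes with |Pearson r| > sqrt(r2_cut) on the same samples.
    """
    probes = list(map(str, signature_probes))
    by = sheet.set_index("sample_id")["group"]
    samples = [s for s in beta.sample_ids if by.get(s) in ("patient", "control")]
    is_case = np.array([by[s] == "patient" for s in samples])
    X = beta.values.loc[probes, samples]

    auc = {}
    for pid in probes:
        a = probe_auc(X.loc[pid].to_numpy(), is_case)
        auc[pid] = max(a, 1.0 - a)  # folded: direction-agnostic separation
    auc = pd.Series(auc)
    after_auc = auc.index[auc >= 1.0 - auc_tol].tolist()
    if not after_auc:
        raise ValueError(
            "no signature probe fully separates patients from controls; "
            "review the AUC tolerance or the signature"
        )
    threshold = float(np.sqrt(r2_cut))
    if len(after_auc) > 1:
        corr = X.loc[after_auc].T.corr()
        pruned = _greedy_prune(corr, threshold)
    else:
        pruned = list(after_auc)
    return FeatureSelection(
        auc=auc,
        retained_after_auc=after_auc,
        retained_after_pruning=pruned,
        pruning_threshold=threshold,
    )


def _stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list:
    """Round-robin class-stratified folds; folds may lack small classes.

    Keeps the requested fold count even when a class (carriers, n = 6) has
    fewer members than folds, so every training split still sees most of
    that class.
    """
    for cls in np.unique(labels):
        n_cls = int((labels == cls).sum())
        if n_cls < n_folds:
            warnings.warn(
                f"class {cls!r} has {n_cls} samples, fewer than {n_folds} folds; "
                "some folds will not contain it"
            )
    assignment = np.empty(len(labels), dtype=int)
    offset = 0
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        assignment[idx] = (np.arange(len(idx)) + offset) % n_folds
        offset += len(idx)  # stagger classes so small classes spread out
    return [np.flatnonzero(assignment == f) for f in range(n_folds)]


@dataclass
class SignatureModel:
    """Selected probes plus a trained, standardized RBF-SVM."""

    probe_ids: list
    class_order: tuple = CLASS_ORDER
    C: float = 1.0
    gamma: float = 1.0
    cv_accuracy: float = float("nan")  # percent
    seed: int = 0
    folds: int = 10
    scaler_mean: Optional[np.ndarray] = None
    scaler_scale: Optional[np.ndarray] = None
    _svc: Optional[SVC] = field(default=None, repr=False)

    # -- scoring -------------------------------------------------------------
    def score_matrix(self, X: np.ndarray) -> np.ndarray:
        """Probability scores (columns in class_order) for raw feature rows."""
        Z = (X - self.scaler_mean) / self.scaler_scale
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            proba = self._svc.predict_proba(Z)
        # libsvm orders columns by integer class code = index into class_order
        return proba

    # -- serialization -------------------------------------------------------
    _SVC_ATTRS = (
        "support_",
        "support_vectors_",
        "_n_support",
        "dual_coef_",
        "_dual_coef_",
        "intercept_",
        "_intercept_",
        "_probA",
        "_probB",
        "classes_",
        "class_weight_",
        "_gamma",
        "fit_status_",
        "shape_fit_",
        "_sparse",
        "n_features_in_",
        "_num_iter",
    )
    _SVC_INT_ATTRS = {"support_": np.int32, "_n_support": np.int32, "_num_iter": np.int32}

    def to_dict(self) -> dict:
        if self._svc is None:
            raise ValueError("model has not been trained")
        svc_state = {}
        for attr in self._SVC_ATTRS:
            val = getattr(self._svc, attr)
            if isinstance(val, np.ndarray):
                svc_state[attr] = {"array": val.tolist(), "dtype": str(val.dtype)}
            elif isinstance(val, tuple):
                svc_state[attr] = {"tuple": list(val)}
            else:
                svc_state[attr] = val
        return {
            "probe_ids": list(self.probe_ids),
            "class_order": list(self.class_order),
            "C": self.C,
            "gamma": self.gamma,
            "cv_accuracy": self.cv_accuracy,
            "seed": self.seed,
            "folds": self.folds,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "svc": svc_state,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SignatureModel":
        model = cls(
            probe_ids=list(payload["probe_ids"]),
            class_order=tuple(payload["class_order"]),
            C=float(payload["C"]),
            gamma=float(payload["gamma"]),
            cv_accuracy=float(payload["cv_accuracy"]),
            seed=int(payload["seed"]),
            folds=int(payload["folds"]),
            scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
            scaler_scale=np.asarray(payload["scaler_scale"], dtype=float),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            svc = SVC(
                kernel="rbf", C=model.C, gamma=model.gamma, probability=True,
                random_state=model.seed,
            )
        for attr, val in payload["svc"].items():
            if isinstance(val, dict) and "array" in val:
                val = np.asarray(val["array"], dtype=np.dtype(val["dtype"]))
            elif isinstance(val, dict) and "tuple" in val:
                val = tuple(val["tuple"])
            setattr(svc, attr, val)
        model._svc = svc
        return model


def _fit_svc(X: np.ndarray, y: np.ndarray, C: float, gamma: float, seed: int) -> SVC:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        svc = SVC(kernel="rbf", C=C, gamma=gamma, probability=True, random_state=seed)
        svc.fit(X, y)
    return svc


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def train_svm(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    probes: Sequence[str],
    folds: int = 10,
    C_grid: Sequence = DEFAULT_C_GRID,
    gamma_grid: Sequence = DEFAULT_GAMMA_GRID,
    seed: int = 0,
) -> SignatureModel:
    """Grid-searched, cross-validated three-class RBF-SVM on beta features.

    Features are standardized with training-fold statistics only.  The grid
    is scored by pooled held-out accuracy over stratified folds; ties prefer
    the smallest C, then the smallest gamma.  The winning setting is refitted
    on all training samples.
    """
    probes = list(map(str, probes))
    by = sheet.set_index("sample_id")["group"]
    samples = [s for s in beta.sample_ids if by.get(s) in CLASS_ORDER]
    y = np.array([CLASS_ORDER.index(by[s]) for s in samples])
    if len(np.unique(y)) < 3:
        raise ValueError("training needs all three classes present")
    X = beta.values.loc[probes, samples].T.to_numpy()

    rng = np.random.default_rng(seed)
    fold_idx = _stratified_folds(y, folds, rng)

    def resolve_gamma(g) -> float:
        return 1.0 / len(probes) if g == "scale_p" else float(g)

    best = None  # (accuracy, C, gamma)
    for C in sorted(float(c) for c in C_grid):
        for gamma in sorted(resolve_gamma(g) for g in gamma_grid):
            hits = 0
            for test in fold_idx:
                if len(test) == 0:
                    continue
                train = np.setdiff1d(np.arange(len(y)), test)
                Z, mean, scale = _standardize(X[train])
                svc = _fit_svc(Z, y[train], C, gamma, seed)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", FutureWarning)
                    proba = svc.predict_proba((X[test] - mean) / scale)
                pred = np.asarray(svc.classes_)[proba.argmax(axis=1)]
                hits += int((pred == y[test]).sum())
            acc = hits / len(y)
            if best is None or acc > best[0]:
                best = (acc, C, gamma)
    acc, C, gamma = best

    Z, mean, scale = _standardize(X)
    svc = _fit_svc(Z, y, C, gamma, seed)
    return SignatureModel(
        probe_ids=probes,
        class_order=CLASS_ORDER,
        C=C,
        gamma=gamma,
        cv_accuracy=100.0 * acc,
        seed=seed,
        folds=folds,
        scaler_mean=mean,
        scaler_scale=scale,
        _svc=svc,
    )


def predict_scores(model: SignatureModel, beta: BetaMatrix) -> pd.DataFrame:
    """Three probability scores and the predicted class for every sample.

    Scores lie in [0, 1] and sum to 1 per sample; the predicted class is the
    argmax, and samples whose top score is below 0.5 carry an ambiguity flag.
    """
    missing = [p for p in model.probe_ids if p not in beta.probe_ids]
    if missing:
        raise ValueError(f"{len(missing)} model probes missing from beta matrix: {missing[:5]}")
    X = beta.values.loc[list(model.probe_ids)].T.to_numpy()
    proba = model.score_matrix(X)
    classes = np.asarray(model._svc.classes_) if model._svc is not None else np.arange(3)
    # map libsvm column order back to class_order
    cols = {int(c): proba[:, k] for k, c in enumerate(classes)}
    scores = np.column_stack([cols[i] for i in range(len(model.class_order))])
    pred_idx = scores.argmax(axis=1)
    out = pd.DataFrame(
        {
            "score_patient": scores[:, 0],
            "score_carrier": scores[:, 1],
            "score_control": scores[:, 2],
            "predicted_class": [model.class_order[i] for i in pred_idx],
            "ambiguous": scores.max(axis=1) < SCORE_CUTOFF,
        },
        index=pd.Index(beta.sample_ids, name="sample_id"),
    )
    return out


@dataclass
class SpecificityResult:
    specificity: float  # percent of external samples predicted control
    per_group: pd.DataFrame  # group x predicted-class counts
    scores: pd.DataFrame


def evaluate_specificity(
    model: SignatureModel, beta: BetaMatrix, sheet: pd.DataFrame
) -> SpecificityResult:
    """Fraction of external samples predicted as control, with score detail."""
    if beta.shape[1] == 0:
        raise ValueError("external cohort is empty")
    scores = predict_scores(model, beta)
    by = sheet.set_index("sample_id")["group"]
    groups = pd.Series([by.get(s, "unknown") for s in scores.index], index=scores.index)
    confusion = (
        pd.crosstab(groups, scores["predicted_class"])
        .reindex(columns=list(model.class_order), fill_value=0)
    )
    spec = 100.0 * float((scores["predicted_class"] == "control").mean())
    return SpecificityResult(specificity=spec, per_group=confusion, scores=scores)
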