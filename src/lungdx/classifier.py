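"""PLS-LDA classification with nested LASSO top-K feature selection and the
balanced repeated four-fold cross-validation engine.

The classifier projects autoscaled features onto a few partial-least-squares
latent components (maximizing covariance with the +/-1-coded class response)
and applies linear discriminant analysis with equal class priors to the
component scores. Inside every training fold, features are first ranked by
their order of entry into the active set along a decreasing-penalty LASSO
path on the +/-1 response, and the first K entrants form the signature; the
held-out quarter of the fold never influences selection, scaling or fitting.

Class imbalance (269 cancer vs 108 inflammation) is handled by drawing a
random majority-class subsample of minority size per repeat, so every
classifier is trained on a balanced set; 250 repeats of a stratified 4-fold
split evaluate the classifier 1000 times and yield per-region selection
frequencies across all evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import lars_path
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ScalingModel",
    "PLSLDAModel",
    "CVConfig",
    "CVResult",
    "LoocvResult",
    "lasso_top_k",
    "fit_pls",
    "fit_pls_lda",
    "predict",
    "balanced_repeated_cv",
    "ablation_cv",
    "loocv_per_stage",
    "augment_with_suvmax",
]


class ClassifierError(ValueError):
    pass


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

@dataclass
class ScalingModel:
    """Per-feature training means and SDs (autoscaling to mean 0, SD 1)."""

    means: np.ndarray
    sds: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "ScalingModel":
        means = X.mean(axis=0)
        sds = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sds == 0)
        if zero.size:
            raise ClassifierError(
                f"zero-variance feature columns at positions {zero.tolist()} "
                "cannot be autoscaled"
            )
        return cls(means=means, sds=sds)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.means) / self.sds


def _encode_labels(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted class labels and the +/-1 coding (first sorted label -> -1)."""
    classes = np.unique(y)
    if classes.size != 2:
        raise ClassifierError(f"exactly two classes required, got {classes.tolist()}")
    return classes, np.where(y == classes[1], 1.0, -1.0)


def lasso_top_k(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """First ``k`` features to enter the LASSO path on the +/-1-coded response.

    The L1 path (least squares loss, LARS algorithm) is traced from the
    all-zero model toward lower penalties; features are ranked by the step at
    which they first become active, ties broken by the smaller column index.
    Exactly duplicated columns are represented by their smallest index only.
    Features that never enter the path are ranked after all entrants by
    decreasing absolute inner product with the response. Returns 0-based
    column indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ClassifierError("X must be 2-D with one row per label")
    n, p = X.shape
    if k < 0 or k > p:
        raise ClassifierError(f"k must lie in 0..{p}, got {k}")
    classes, yy = _encode_labels(y)
    if k == 0:
        return np.empty(0, dtype=int)

    # collapse exact duplicate columns onto their smallest index
    _, first_idx = np.unique(X, axis=1, return_index=True)
    keep = np.sort(first_idx)
    Xu = X[:, keep]

    _, _, coefs = lars_path(Xu, yy, method="lasso")
    entered = coefs != 0
    entry_step = np.where(entered.any(axis=1), entered.argmax(axis=1), np.iinfo(np.int64).max)
    corr = np.abs(Xu.T @ yy)
    # primary: entry order; never-entered columns: by |inner product| desc, then index
    order = sorted(range(Xu.shape[1]),
                   key=lambda j: (entry_step[j], -corr[j], keep[j]))
    ranked = keep[np.array(order)]
    return ranked[: min(k, ranked.size)].astype(int)


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    """Partial least squares regression of a +/-1 response on centered/scaled X.

    Successive weight vectors maximize covariance with the deflated response;
    the returned estimator exposes ``x_weights_``, ``x_loadings_`` and
    ``transform`` for the orthogonal score vectors.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if not 1 <= n_components <= min(p, n - 1):
        raise ClassifierError(
            f"n_components must lie in 1..min(p, n-1) = {min(p, n - 1)}, got {n_components}"
        )
    if np.any(X.std(axis=0) == 0):
        raise ClassifierError("zero-variance feature column in PLS input")
    est = PLSRegression(n_components=n_components, scale=False)
    est.fit(X, y)
    return est


@dataclass
class PLSLDAModel:
    """Everything needed to classify new subjects: the selected signature,
    the training scaling, the PLS projection and the LDA rule on scores."""

    classes: np.ndarray
    selected: np.ndarray
    scaling: ScalingModel
    pls: PLSRegression
    lda: LinearDiscriminantAnalysis
    n_features_in: int
    n_components: int


def fit_pls_lda(
    X_train: np.ndarray, y_train: np.ndarray, top_k: int, n_components: int
) -> PLSLDAModel:
    """Fit the full pipeline on a training partition only: autoscale ->
    LASSO top-K selection -> PLS projection -> equal-prior LDA on scores."""
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train)
    classes, _ = _encode_labels(y_train)
    if top_k < 1:
        raise ClassifierError("top_k must be >= 1 to fit a classifier")
    scaling = ScalingModel.fit(X_train)
    Xs = scaling.transform(X_train)
    selected = lasso_top_k(Xs, y_train, top_k)
    if selected.size == 0:
        raise ClassifierError("feature selection returned an empty signature")
    _, yy = _encode_labels(y_train)
    n_comp = min(n_components, selected.size, X_train.shape[0] - 1)
    pls = fit_pls(Xs[:, selected], yy, n_comp)
    scores = pls.transform(Xs[:, selected])
    lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    lda.fit(scores, y_train)
    return PLSLDAModel(
        classes=classes,
        selected=selected,
        scaling=scaling,
        pls=pls,
        lda=lda,
        n_features_in=X_train.shape[1],
        n_components=n_comp,
    )


def predict(model: PLSLDAModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic class calls and discriminant scores for new rows.

    A point exactly on the decision boundary (discriminant 0) is assigned to
    the first class label in sort order.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.n_features_in:
        raise ClassifierError(
            f"expected {model.n_features_in} features, got {X_new.shape[1]}"
        )
    scores = model.pls.transform(model.scaling.transform(X_new)[:, model.selected])
    d = model.lda.decision_function(scores)
    labels = np.where(d > 0, model.classes[1], model.classes[0])
    return labels, d


# ---------------------------------------------------------------------------
# cross-validation engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings: 250 repeats of a stratified 4-fold split on
    a balanced subsample, a top-16 signature, and automatic latent-component
    choice by inner 4-fold training-set MCE over 1..min(8, top_k)."""

    n_repeats: int = 250
    n_folds: int = 4
    top_k: int = 16
    n_components: int | str = "auto"
    balance: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.n_folds < 2:
            raise ClassifierError("need n_repeats >= 1 and n_folds >= 2")
        if self.top_k < 1:
            raise ClassifierError("top_k must be >= 1")
        if isinstance(self.n_components, str):
            if self.n_components != "auto":
                raise ClassifierError("n_components must be an integer or 'auto'")
        elif self.n_components < 1:
            raise ClassifierError("n_components must be >= 1")


@dataclass
class CVResult:
    """Per-evaluation error rates plus aggregates and selection frequencies."""

    per_eval: pd.DataFrame          # columns: repeat, fold, n_test, mce, sensitivity, specificity
    mce_mean: float
    sensitivity_mean: float
    specificity_mean: float
    selection_frequency: dict[str, float]
    balanced_class_counts: list[dict[str, int]]
    pos_label: str
    config: CVConfig

    @property
    def n_evaluations(self) -> int:
        return len(self.per_eval)

    def to_json_dict(self) -> dict:
        return {
            "mce_mean": self.mce_mean,
            "sens_mean": self.sensitivity_mean,
            "spec_mean": self.specificity_mean,
            "pos_label": self.pos_label,
            "n_evaluations": self.n_evaluations,
            "per_eval": self.per_eval.to_dict(orient="records"),
            "selection_frequency": self.selection_frequency,
        }


def _component_candidates(config: CVConfig) -> list[int]:
    return list(range(1, min(8, config.top_k) + 1))


def _choose_components(
    Xs_sel: np.ndarray, y: np.ndarray, candidates: Sequence[int], seed: int,
    n_folds: int = 4,
) -> int:
    """Inner stratified CV over the already-selected training features: the
    smallest candidate attaining the minimal inner MCE wins."""
    candidates = [a for a in candidates if a <= min(Xs_sel.shape[1], Xs_sel.shape[0] - 2)]
    if not candidates:
        return 1
    if len(candidates) == 1:
        return candidates[0]
    classes, yy = _encode_labels(y)
    n_folds = min(n_folds, np.bincount(np.searchsorted(classes, y)).min())
    if n_folds < 2:
        return candidates[0]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = np.zeros(len(candidates))
    for tr, te in skf.split(Xs_sel, y):
        mu = Xs_sel[tr].mean(axis=0)
        sd = Xs_sel[tr].std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xtr = (Xs_sel[tr] - mu) / sd
        Xte = (Xs_sel[te] - mu) / sd
        for i, a in enumerate(candidates):
            a_eff = min(a, Xtr.shape[0] - 1)
            pls = PLSRegression(n_components=a_eff, scale=False).fit(Xtr, yy[tr])
            lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            lda.fit(pls.transform(Xtr), y[tr])
            pred = lda.predict(pls.transform(Xte))
            errors[i] += np.sum(pred != y[te])
    return candidates[int(np.argmin(errors))]


def _fit_fold(
    X_tr: np.ndarray, y_tr: np.ndarray, config: CVConfig, inner_seed: int
) -> PLSLDAModel:
    """One training-fold fit; shares the selection between component choice
    and the final model so the LASSO path is traced once per fold."""
    classes, yy = _encode_labels(y_tr)
    scaling = ScalingModel.fit(X_tr)
    Xs = scaling.transform(X_tr)
    selected = lasso_top_k(Xs, y_tr, config.top_k)
    if selected.size == 0:
        raise ClassifierError("feature selection returned an empty signature")
    if config.n_components == "auto":
        a = _choose_components(Xs[:, selected], y_tr,
                               _component_candidates(config), inner_seed)
    else:
        a = int(config.n_components)
    a = min(a, selected.size, X_tr.shape[0] - 1)
    pls = fit_pls(Xs[:, selected], yy, a)
    lda = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
    lda.fit(pls.transform(Xs[:, selected]), y_tr)
    return PLSLDAModel(
        classes=classes, selected=selected, scaling=scaling, pls=pls, lda=lda,
        n_features_in=X_tr.shape[1], n_components=a,
    )


def _rates(y_true: np.ndarray, y_pred: np.ndarray, pos_label: str) -> tuple[float, float, float]:
    pos = y_true == pos_label
    neg = ~pos
    mce = float(np.mean(y_pred != y_true))
    sens = float(np.mean(y_pred[pos] == pos_label)) if pos.any() else float("nan")
    spec = float(np.mean(y_pred[neg] != pos_label)) if neg.any() else float("nan")
    return mce, sens, spec


def _as_table(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    arr = np.asarray(X, dtype=float)
    return arr, [f"X{j + 1}" for j in range(arr.shape[1])]


def balanced_repeated_cv(
    X, y, config: CVConfig, pos_label: str | None = None
) -> CVResult:
    """Balanced repeated stratified k-fold CV with fully nested selection.

    Per repeat, the majority class is subsampled without replacement down to
    the minority size (when ``config.balance``), the balanced set is split
    into stratified folds, and each fold evaluation refits scaling, LASSO
    selection, component choice and PLS-LDA on its own 3/4 training portion.
    One master seed drives the whole schedule, so equal seeds give identical
    results; MCE, sensitivity and specificity are averaged over all
    ``n_repeats * n_folds`` evaluations and each feature's selection
    frequency is the fraction of evaluations whose signature contained it.
    """
    Xa, names = _as_table(X)
    ya = np.asarray(y)
    classes, _ = _encode_labels(ya)
    counts = {c: int(np.sum(ya == c)) for c in classes}
    minority = min(classes, key=lambda c: counts[c])
    majority = max(classes, key=lambda c: counts[c])
    if counts[minority] < config.n_folds:
        raise ClassifierError(
            f"minority class {minority!r} has {counts[minority]} subjects, "
            f"fewer than n_folds={config.n_folds}"
        )
    if pos_label is None:
        pos_label = str(classes[0])
    elif pos_label not in classes:
        raise ClassifierError(f"pos_label {pos_label!r} not among classes {classes.tolist()}")

    master = np.random.SeedSequence(config.seed)
    repeat_seeds = master.spawn(config.n_repeats)
    records = []
    sel_counts = np.zeros(len(names))
    balanced_counts: list[dict[str, int]] = []
    min_idx = np.flatnonzero(ya == minority)
    maj_idx = np.flatnonzero(ya == majority)

    for r, child in enumerate(repeat_seeds):
        rng = np.random.default_rng(child)
        if config.balance and counts[majority] > counts[minority]:
            sub = rng.choice(maj_idx, size=counts[minority], replace=False)
            idx = np.sort(np.concatenate([min_idx, sub]))
        else:
            idx = np.arange(len(ya))
        Xb, yb = Xa[idx], ya[idx]
        balanced_counts.append({str(c): int(np.sum(yb == c)) for c in classes})
        skf = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True,
            random_state=int(rng.integers(2**31 - 1)),
        )
        for fold, (tr, te) in enumerate(skf.split(Xb, yb)):
            model = _fit_fold(Xb[tr], yb[tr], config, int(rng.integers(2**31 - 1)))
            pred, _ = predict(model, Xb[te])
            mce, sens, spec = _rates(yb[te], pred, pos_label)
            records.append((r, fold, len(te), mce, sens, spec))
            sel_counts[model.selected] += 1

    per_eval = pd.DataFrame(
        records, columns=["repeat", "fold", "n_test", "mce", "sensitivity", "specificity"]
    )
    n_eval = len(per_eval)
    return CVResult(
        per_eval=per_eval,
        mce_mean=float(per_eval["mce"].mean()),
        sensitivity_mean=float(per_eval["sensitivity"].mean()),
        specificity_mean=float(per_eval["specificity"].mean()),
        selection_frequency={names[j]: float(sel_counts[j] / n_eval) for j in range(len(names))},
        balanced_class_counts=balanced_counts,
        pos_label=str(pos_label),
        config=config,
    )


def ablation_cv(
    X, y, config: CVConfig, removed: Iterable[str] | Iterable[int],
    pos_label: str | None = None,
) -> CVResult:
    """The identical CV procedure after deleting the given feature columns.

    ``removed`` may hold column names (e.g. ``"IR89"``) or 0-based positions.
    Run under the same master seed as the unablated call, the subsample and
    fold schedule is identical, making the two results directly comparable.
    """
    if not isinstance(X, pd.DataFrame):
        arr, names = _as_table(X)
        X = pd.DataFrame(arr, columns=names)
    removed = list(removed)
    cols = list(X.columns)
    drop: list[str] = []
    for item in removed:
        if isinstance(item, (int, np.integer)):
            if not 0 <= item < len(cols):
                raise ClassifierError(f"removed column position {item} out of range")
            drop.append(cols[item])
        else:
            if item not in cols:
                raise ClassifierError(f"removed column {item!r} not in feature table")
            drop.append(str(item))
    if len(set(drop)) == len(cols):
        raise ClassifierError("cannot remove every feature column")
    return balanced_repeated_cv(X.drop(columns=sorted(set(drop))), y, config, pos_label)


@dataclass
class LoocvResult:
    overall_mce: float
    sensitivity: float
    specificity: float
    per_stage: pd.DataFrame  # columns: stage, n, errors, mce (mce NaN when n == 0)
    n_evaluations: int


def loocv_per_stage(
    X, y, stages: Sequence[str | None], top_k: int = 16,
    n_components: int | str = "auto", seed: int = 0,
    pos_label: str | None = None, balance: bool = True,
    stage_order: Sequence[str] | None = None,
) -> LoocvResult:
    """Leave-one-out CV on a balanced set, attributing errors to TNM stages.

    Every cancer subject entering the balanced set must carry a stage label;
    each held-out subject is classified by a model with fully nested
    selection fitted on the remaining subjects, and each held-out cancer
    subject's error is attributed to its stage. A stage with zero subjects is
    reported with ``n = 0`` and an undefined (NaN) MCE rather than 0.
    """
    Xa, _ = _as_table(X)
    ya = np.asarray(y)
    stages_a = np.asarray(stages, dtype=object)
    classes, _ = _encode_labels(ya)
    cancer_mask = ya == "cancer"
    if cancer_mask.any() and any(s is None for s in stages_a[cancer_mask]):
        raise ClassifierError("every cancer subject needs a stage label")
    counts = {c: int(np.sum(ya == c)) for c in classes}
    minority = min(classes, key=lambda c: counts[c])
    majority = max(classes, key=lambda c: counts[c])
    if pos_label is None:
        pos_label = str(classes[0])

    rng = np.random.default_rng(seed)
    if balance and counts[majority] > counts[minority]:
        sub = rng.choice(np.flatnonzero(ya == majority), size=counts[minority], replace=False)
        idx = np.sort(np.concatenate([np.flatnonzero(ya == minority), sub]))
    else:
        idx = np.arange(len(ya))
    Xb, yb, sb = Xa[idx], ya[idx], stages_a[idx]

    cfg = CVConfig(n_repeats=1, n_folds=4, top_k=top_k,
                   n_components=n_components, seed=seed)
    errors = np.zeros(len(yb), dtype=bool)
    preds = np.empty(len(yb), dtype=object)
    for i in range(len(yb)):
        tr = np.ones(len(yb), dtype=bool)
        tr[i] = False
        model = _fit_fold(Xb[tr], yb[tr], cfg, int(rng.integers(2**31 - 1)))
        pred, _ = predict(model, Xb[i])
        preds[i] = pred[0]
        errors[i] = pred[0] != yb[i]

    mce, sens, spec = _rates(yb, preds.astype(yb.dtype), pos_label)
    stage_labels = stage_order if stage_order is not None else sorted(
        {s for s in sb if s is not None}
    )
    rows = []
    for s in stage_labels:
        mask = sb == s
        n_s = int(mask.sum())
        err_s = int(errors[mask].sum())
        rows.append((s, n_s, err_s, err_s / n_s if n_s else float("nan")))
    per_stage = pd.DataFrame(rows, columns=["stage", "n", "errors", "mce"])
    return LoocvResult(
        overall_mce=mce, sensitivity=sens, specificity=spec,
        per_stage=per_stage, n_evaluations=len(yb),
    )


def augment_with_suvmax(X: pd.DataFrame, suvmax: pd.Series | Sequence[float]) -> pd.DataFrame:
    """Append SUVmax as one extra feature column named ``SUVmax``.

    Inside the CV engine the column is autoscaled per training fold together
    with the IRs and competes in LASSO selection like any region. Missing
    values are rejected with the offending subject ids.
    """
    suv = pd.Series(suvmax, index=X.index if hasattr(suvmax, "index") else X.index)
    if isinstance(suvmax, pd.Series):
        suv = suvmax.reindex(X.index)
    missing = suv.index[suv.isna()].tolist()
    if missing:
        raise ClassifierError(f"SUVmax missing for subjects: {missing}")
    out = X.copy()
    out["SUVmax"] = suv.astype(float).to_numpy()
    return out
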