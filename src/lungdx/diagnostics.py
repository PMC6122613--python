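"""ROC construction, AUC estimators, Youden cutoff, confusion-matrix
arithmetic, and the combined SUVmax / glutamate decision rule.

The relative glutamate concentration is lower in lung cancer than in benign
inflammation, so the glutamate test calls cancer when the value falls at or
below the cutoff (0.31 on the published ROC curve); PET calls a lesion
positive when SUVmax >= 2.5. Concordant calls settle the diagnosis; the two
discordant cells are tallied separately because cancers hide there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCCurve",
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "CombinedCallConfig",
    "roc_curve",
    "auc_empirical",
    "auc_binormal",
    "youden_cutoff",
    "metrics_from_confusion",
    "metrics_from_rates",
    "combined_rule",
    "stratified_metrics",
    "COMBINED_CATEGORIES",
]

Direction = Literal["lower", "higher"]

COMBINED_CATEGORIES = ("both-cancer", "both-benign", "discordant-PET+", "discordant-PET-")


class DiagnosticsError(ValueError):
    pass


@dataclass
class ROCCurve:
    """Threshold sweep for a continuous marker.

    ``direction == "lower"`` means a value at or below the threshold is a
    positive call. Thresholds ascend and include -inf/+inf sentinels, so the
    curve contains both the (sens 0, spec 1) and (sens 1, spec 0) endpoints.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    direction: Direction

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "sensitivity": self.sensitivity,
             "specificity": self.specificity}
        )


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts; fractional cells are allowed for expected-count arithmetic."""

    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise DiagnosticsError("confusion counts must be >= 0")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Confusion-derived rates; a rate whose denominator is zero is NaN."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    mce: float

    def to_dict(self) -> dict[str, float]:
        return {"sensitivity": self.sensitivity, "specificity": self.specificity,
                "ppv": self.ppv, "npv": self.npv, "mce": self.mce}


@dataclass(frozen=True)
class CombinedCallConfig:
    """Cutoffs of the two-test rule: PET positive iff SUVmax >= suv_cutoff,
    glutamate positive-for-cancer iff value <= glutamate_cutoff."""

    suv_cutoff: float = 2.5
    glutamate_cutoff: float = 0.31

    def __post_init__(self) -> None:
        if self.suv_cutoff <= 0 or self.glutamate_cutoff <= 0:
            raise DiagnosticsError("both cutoffs must be > 0")


def _validate_marker(values, labels) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if v.shape != lab.shape or v.ndim != 1:
        raise DiagnosticsError("values and labels must be matching 1-D vectors")
    if not np.all(np.isfinite(v)):
        raise DiagnosticsError("marker values must be finite")
    if lab.all() or not lab.any():
        raise DiagnosticsError("both classes must be present")
    return v, lab


def roc_curve(values, labels, direction: Direction = "lower") -> ROCCurve:
    """ROC over thresholds at midpoints between consecutive distinct marker
    values, plus -inf/+inf sentinels. ``labels`` are truth (True = positive
    class); with ``direction="lower"`` a subject is called positive when its
    value is <= the threshold."""
    v, lab = _validate_marker(values, labels)
    if direction not in ("lower", "higher"):
        raise DiagnosticsError("direction must be 'lower' or 'higher'")
    distinct = np.unique(v)
    mids = (distinct[:-1] + distinct[1:]) / 2 if distinct.size > 1 else np.empty(0)
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    n_pos = lab.sum()
    n_neg = (~lab).sum()
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, t in enumerate(thresholds):
        called = v <= t if direction == "lower" else v >= t
        sens[i] = np.sum(called & lab) / n_pos
        spec[i] = np.sum(~called & ~lab) / n_neg
    return ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                    direction=direction)


def auc_empirical(curve_or_values, labels=None, direction: Direction = "lower") -> float:
    """Trapezoidal area under the empirical ROC curve.

    Equals the Mann-Whitney probability that a random positive is ranked
    toward the positive side of a random negative, ties counted 1/2.
    """
    if isinstance(curve_or_values, ROCCurve):
        curve = curve_or_values
    else:
        curve = roc_curve(curve_or_values, labels, direction)
    fpr = 1.0 - curve.specificity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def auc_binormal(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Closed-form AUC for two normal marker distributions:
    Phi(|mean_pos - mean_neg| / sqrt(sd_pos^2 + sd_neg^2))."""
    if sd_pos < 0 or sd_neg < 0:
        raise DiagnosticsError("SDs must be >= 0")
    if sd_pos == 0 and sd_neg == 0:
        return 1.0 if mean_pos != mean_neg else 0.5
    return float(stats.norm.cdf(abs(mean_pos - mean_neg) / np.hypot(sd_pos, sd_neg)))


def youden_cutoff(curve: ROCCurve) -> tuple[float, float, float]:
    """Threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties are broken toward the smaller threshold. Returns (threshold,
    sensitivity, specificity) at the optimum.
    """
    j = curve.sensitivity + curve.specificity - 1.0
    order = np.argsort(curve.thresholds, kind="stable")
    best = order[int(np.argmax(j[order]))]
    return (float(curve.thresholds[best]), float(curve.sensitivity[best]),
            float(curve.specificity[best]))


def metrics_from_confusion(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """sens = TP/(TP+FN), spec = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), MCE = (FP+FN)/total; zero denominators give NaN."""
    if cm.total == 0:
        raise DiagnosticsError("all-zero confusion matrix")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("nan")

    return DiagnosticMetrics(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        mce=(cm.fp + cm.fn) / cm.total,
    )


def metrics_from_rates(
    sensitivity: float, specificity: float, n_pos: int, n_neg: int
) -> DiagnosticMetrics:
    """Predictive values implied by printed sensitivity/specificity at the
    given class sizes, via fractional expected confusion counts."""
    for r, name in ((sensitivity, "sensitivity"), (specificity, "specificity")):
        if not 0 <= r <= 1:
            raise DiagnosticsError(f"{name} must lie in [0, 1], got {r}")
    if n_pos <= 0 or n_neg <= 0:
        raise DiagnosticsError("class sizes must be > 0")
    cm = ConfusionMatrix(
        tp=sensitivity * n_pos,
        fn=(1 - sensitivity) * n_pos,
        tn=specificity * n_neg,
        fp=(1 - specificity) * n_neg,
    )
    return metrics_from_confusion(cm)


def combined_rule(
    suvmax: float, glutamate: float, config: CombinedCallConfig | None = None
) -> str:
    """Four-way category of the two-test rule.

    PET call positive iff SUVmax >= suv_cutoff; glutamate call positive for
    cancer iff value <= glutamate_cutoff (both boundaries inclusive for the
    cancer call). Concordant pairs give "both-cancer" / "both-benign";
    "discordant-PET+" is PET-positive with high glutamate, "discordant-PET-"
    PET-negative with low glutamate.
    """
    if config is None:
        config = CombinedCallConfig()
    if suvmax is None or glutamate is None:
        raise DiagnosticsError("both SUVmax and glutamate must be present")
    if not (np.isfinite(suvmax) and np.isfinite(glutamate)):
        raise DiagnosticsError("both SUVmax and glutamate must be finite")
    if suvmax < 0 or glutamate < 0:
        raise DiagnosticsError("marker values must be >= 0")
    pet_pos = suvmax >= config.suv_cutoff
    glu_pos = glutamate <= config.glutamate_cutoff
    if pet_pos and glu_pos:
        return "both-cancer"
    if not pet_pos and not glu_pos:
        return "both-benign"
    return "discordant-PET+" if pet_pos else "discordant-PET-"


def stratified_metrics(
    table: pd.DataFrame, config: CombinedCallConfig | None = None,
    discordant_call: Literal["glutamate", "pet"] = "glutamate",
) -> dict:
    """Per-category diagnostic metrics of the combined rule plus the
    discordant miss fraction.

    ``table`` needs columns ``group`` (``cancer`` is the positive truth),
    ``suvmax`` and ``glutamate``. Concordant categories carry their shared
    call; in the discordant categories the call follows ``discordant_call``
    (glutamate by default). The miss fraction is the share of cancer subjects
    in the two discordant categories whose call is benign. Empty categories
    report ``"not applicable"``.
    """
    if config is None:
        config = CombinedCallConfig()
    required = {"group", "suvmax", "glutamate"}
    if not required.issubset(table.columns):
        raise DiagnosticsError(f"table needs columns {sorted(required)}")
    if table[["suvmax", "glutamate"]].isna().any().any():
        bad = table.index[table[["suvmax", "glutamate"]].isna().any(axis=1)].tolist()
        raise DiagnosticsError(f"missing marker values for subjects: {bad}")

    categories = [
        combined_rule(row.suvmax, row.glutamate, config)
        for row in table.itertuples(index=False)
    ]
    cat = pd.Series(categories, index=table.index, name="category")
    truth_cancer = table["group"] == "cancer"

    def call_is_cancer(category: str, glu_pos: bool, pet_pos: bool) -> bool:
        if category == "both-cancer":
            return True
        if category == "both-benign":
            return False
        return glu_pos if discordant_call == "glutamate" else pet_pos

    glu_pos = table["glutamate"] <= config.glutamate_cutoff
    pet_pos = table["suvmax"] >= config.suv_cutoff
    called_cancer = pd.Series(
        [call_is_cancer(c, g, p) for c, g, p in zip(cat, glu_pos, pet_pos)],
        index=table.index,
    )

    per_category: dict[str, object] = {}
    counts: dict[str, int] = {}
    for c in COMBINED_CATEGORIES:
        mask = cat == c
        counts[c] = int(mask.sum())
        if counts[c] == 0:
            per_category[c] = "not applicable"
            continue
        tp = int((mask & truth_cancer & called_cancer).sum())
        fn = int((mask & truth_cancer & ~called_cancer).sum())
        fp = int((mask & ~truth_cancer & called_cancer).sum())
        tn = int((mask & ~truth_cancer & ~called_cancer).sum())
        per_category[c] = metrics_from_confusion(ConfusionMatrix(tp, fp, tn, fn))

    discordant = cat.isin(["discordant-PET+", "discordant-PET-"])
    n_disc_cancer = int((discordant & truth_cancer).sum())
    missed = int((discordant & truth_cancer & ~called_cancer).sum())
    miss_fraction = missed / n_disc_cancer if n_disc_cancer else float("nan")

    return {
        "per_category": per_category,
        "category_counts": counts,
        "discordant_cancer_n": n_disc_cancer,
        "discordant_miss_fraction": miss_fraction,
    }
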