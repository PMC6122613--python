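"""One-shot orchestration: generate (or read) a cohort, normalize, run the
univariate screen for the three pairwise group contrasts, the balanced
repeated CV with and without the glutamate region and with SUVmax appended,
the glutamate ROC with its Youden cutoff, and the combined SUVmax/glutamate
rule — writing every table to one output directory.

All randomness derives from a single master seed, so a rerun with the same
configuration produces byte-identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classifier import (
    CVConfig,
    CVResult,
    ablation_cv,
    augment_with_suvmax,
    balanced_repeated_cv,
)
from .diagnostics import (
    CombinedCallConfig,
    auc_empirical,
    roc_curve,
    stratified_metrics,
    youden_cutoff,
)
from .ir_features import extract_marker, normalize_cohort
from .synthetic_cohort import default_config, generate_cohort, read_cohort, write_cohort
from .univariate_stats import results_to_frame, univariate_screen, volcano_table

__all__ = ["RunConfig", "run_pipeline"]

PAIRWISE_CONTRASTS = (
    ("cancer", "inflammation"),
    ("inflammation", "control"),
    ("cancer", "control"),
)


class PipelineError(RuntimeError):
    """A stage failure, labelled with the stage that raised it."""


@dataclass
class RunConfig:
    out_dir: str | Path = "lungdx_run"
    seed: int = 0
    cohort_path: str | Path | None = None   # read instead of generating
    n_repeats: int = 250
    n_folds: int = 4
    top_k: int = 16
    n_components: int | str = "auto"
    suv_cutoff: float = 2.5
    glutamate_cutoff: float = 0.31
    glutamate_ir: int = 89

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(d["out_dir"])
        if d["cohort_path"] is not None:
            d["cohort_path"] = str(d["cohort_path"])
        return d


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write the report bundle.

    Outputs in ``config.out_dir``: ``config.json`` (echoed configuration),
    ``cohort.csv``, ``univariate_<a>_vs_<b>.csv`` and ``volcano_<a>_vs_<b>.csv``
    for the three contrasts, ``cv_result.json`` (base, glutamate-ablated, and
    SUVmax-augmented runs), ``roc.csv``, ``combined.json`` and ``run.log``.
    Returns the in-memory results keyed by the same names.
    """
    out = Path(config.out_dir)

    if config.cohort_path is not None:
        source = Path(config.cohort_path)
        if not source.exists():
            raise PipelineError(f"stage 'load_cohort' failed: no such file {source}")
        cohort = _stage("load_cohort")(read_cohort, source)
    else:
        cohort = _stage("generate")(generate_cohort, default_config(seed=config.seed))

    out.mkdir(parents=True, exist_ok=True)
    config_text = json.dumps(config.to_dict(), indent=2, sort_keys=True)
    (out / "config.json").write_text(config_text + "\n")
    config_hash = hashlib.sha256(config_text.encode()).hexdigest()

    write_cohort(cohort, out / "cohort.csv")
    normalized = _stage("normalize")(normalize_cohort, cohort)

    results: dict = {"cohort": cohort}
    for a, b in PAIRWISE_CONTRASTS:
        res = _stage("univariate")(univariate_screen, normalized, a, b)
        frame = results_to_frame(res)
        frame.to_csv(out / f"univariate_{a}_vs_{b}.csv", index=False)
        volcano_table(res).to_csv(out / f"volcano_{a}_vs_{b}.csv", index=False)
        results[f"univariate_{a}_vs_{b}"] = frame

    matrix = normalized.feature_matrix()
    labels = normalized.labels()
    pair = labels.isin(["cancer", "inflammation"])
    X_pair, y_pair = matrix[pair], labels[pair]
    cv_cfg = CVConfig(
        n_repeats=config.n_repeats, n_folds=config.n_folds, top_k=config.top_k,
        n_components=config.n_components, seed=config.seed,
    )
    glut_col = f"IR{config.glutamate_ir}"
    cv_runs: dict[str, CVResult] = {}
    cv_runs["cancer_vs_inflammation"] = _stage("cv")(
        balanced_repeated_cv, X_pair, y_pair, cv_cfg, "cancer")
    cv_runs["cancer_vs_inflammation_no_glutamate"] = _stage("cv_ablation")(
        ablation_cv, X_pair, y_pair, cv_cfg, [glut_col], "cancer")
    suv = pd.Series([s.suvmax for s in normalized.subjects],
                    index=[s.id for s in normalized.subjects])
    X_suv = _stage("augment_suvmax")(augment_with_suvmax, X_pair, suv[pair.index[pair]])
    cv_runs["cancer_vs_inflammation_with_suvmax"] = _stage("cv_suvmax")(
        balanced_repeated_cv, X_suv, y_pair, cv_cfg, "cancer")
    results["cv"] = cv_runs
    (out / "cv_result.json").write_text(
        json.dumps({k: v.to_json_dict() for k, v in cv_runs.items()},
                   indent=2, sort_keys=True, default=_json_default) + "\n"
    )

    marker = extract_marker(normalized, config.glutamate_ir)
    marker_pair = marker[marker["group"].isin(["cancer", "inflammation"])]
    curve = _stage("roc")(
        roc_curve, marker_pair["value"].to_numpy(),
        (marker_pair["group"] == "cancer").to_numpy(), "lower",
    )
    curve.to_frame().to_csv(out / "roc.csv", index=False)
    cutoff, sens, spec = youden_cutoff(curve)
    auc = auc_empirical(curve)
    results["roc"] = {"curve": curve, "auc": auc, "youden_cutoff": cutoff,
                      "sensitivity": sens, "specificity": spec}

    combined_table = pd.DataFrame(
        {"group": marker_pair["group"],
         "suvmax": suv.loc[marker_pair.index],
         "glutamate": marker_pair["value"]}
    )
    combined = _stage("combined")(
        stratified_metrics, combined_table,
        CombinedCallConfig(config.suv_cutoff, config.glutamate_cutoff),
    )
    results["combined"] = combined
    combined_out = {
        "auc_empirical": auc,
        "youden": {"cutoff": cutoff, "sensitivity": sens, "specificity": spec},
        "category_counts": combined["category_counts"],
        "per_category": {
            k: (v if isinstance(v, str) else v.to_dict())
            for k, v in combined["per_category"].items()
        },
        "discordant_cancer_n": combined["discordant_cancer_n"],
        "discordant_miss_fraction": combined["discordant_miss_fraction"],
    }
    (out / "combined.json").write_text(
        json.dumps(combined_out, indent=2, sort_keys=True, default=_json_default) + "\n"
    )

    import sklearn
    import scipy

    log_lines = [
        f"lungdx {__version__}",
        f"numpy {np.__version__}, scipy {scipy.__version__}, "
        f"pandas {pd.__version__}, scikit-learn {sklearn.__version__}",
        f"master seed: {config.seed}",
        f"config sha256: {config_hash}",
        f"subjects: {cohort.group_counts()}",
    ]
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    results["config_hash"] = config_hash
    return results
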