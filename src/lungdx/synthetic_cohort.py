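"""Synthetic cohorts emulating the published group structure of the lung-cancer
vs lung-inflammation plasma NMR study.

The study population (269 lung cancer, 108 inflammation, 347 controls) is not
publicly deposited, so every downstream stage of the pipeline is exercised on
cohorts drawn here. The generator reproduces the printed group-level facts:
group sizes, the TNM stage table of the cancer arm, per-group SUVmax moments,
and per-group relative glutamate (IR89) moments, plus configurable effects in
further integration regions (IRs). All remaining IRs are sampled from a common
background distribution shared by every group, so that by construction only
the configured effect regions carry class signal.

Relative concentrations are non-negative and strongly right-skewed (the cancer
group's coefficient of variation is close to 1), so marker values are drawn
from a gamma distribution moment-matched to the printed mean and SD rather
than from a truncated normal, which would distort both moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSpec",
    "EffectSpec",
    "CohortConfig",
    "Subject",
    "Cohort",
    "gamma_params",
    "sample_positive",
    "generate_cohort",
    "default_config",
    "write_cohort",
    "read_cohort",
    "GROUP_LABELS",
]

GROUP_LABELS = ("cancer", "inflammation", "control")

#: TNM stage counts of the cancer arm (sums to 269).
DEFAULT_STAGE_DISTRIBUTION: dict[str, int] = {
    "IA": 53,
    "IB": 22,
    "IIA": 16,
    "IIB": 16,
    "IIIA": 63,
    "IIIB": 28,
    "IV": 71,
}


class CohortConfigError(ValueError):
    """Raised for invalid generator parameters."""


class CohortParseError(ValueError):
    """Raised when a cohort CSV violates the expected schema."""


@dataclass(frozen=True)
class GroupSpec:
    """Printed summary statistics of one study group.

    Glutamate moments are moments of the *relative* IR89 concentration
    (dimensionless fraction of the total integrated area). SUVmax moments are
    absent for controls, who were never PET-imaged. The stage distribution is
    given only for the cancer group and its counts must sum to ``n``.
    """

    name: str
    n: int
    glutamate_mean: float
    glutamate_sd: float
    suvmax_mean: float | None = None
    suvmax_sd: float | None = None
    stage_distribution: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise CohortConfigError(f"group {self.name!r}: n must be > 0")
        if self.glutamate_mean <= 0:
            raise CohortConfigError(f"group {self.name!r}: glutamate mean must be > 0")
        if self.glutamate_sd < 0:
            raise CohortConfigError(f"group {self.name!r}: glutamate SD must be >= 0")
        if (self.suvmax_mean is None) != (self.suvmax_sd is None):
            raise CohortConfigError(
                f"group {self.name!r}: SUVmax mean and SD must be given together"
            )
        if self.suvmax_mean is not None:
            if self.suvmax_mean <= 0 or self.suvmax_sd < 0:
                raise CohortConfigError(f"group {self.name!r}: invalid SUVmax moments")
        if self.stage_distribution is not None:
            if any(c < 0 for c in self.stage_distribution.values()):
                raise CohortConfigError(f"group {self.name!r}: negative stage count")
            total = sum(self.stage_distribution.values())
            if total != self.n:
                raise CohortConfigError(
                    f"group {self.name!r}: stage counts sum to {total}, expected {self.n}"
                )

    @property
    def has_suvmax(self) -> bool:
        return self.suvmax_mean is not None


@dataclass(frozen=True)
class EffectSpec:
    """A secondary discriminating IR with per-group relative-concentration moments.

    ``moments`` maps each group name to a ``(mean, sd)`` pair on the relative
    scale. IR15 (tyrosine) and IR96 (alanine/isoleucine/lysine) are the
    canonical secondary discriminators of the cancer-vs-inflammation contrast.
    """

    ir_index: int
    moments: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for group, (mean, sd) in self.moments.items():
            if mean <= 0:
                raise CohortConfigError(
                    f"effect IR{self.ir_index}, group {group!r}: mean must be > 0"
                )
            if sd < 0:
                raise CohortConfigError(
                    f"effect IR{self.ir_index}, group {group!r}: SD must be >= 0"
                )


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of a synthetic cohort draw.

    Parameters
    ----------
    groups
        One :class:`GroupSpec` per study group.
    effects
        Secondary discriminating IRs beyond the glutamate region.
    n_ir
        Number of integration regions (110 for the published segmentation).
    glutamate_ir
        Index of the region holding the per-group glutamate moments (IR89).
    background_mean, background_sd
        Gamma moments of the i.i.d. background draws used to apportion the
        non-effect IRs. Shared by all groups, so background regions carry no
        class signal; only their relative proportions matter.
    total_area_mean, total_area_sd
        Moments of the per-subject raw total integrated area. The generator
        emits raw (un-normalized) integrals; dividing by the total area
        recovers the configured relative concentrations exactly.
    suv_glutamate_rho
        Gaussian-copula rank-dependence between SUVmax and glutamate within a
        class. 0 (the default) means conditional independence given the class;
        the published study reports only marginal moments.
    seed
        Master seed; a fixed seed reproduces the cohort exactly.
    """

    groups: Sequence[GroupSpec]
    effects: Sequence[EffectSpec] = ()
    n_ir: int = 110
    glutamate_ir: int = 89
    background_mean: float = 1.0
    background_sd: float = 2.0
    total_area_mean: float = 100.0
    total_area_sd: float = 10.0
    suv_glutamate_rho: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise CohortConfigError("at least one group is required")
        names = [g.name for g in self.groups]
        if len(set(names)) != len(names):
            raise CohortConfigError("duplicate group names")
        if not 1 <= self.glutamate_ir <= self.n_ir:
            raise CohortConfigError(
                f"glutamate IR index {self.glutamate_ir} outside 1..{self.n_ir}"
            )
        indices = [e.ir_index for e in self.effects]
        if len(set(indices)) != len(indices):
            raise CohortConfigError("effect IR indices must be distinct")
        for e in self.effects:
            if not 1 <= e.ir_index <= self.n_ir:
                raise CohortConfigError(
                    f"effect IR index {e.ir_index} outside 1..{self.n_ir}"
                )
            if e.ir_index == self.glutamate_ir:
                raise CohortConfigError(
                    f"effect IR{e.ir_index} collides with the glutamate region"
                )
            missing = [g.name for g in self.groups if g.name not in e.moments]
            if missing:
                raise CohortConfigError(
                    f"effect IR{e.ir_index} lacks moments for groups {missing}"
                )
        if self.background_mean <= 0 or self.background_sd < 0:
            raise CohortConfigError("invalid background moments")
        if self.total_area_mean <= 0 or self.total_area_sd < 0:
            raise CohortConfigError("invalid total-area moments")
        if not -1.0 < self.suv_glutamate_rho < 1.0:
            raise CohortConfigError("suv_glutamate_rho must lie in (-1, 1)")


@dataclass
class Subject:
    id: str
    group: str
    stage: str | None
    suvmax: float | None
    ir_values: np.ndarray

    def __post_init__(self) -> None:
        self.ir_values = np.asarray(self.ir_values, dtype=float)
        if np.any(self.ir_values < 0) or not np.all(np.isfinite(self.ir_values)):
            raise CohortConfigError(f"subject {self.id!r}: IR values must be finite and >= 0")
        if (self.group == "cancer") != (self.stage is not None):
            raise CohortConfigError(
                f"subject {self.id!r}: stage must be present iff group is 'cancer'"
            )
        if self.suvmax is not None and self.suvmax < 0:
            raise CohortConfigError(f"subject {self.id!r}: SUVmax must be >= 0")


@dataclass
class Cohort:
    """A list of subjects plus a flag stating whether IR values are relative
    concentrations (each subject's values summing to 1) or raw integrals."""

    subjects: list[Subject]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.normalized:
            for s in self.subjects:
                total = float(np.sum(s.ir_values))
                if abs(total - 1.0) > 1e-9:
                    raise CohortConfigError(
                        f"subject {s.id!r}: normalized cohort but values sum to {total!r}"
                    )

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_ir(self) -> int:
        return len(self.subjects[0].ir_values) if self.subjects else 0

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.subjects:
            counts[s.group] = counts.get(s.group, 0) + 1
        return counts

    def feature_matrix(self) -> pd.DataFrame:
        """Subjects x IRs table with columns IR1..IRn, indexed by subject id."""
        cols = [f"IR{i}" for i in range(1, self.n_ir + 1)]
        data = np.vstack([s.ir_values for s in self.subjects])
        return pd.DataFrame(data, index=[s.id for s in self.subjects], columns=cols)

    def labels(self) -> pd.Series:
        return pd.Series([s.group for s in self.subjects],
                         index=[s.id for s in self.subjects], name="group")

    def to_frame(self) -> pd.DataFrame:
        """Flat table in the cohort CSV column layout."""
        records = []
        for s in self.subjects:
            rec: dict[str, object] = {
                "subject_id": s.id,
                "group": s.group,
                "stage": s.stage if s.stage is not None else "",
                "suvmax": s.suvmax if s.suvmax is not None else np.nan,
            }
            for i, v in enumerate(s.ir_values, start=1):
                rec[f"IR{i}"] = v
            records.append(rec)
        return pd.DataFrame.from_records(records)


def gamma_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched gamma (shape, scale): shape = (mean/sd)^2, scale = sd^2/mean."""
    if mean <= 0:
        raise CohortConfigError("mean must be > 0")
    if sd <= 0:
        raise CohortConfigError("sd must be > 0 for a non-degenerate gamma")
    return (mean / sd) ** 2, sd**2 / mean


def sample_positive(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` non-negative values with population mean ``mean`` and SD ``sd``.

    Uses a gamma distribution with shape ``(mean/sd)**2`` and scale
    ``sd**2/mean`` so both moments are matched exactly; ``sd == 0`` yields the
    degenerate constant sample.
    """
    if mean <= 0:
        raise CohortConfigError(f"mean must be > 0, got {mean}")
    if sd < 0:
        raise CohortConfigError(f"sd must be >= 0, got {sd}")
    if n < 1:
        raise CohortConfigError(f"n must be >= 1, got {n}")
    if sd == 0:
        return np.full(n, float(mean))
    shape, scale = gamma_params(mean, sd)
    return rng.gamma(shape, scale, size=n)


def _copula_pair(
    mean_a: float, sd_a: float, mean_b: float, sd_b: float,
    rho: float, n: int, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two gamma marginals coupled through a Gaussian copula with correlation rho."""
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = stats.norm.cdf(z)
    ka, ta = gamma_params(mean_a, sd_a)
    kb, tb = gamma_params(mean_b, sd_b)
    return stats.gamma.ppf(u[:, 0], ka, scale=ta), stats.gamma.ppf(u[:, 1], kb, scale=tb)


# Subjects whose configured effect regions would together exceed this share of
# the total area are redrawn; with the study's parameters this is vanishingly
# rare and leaves the marker moments essentially untouched.
_MAX_EFFECT_FRACTION = 0.99
_MAX_REDRAWS = 1000


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a cohort of raw (un-normalized) IR integrals under ``config``.

    Per subject, the effect regions (glutamate plus any :class:`EffectSpec`)
    are drawn on the relative-concentration scale; the remaining background
    regions share the leftover area in proportion to i.i.d. gamma draws; the
    whole vector is then multiplied by a subject-specific total area. Total-
    area normalization therefore recovers the configured relative values of
    the effect regions exactly.
    """
    rng = np.random.default_rng(config.seed)
    effect_idx = [config.glutamate_ir] + [e.ir_index for e in config.effects]
    bg_idx = [i for i in range(1, config.n_ir + 1) if i not in set(effect_idx)]
    if not bg_idx:
        raise CohortConfigError("at least one background IR is required")

    subjects: list[Subject] = []
    for group in config.groups:
        n = group.n
        if group.has_suvmax and config.suv_glutamate_rho != 0.0:
            glut, suv = _copula_pair(
                group.glutamate_mean, group.glutamate_sd,
                group.suvmax_mean, group.suvmax_sd,
                config.suv_glutamate_rho, n, rng,
            )
        else:
            glut = sample_positive(group.glutamate_mean, group.glutamate_sd, n, rng)
            suv = (
                sample_positive(group.suvmax_mean, group.suvmax_sd, n, rng)
                if group.has_suvmax else None
            )
        effect_vals = {config.glutamate_ir: glut}
        for e in config.effects:
            mean, sd = e.moments[group.name]
            effect_vals[e.ir_index] = sample_positive(mean, sd, n, rng)

        # Redraw the (rare) subjects whose effect values would leave no room
        # for the background regions.
        totals = np.sum(np.column_stack(list(effect_vals.values())), axis=1)
        for attempt in range(_MAX_REDRAWS):
            bad = np.flatnonzero(totals >= _MAX_EFFECT_FRACTION)
            if bad.size == 0:
                break
            for j in bad:
                effect_vals[config.glutamate_ir][j] = sample_positive(
                    group.glutamate_mean, group.glutamate_sd, 1, rng)[0]
                for e in config.effects:
                    mean, sd = e.moments[group.name]
                    effect_vals[e.ir_index][j] = sample_positive(mean, sd, 1, rng)[0]
            totals = np.sum(np.column_stack(list(effect_vals.values())), axis=1)
        else:
            raise CohortConfigError(
                "effect moments leave no area for background regions; "
                "configured relative means are too large"
            )

        bg = sample_positive(config.background_mean, config.background_sd,
                             n * len(bg_idx), rng).reshape(n, len(bg_idx))
        bg_share = bg / bg.sum(axis=1, keepdims=True) * (1.0 - totals)[:, None]
        area = sample_positive(config.total_area_mean, config.total_area_sd, n, rng)

        stages: list[str | None]
        if group.stage_distribution is not None:
            pool = [s for s, c in group.stage_distribution.items() for _ in range(c)]
            stages = list(rng.permutation(np.array(pool, dtype=object)))
        else:
            stages = [None] * n

        for j in range(n):
            rel = np.empty(config.n_ir)
            for idx, vals in effect_vals.items():
                rel[idx - 1] = vals[j]
            rel[np.array(bg_idx) - 1] = bg_share[j]
            subjects.append(
                Subject(
                    id=f"{group.name}_{j + 1:04d}",
                    group=group.name,
                    stage=stages[j],
                    suvmax=float(suv[j]) if suv is not None else None,
                    ir_values=rel * area[j],
                )
            )
    return Cohort(subjects=subjects, normalized=False)


def default_config(
    seed: int = 0,
    effects: Sequence[EffectSpec] | None = None,
    suv_glutamate_rho: float = 0.0,
) -> CohortConfig:
    """The study conditions: printed group sizes, stage table, SUVmax and
    glutamate moments, plus modest secondary effects in IR15 and IR96."""
    groups = [
        GroupSpec("cancer", 269, 0.159, 0.156, 12.1, 7.6, DEFAULT_STAGE_DISTRIBUTION),
        GroupSpec("inflammation", 108, 0.485, 0.237, 4.3, 2.8),
        GroupSpec("control", 347, 0.152, 0.113),
    ]
    if effects is None:
        effects = (
            EffectSpec(15, {"cancer": (0.010, 0.004), "inflammation": (0.014, 0.005),
                            "control": (0.012, 0.004)}),
            EffectSpec(96, {"cancer": (0.020, 0.008), "inflammation": (0.028, 0.010),
                            "control": (0.024, 0.008)}),
        )
    return CohortConfig(groups=groups, effects=tuple(effects),
                        suv_glutamate_rho=suv_glutamate_rho, seed=seed)


# ---------------------------------------------------------------------------
# CSV persistence
# ---------------------------------------------------------------------------

def _csv_columns(n_ir: int) -> list[str]:
    return ["subject_id", "group", "stage", "suvmax"] + [f"IR{i}" for i in range(1, n_ir + 1)]


def write_cohort(cohort: Cohort, destination: str | Path) -> None:
    """Write the cohort CSV (``subject_id,group,stage,suvmax,IR1,...,IRn``).

    Empty cells encode an inapplicable stage or SUVmax; floats are written at
    full round-trip precision.
    """
    frame = cohort.to_frame()
    frame.to_csv(destination, index=False, float_format="%.17g")


def read_cohort(source: str | Path, n_ir: int = 110) -> Cohort:
    """Read a cohort CSV; the normalized flag is inferred from the row sums."""
    try:
        frame = pd.read_csv(source, dtype={"subject_id": str, "group": str, "stage": str},
                            float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise CohortParseError(f"cannot parse cohort file {source}: {exc}") from exc
    expected = _csv_columns(n_ir)
    if list(frame.columns) != expected:
        missing = [c for c in expected if c not in frame.columns]
        extra = [c for c in frame.columns if c not in expected]
        raise CohortParseError(
            f"cohort file {source}: bad column layout "
            f"(missing {missing or 'none'}, unexpected {extra or 'none'})"
        )
    if len(frame) == 0:
        raise CohortParseError(f"cohort file {source}: no subject rows")

    ir_cols = expected[4:]
    subjects: list[Subject] = []
    for row_num, row in enumerate(frame.itertuples(index=False), start=2):
        rec = dict(zip(expected, row))
        group = rec["group"]
        if group not in GROUP_LABELS:
            raise CohortParseError(
                f"cohort file {source}: unknown group label {group!r} "
                f"at row {row_num}, column 'group'"
            )
        values = np.empty(n_ir)
        for k, col in enumerate(ir_cols):
            v = rec[col]
            try:
                values[k] = float(v)
            except (TypeError, ValueError):
                raise CohortParseError(
                    f"cohort file {source}: non-numeric IR value {v!r} "
                    f"at row {row_num}, column {col!r}"
                ) from None
            if not np.isfinite(values[k]):
                raise CohortParseError(
                    f"cohort file {source}: non-finite IR value "
                    f"at row {row_num}, column {col!r}"
                )
        stage = rec["stage"] if isinstance(rec["stage"], str) and rec["stage"] else None
        suv = rec["suvmax"]
        suvmax = None if suv is None or (isinstance(suv, float) and np.isnan(suv)) else float(suv)
        subjects.append(Subject(rec["subject_id"], group, stage, suvmax, values))

    normalized = all(abs(float(np.sum(s.ir_values)) - 1.0) <= 1e-9 for s in subjects)
    return Cohort(subjects=subjects, normalized=normalized)
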