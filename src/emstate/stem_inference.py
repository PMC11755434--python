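"""Relating stemness to the E/M phenotype: OLS, classification, ANOVA.

The organ-specific STEM score of each cell is regressed on its mean MES and
mean EPITH scores (ordinary least squares, per tissue class), cells are
classified stem vs mature by the sign of their STEM score, and score
differences between annotated groups are tested with one-way fixed-effects
ANOVA.  Significance stars follow a deliberately nonstandard ladder used for
the bar plots: * p<0.05, ** p<0.001, *** p<0.0001, **** p<0.00001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .data_model_io import CellMetadata, ValidationError

METRICS = ("mean_mes", "mean_epith", "mes_epith_ratio")

#: (threshold, stars) ladder, checked in order; p >= 0.05 is "ns"
STAR_LADDER = (
    (0.00001, "****"),
    (0.0001, "***"),
    (0.001, "**"),
    (0.05, "*"),
)


def stars_for_p(p: float) -> str:
    """Map a p-value to its significance stars (pure step function)."""
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise ValidationError(f"p-value out of [0,1]: {p}")
    for threshold, stars in STAR_LADDER:
        if p < threshold:
            return stars
    return "ns"


@dataclass
class RegressionResult:
    """OLS of stem_score on [1, mean_mes, mean_epith] for one tissue class."""

    tissue_class: str
    beta0: float
    beta_mes: float
    beta_epith: float
    se: dict[str, float]
    t: dict[str, float]
    p: dict[str, float]
    r_squared: float
    n: int
    r_stem_mes: float
    p_stem_mes: float
    r_stem_epith: float
    p_stem_epith: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("regression requires n >= 3")


@dataclass
class GroupComparison:
    """One-way ANOVA of a score metric across annotated groups."""

    metric: str
    groups: list[str]
    group_means: dict[str, float]
    group_se: dict[str, float]
    group_n: dict[str, int]
    f_stat: float
    p_value: float
    stars: str


def fit_stem_regression(scores: pd.DataFrame, meta: CellMetadata,
                        tissue_class: str) -> RegressionResult:
    """OLS stem_score ~ mean_mes + mean_epith over cells of one tissue class.

    Observations are individual cells.  Also reports the pairwise Pearson
    correlations r(stem, mes) and r(stem, epith).  Nearly collinear
    predictors (|r| > 0.9999) are rejected as unidentifiable.
    """
    mask = meta.column("tissue_class").reindex(scores.index) == tissue_class
    sub = scores.loc[mask.fillna(False)].dropna(subset=["stem_score"])
    n = len(sub)
    if n < 3:
        raise ValidationError(
            f"tissue class {tissue_class!r}: {n} cells with stem_score; "
            "need >= 3"
        )
    mes = sub["mean_mes"].to_numpy()
    epith = sub["mean_epith"].to_numpy()
    stem = sub["stem_score"].to_numpy()
    if mes.std() > 0 and epith.std() > 0:
        r_pred = scipy.stats.pearsonr(mes, epith).statistic
        if abs(r_pred) > 0.9999:
            raise ValidationError(
                f"tissue class {tissue_class!r}: mean_mes and mean_epith are "
                f"collinear (r = {r_pred:.6f}); coefficients unidentifiable"
            )
    X = sm.add_constant(np.column_stack([mes, epith]))
    fit = sm.OLS(stem, X).fit()
    names = ("const", "mean_mes", "mean_epith")
    r_mes = scipy.stats.pearsonr(stem, mes)
    r_epith = scipy.stats.pearsonr(stem, epith)
    return RegressionResult(
        tissue_class=tissue_class,
        beta0=float(fit.params[0]),
        beta_mes=float(fit.params[1]),
        beta_epith=float(fit.params[2]),
        se=dict(zip(names, map(float, fit.bse))),
        t=dict(zip(names, map(float, fit.tvalues))),
        p=dict(zip(names, map(float, fit.pvalues))),
        r_squared=float(fit.rsquared),
        n=n,
        r_stem_mes=float(r_mes.statistic),
        p_stem_mes=float(r_mes.pvalue),
        r_stem_epith=float(r_epith.statistic),
        p_stem_epith=float(r_epith.pvalue),
    )


def classify_stem_mature(scores: pd.DataFrame, meta: CellMetadata,
                         mode: str = "threshold",
                         annotation_column: str = "truth_state"
                         ) -> pd.DataFrame:
    """Label each cell stem or mature.

    ``threshold`` mode uses the sign of the organ-specific STEM score:
    positive -> stem, negative -> mature; an exact zero (excluded by the
    sign rule) is deterministically assigned mature with a boundary flag.
    ``annotation`` mode passes through an existing stem/mature metadata
    column.
    """
    if mode == "annotation":
        ann = meta.column(annotation_column).reindex(scores.index)
        if ann.isna().any():
            raise ValidationError(
                f"annotation column {annotation_column!r} missing for some cells"
            )
        return pd.DataFrame({"label": ann.astype(str), "flag": ""},
                            index=scores.index)
    if mode != "threshold":
        raise ValueError("mode must be 'annotation' or 'threshold'")
    stem = scores["stem_score"]
    if stem.isna().any():
        raise ValidationError("threshold mode requires stem_score for all cells")
    label = np.where(stem > 0, "stem", "mature")
    flag = np.where(stem == 0, "boundary_zero", "")
    return pd.DataFrame({"label": label, "flag": flag}, index=scores.index)


def compare_groups(scores: pd.DataFrame, meta: CellMetadata,
                   metric: str, group_by: str) -> GroupComparison:
    """One-way fixed-effects ANOVA of ``metric`` across groups.

    Requires >= 2 groups with >= 2 cells each.  Zero within-group variance
    is allowed; if every observation is identical across all groups the test
    degenerates to F = 0, p = 1.
    """
    if metric not in scores.columns:
        raise ValidationError(f"unknown metric {metric!r}")
    groups = meta.column(group_by).reindex(scores.index)
    samples = {str(label): scores.loc[idx, metric].dropna().to_numpy()
               for label, idx in scores.groupby(groups).groups.items()}
    samples = dict(sorted(samples.items()))
    if len(samples) < 2:
        raise ValidationError("ANOVA requires >= 2 groups")
    for label, vals in samples.items():
        if len(vals) < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 cells")
    values = list(samples.values())
    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        f_stat, p_value = 0.0, 1.0
    else:
        res = scipy.stats.f_oneway(*values)
        f_stat, p_value = float(res.statistic), float(res.pvalue)
        if not np.isfinite(f_stat):  # all variance between groups
            f_stat, p_value = np.inf, 0.0
    return GroupComparison(
        metric=metric,
        groups=list(samples),
        group_means={k: float(v.mean()) for k, v in samples.items()},
        group_se={k: float(v.std(ddof=1) / np.sqrt(len(v)))
                  for k, v in samples.items()},
        group_n={k: len(v) for k, v in samples.items()},
        f_stat=f_stat,
        p_value=p_value,
        stars=stars_for_p(min(max(p_value, 0.0), 1.0)),
    )
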