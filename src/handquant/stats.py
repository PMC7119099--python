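"""Cohort statistics: linear age/BMI/disease models, adjusted group
differences, percent change over an age window, and decade-wise ANOVA.

The analysis mirrors a cross-sectional three-group design (Pso as control
group, PsA, RA), stratified by sex.  Responses (hand volume V_H, relative
muscle volume V_M^rel, fat measures) are modeled by ordinary least squares
on age (or age^3), optionally BMI, and diagnosis as a categorical factor.
Records without BMI are dropped only when BMI is in the model (the
"BMI-available subset" semantics); dropping is never silent — the fitted
model reports the n used.

The adjusted group difference Δ is the model-predicted mean difference
between two diagnoses averaged over the age window; in the default
parallel-slopes model this equals the factor-coefficient difference, and
its p-value comes from the corresponding linear contrast.

For an age-sensitive comparison the window 40-80 is partitioned into
decades [40,50), [50,60), [60,70), [70,80]; per decade a one-way ANOVA
across diagnoses is followed by Tukey HSD pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import DataError, ModelError

__all__ = [
    "DIAGNOSES",
    "validate_cohort",
    "ModelSpec",
    "FittedModel",
    "GroupDifference",
    "DecadeResult",
    "DecadeAnovaResult",
    "fit_model",
    "group_difference",
    "percent_change_over_window",
    "decade_anova",
]

DIAGNOSES = ("Pso", "PsA", "RA")
SEXES = ("male", "female")
DECADES: tuple[tuple[float, float], ...] = ((40, 50), (50, 60), (60, 70), (70, 80))


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Check the cohort table schema and record-level invariants."""
    needed = {"id", "sex", "diagnosis", "age", "vh", "vmrel"}
    missing = needed - set(df.columns)
    if missing:
        raise DataError(f"cohort table lacks columns {sorted(missing)}")
    if not df["sex"].isin(SEXES).all():
        raise DataError("sex must be 'male' or 'female'")
    if not df["diagnosis"].isin(DIAGNOSES).all():
        raise DataError(f"diagnosis must be one of {DIAGNOSES}")
    if not df["age"].between(0, 120, inclusive="neither").all():
        raise DataError("ages must lie in (0, 120)")
    if "vm" in df.columns:
        ok = np.isclose(df["vmrel"], df["vm"] / df["vh"], atol=1e-9, rtol=1e-9)
        if not ok.all():
            raise DataError("vmrel != vm/vh for some records")
    return df


@dataclass(frozen=True)
class ModelSpec:
    """One linear-model specification.

    ``age_term`` is ``"age"`` or ``"age3"`` (age cubed); ``group`` adds
    diagnosis as a categorical factor with ``reference`` as baseline;
    ``sex`` restricts to one stratum (stratified fits never pool sexes);
    ``interaction`` adds an age x diagnosis interaction (then Δ is the
    window-averaged predicted difference rather than a single coefficient).
    """

    response: str = "vmrel"
    age_term: str = "age"
    include_bmi: bool = False
    group: str | None = "diagnosis"
    sex: str | None = None
    window: tuple[float, float] = (20.0, 80.0)
    reference: str = "Pso"
    interaction: bool = False

    def __post_init__(self) -> None:
        if self.age_term not in ("age", "age3"):
            raise DataError(f"unknown age term {self.age_term!r}")
        if self.group not in (None, "diagnosis"):
            raise DataError(f"unknown group factor {self.group!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise DataError(f"unknown sex stratum {self.sex!r}")
        if not self.window[0] < self.window[1]:
            raise DataError("age window must satisfy lo < hi")
        if self.reference not in DIAGNOSES:
            raise DataError(f"reference must be one of {DIAGNOSES}")


@dataclass(frozen=True)
class FittedModel:
    """OLS fit plus the spec and data it used."""

    spec: ModelSpec
    result: object                 # statsmodels RegressionResults
    data: pd.DataFrame             # records actually used
    exog_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return int(self.result.nobs)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def r_squared(self) -> float:
        return float(self.result.rsquared)

    def summary_dict(self) -> dict:
        res = self.result
        return {
            "response": self.spec.response,
            "n": self.n,
            "r_squared": self.r_squared,
            "coefficients": {
                k: {
                    "estimate": float(res.params[k]),
                    "se": float(res.bse[k]),
                    "p": float(res.pvalues[k]),
                }
                for k in res.params.index
            },
        }


def _design_row(
    spec: ModelSpec,
    exog_names: Sequence[str],
    age: float,
    diagnosis: str | None,
    covariate_means: dict,
) -> np.ndarray:
    """One design-matrix row for prediction at a given age/diagnosis."""
    age_val = age**3 if spec.age_term == "age3" else age
    row = []
    for name in exog_names:
        if name == "Intercept":
            row.append(1.0)
        elif name == "age_term":
            row.append(age_val)
        elif name == "bmi":
            row.append(covariate_means.get("bmi", 0.0))
        elif name.startswith("diag_"):
            level = name[len("diag_") :]
            base = 1.0 if diagnosis == level else 0.0
            if diagnosis is None:
                base = covariate_means.get(name, 0.0)  # population-average level share
            row.append(base)
        elif name.startswith("agex_"):
            level = name[len("agex_") :]
            ind = 1.0 if diagnosis == level else 0.0
            if diagnosis is None:
                ind = covariate_means.get(f"diag_{level}", 0.0)
            row.append(ind * age_val)
        else:
            raise ModelError(f"unknown design column {name!r}")
    return np.asarray(row)


def _build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series]:
    X = pd.DataFrame(index=df.index)
    X["Intercept"] = 1.0
    X["age_term"] = df["age"] ** 3 if spec.age_term == "age3" else df["age"]
    if spec.include_bmi:
        X["bmi"] = df["bmi"]
    if spec.group == "diagnosis":
        levels = [d for d in DIAGNOSES if d != spec.reference]
        for lv in levels:
            X[f"diag_{lv}"] = (df["diagnosis"] == lv).astype(float)
        if spec.interaction:
            for lv in levels:
                X[f"agex_{lv}"] = X[f"diag_{lv}"] * X["age_term"]
    return X, df[spec.response]


def fit_model(cohort: pd.DataFrame, spec: ModelSpec) -> FittedModel:
    """Ordinary least squares on the design implied by ``spec``.

    Filtering: sex stratum, age window, and (only if BMI is in the model)
    complete BMI cases.  Raises :class:`ModelError` on too-few records or
    a rank-deficient design.
    """
    df = validate_cohort(cohort).copy()
    if spec.sex is not None:
        df = df[df["sex"] == spec.sex]
    lo, hi = spec.window
    df = df[(df["age"] >= lo) & (df["age"] <= hi)]
    if spec.include_bmi:
        if "bmi" not in df.columns:
            raise ModelError("spec includes BMI but the table has no bmi column")
        df = df[df["bmi"].notna()]
    if spec.group == "diagnosis" and df.empty:
        raise ModelError("no records after filtering")
    X, y = _build_design(df, spec)
    k = X.shape[1]
    if len(df) < k + 3:
        raise ModelError(f"need at least {k + 3} records for {k} parameters, have {len(df)}")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        raise ModelError("rank-deficient design (e.g. a diagnosis level is absent)")
    result = sm.OLS(y.to_numpy(), X).fit()
    return FittedModel(spec=spec, result=result, data=df, exog_names=tuple(X.columns))


@dataclass(frozen=True)
class GroupDifference:
    """Adjusted mean difference between two diagnoses over an age window."""

    contrast: tuple[str, str]      # (A, B): Δ = mean_A - mean_B
    delta: float
    p_value: float                 # NaN when the contrast is degenerate
    window: tuple[float, float]
    adjustment: tuple[str, ...]    # covariates adjusted for

    def to_dict(self) -> dict:
        return {
            "contrast": f"{self.contrast[0]} - {self.contrast[1]}",
            "delta": self.delta,
            "p": self.p_value,
            "window": list(self.window),
            "adjustment": list(self.adjustment),
        }


def group_difference(
    fitted: FittedModel, contrast: tuple[str, str], n_grid: int = 81
) -> GroupDifference:
    """Δ between two diagnosis groups, averaged over the model's age window.

    The contrast vector is the window-average of design-row differences
    between the two groups (other covariates at their stratum means); in a
    parallel-slopes model this reduces exactly to the coefficient
    difference.  The p-value is the t-test of that linear contrast.
    """
    spec = fitted.spec
    if spec.group != "diagnosis":
        raise ModelError("model has no diagnosis factor")
    a, b = contrast
    for g in (a, b):
        if g not in DIAGNOSES:
            raise ModelError(f"unknown diagnosis {g!r}")
        if g != spec.reference and f"diag_{g}" not in fitted.exog_names:
            raise ModelError(f"group {g!r} absent from the fitted model")
    means = {"bmi": float(fitted.data["bmi"].mean()) if spec.include_bmi else 0.0}
    ages = np.linspace(spec.window[0], spec.window[1], n_grid)
    rows_a = np.mean(
        [_design_row(spec, fitted.exog_names, t, a, means) for t in ages], axis=0
    )
    rows_b = np.mean(
        [_design_row(spec, fitted.exog_names, t, b, means) for t in ages], axis=0
    )
    L = rows_a - rows_b
    adjustment = ("age",) + (("bmi",) if spec.include_bmi else ())
    if a == b:
        return GroupDifference(contrast, 0.0, float("nan"), spec.window, adjustment)
    tt = fitted.result.t_test(L)
    return GroupDifference(
        contrast=contrast,
        delta=float(np.squeeze(tt.effect)),
        p_value=float(np.squeeze(tt.pvalue)),
        window=spec.window,
        adjustment=adjustment,
    )


def percent_change_over_window(
    fitted: FittedModel, window: tuple[float, float] | None = None
) -> float:
    """Percent change of the predicted response between two ages.

    ``100 * (pred(b) - pred(a)) / pred(a)``, other covariates at stratum
    means and diagnosis at the observed group shares.  Anchored at the
    lower endpoint; raises on a non-positive anchor prediction.
    """
    spec = fitted.spec
    a, b = window if window is not None else spec.window
    means = {"bmi": float(fitted.data["bmi"].mean()) if spec.include_bmi else 0.0}
    if spec.group == "diagnosis":
        for lv in DIAGNOSES:
            if f"diag_{lv}" in fitted.exog_names:
                means[f"diag_{lv}"] = float((fitted.data["diagnosis"] == lv).mean())
    beta = fitted.result.params.to_numpy()
    pred_a = float(_design_row(spec, fitted.exog_names, a, None, means) @ beta)
    pred_b = float(_design_row(spec, fitted.exog_names, b, None, means) @ beta)
    if pred_a <= 0:
        raise ModelError(f"prediction at age {a} is non-positive; percent change undefined")
    return 100.0 * (pred_b - pred_a) / pred_a


@dataclass(frozen=True)
class DecadeResult:
    """One decade's group comparison (or the reason it was not testable)."""

    decade: tuple[float, float]
    testable: bool
    reason: str = ""
    group_means: dict = field(default_factory=dict)
    group_n: dict = field(default_factory=dict)
    anova_p: float = float("nan")
    anova_f: float = float("nan")
    pairwise: tuple = ()           # (groupA, groupB, mean difference A-B, adjusted p)


@dataclass(frozen=True)
class DecadeAnovaResult:
    """Decade-partitioned one-way ANOVA with Tukey HSD post-hoc tests."""

    response: str
    sex: str | None
    decades: tuple[DecadeResult, ...]

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "sex": self.sex,
            "decades": [
                {
                    "decade": list(d.decade),
                    "testable": d.testable,
                    "reason": d.reason,
                    "group_means": d.group_means,
                    "group_n": d.group_n,
                    "anova_p": d.anova_p,
                    "anova_f": d.anova_f,
                    "pairwise": [list(p) for p in d.pairwise],
                }
                for d in self.decades
            ],
        }


def decade_anova(
    cohort: pd.DataFrame,
    response: str = "vmrel",
    sex: str | None = None,
    alpha: float = 0.05,
    include_pairwise: bool = True,
) -> DecadeAnovaResult:
    """Group comparison per age decade (5th-8th: [40,50) ... [70,80]).

    Within each decade, a one-way ANOVA across diagnoses followed by Tukey
    HSD pairwise comparisons.  A decade with fewer than two groups of at
    least two records each is reported as not testable.
    ``include_pairwise=False`` skips the post-hoc tests (the studentized
    range p-values dominate the cost in large simulations).
    """
    df = validate_cohort(cohort)
    if sex is not None:
        df = df[df["sex"] == sex]
    results = []
    for i, (lo, hi) in enumerate(DECADES):
        last = i == len(DECADES) - 1
        sel = (df["age"] >= lo) & ((df["age"] <= hi) if last else (df["age"] < hi))
        sub = df[sel]
        groups = {
            g: sub.loc[sub["diagnosis"] == g, response].to_numpy()
            for g in DIAGNOSES
            if (sub["diagnosis"] == g).sum() >= 2
        }
        if len(groups) < 2:
            results.append(
                DecadeResult(
                    decade=(lo, hi),
                    testable=False,
                    reason=f"only {len(groups)} group(s) with >= 2 records",
                )
            )
            continue
        vals = np.concatenate(list(groups.values()))
        labs = np.concatenate([[g] * len(v) for g, v in groups.items()])
        if np.ptp(vals) == 0:
            # identical values everywhere: no signal, F = 0 by convention
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = sps.f_oneway(*groups.values())
        pairwise: tuple = tuple(
            (ga, gb, 0.0, 1.0)
            for k, ga in enumerate(sorted(groups))
            for gb in sorted(groups)[k + 1 :]
        ) if np.ptp(vals) == 0 else ()
        if include_pairwise and np.ptp(vals) > 0:
            tk = pairwise_tukeyhsd(vals, labs, alpha=alpha)
            pairwise = tuple(
                (str(g1), str(g2), float(md), float(padj))
                for (g1, g2, md, padj) in zip(
                    tk.groupsunique[np.triu_indices(len(tk.groupsunique), 1)[0]],
                    tk.groupsunique[np.triu_indices(len(tk.groupsunique), 1)[1]],
                    tk.meandiffs * -1.0,  # statsmodels reports mean(B)-mean(A)
                    tk.pvalues,
                )
            )
        results.append(
            DecadeResult(
                decade=(lo, hi),
                testable=True,
                group_means={g: float(v.mean()) for g, v in groups.items()},
                group_n={g: int(len(v)) for g, v in groups.items()},
                anova_p=float(p),
                anova_f=float(f_stat),
                pairwise=pairwise,
            )
        )
    return DecadeAnovaResult(response=response, sex=sex, decades=tuple(results))
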