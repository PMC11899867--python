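"""Clustered-eye cohort statistics for the vascular indices.

Both eyes of a participant are correlated, so group comparisons use a
Gaussian identity-link GEE (generalized estimating equations) clustered on
subject, with an exchangeable working correlation and robust sandwich
standard errors; 95% CIs are estimate +- 1.96 * robust SE.  Disease-activity
labels follow the clinical activity score (CAS) rule: a CAS of 3 or higher
is active disease.  Families of region x layer comparisons per metric are
Sidak-corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "METRICS",
    "REGIONS",
    "LAYERS",
    "ComparisonResult",
    "RegressionResult",
    "classify_activity",
    "gee_compare",
    "sidak_adjust",
    "cas_association",
    "descriptive_table",
    "comparison_table",
    "association_table",
]

METRICS = ("vd", "vld", "vdi", "fd")
REGIONS = ("nasal", "temporal")
LAYERS = ("superficial", "deep")

#: Normal quantile for 95% CIs (GEE asymptotics use z, not t).
Z95 = 1.959963984540054

#: Columns a tidy cohort table must carry (one row per eye x region x layer).
REQUIRED_COLUMNS = (
    "subject_id",
    "eye",
    "group",
    "age",
    "gender",
    "region",
    "layer",
)


@dataclass
class ComparisonResult:
    metric: str
    region: str
    layer: str
    amd: float  # adjusted mean difference (group coefficient)
    ci_low: float
    ci_high: float
    p: float
    p_adj: float | None = None
    n_obs: int = 0


@dataclass
class RegressionResult:
    metric: str
    region: str
    layer: str
    coef: float  # slope per CAS unit
    ci_low: float
    ci_high: float
    p: float
    n_obs: int = 0


def classify_activity(cas: int) -> Literal["active", "inactive"]:
    """Active disease iff CAS >= 3 (scores run 0-7)."""
    cas = int(cas)
    if not 0 <= cas <= 7:
        raise ValueError(f"CAS must be in 0..7, got {cas}")
    return "active" if cas >= 3 else "inactive"


def _cov_struct(name: str) -> sm.cov_struct.CovStruct:
    if name == "exchangeable":
        return sm.cov_struct.Exchangeable()
    if name == "independence":
        return sm.cov_struct.Independence()
    raise ValueError(f"unknown working correlation {name!r}")


def _design(
    df: pd.DataFrame, contrast: np.ndarray, contrast_name: str,
    covariates: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    """X = [1, contrast, covariates]; categorical covariates dummy-coded.

    Raises on a singular design, naming the constant term.
    """
    cols: list[np.ndarray] = [np.ones(len(df)), np.asarray(contrast, dtype=float)]
    names = ["intercept", contrast_name]
    for cov in covariates:
        v = df[cov]
        if v.dtype == object or str(v.dtype) == "category":
            levels = sorted(v.unique())
            if len(levels) < 2:
                raise ValueError(f"design is singular: covariate {cov!r} is constant")
            cols.append((v == levels[-1]).to_numpy(dtype=float))
        else:
            cols.append(v.to_numpy(dtype=float))
        names.append(cov)
    X = np.column_stack(cols)
    for j, name in enumerate(names[1:], start=1):
        if np.ptp(X[:, j]) == 0:
            raise ValueError(f"design is singular: term {name!r} is constant")
    return X, names


def _fit_gee(
    df: pd.DataFrame,
    metric: str,
    contrast_col: str,
    positive_label: str,
    covariates: Sequence[str],
    corr: str,
) -> tuple[float, float, float, int]:
    """Fit the clustered Gaussian GEE; return (coef, robust SE, p, n)."""
    df = df.dropna(subset=[metric, contrast_col, *covariates]).copy()
    indicator = (df[contrast_col] == positive_label).to_numpy(dtype=float)
    X, names = _design(df, indicator, contrast_col, covariates)
    y = df[metric].to_numpy(dtype=float)
    groups = df["subject_id"].to_numpy()

    model = sm.GEE(
        y,
        X,
        groups=groups,
        family=sm.families.Gaussian(),
        cov_struct=_cov_struct(corr),
    )
    res = model.fit()  # robust (sandwich) covariance is the GEE default
    j = names.index(contrast_col)
    return float(res.params[j]), float(res.bse[j]), float(res.pvalues[j]), len(df)


def _cell(df: pd.DataFrame, region: str, layer: str) -> pd.DataFrame:
    return df[(df["region"] == region) & (df["layer"] == layer)]


def gee_compare(
    table: pd.DataFrame,
    metric: str,
    region: str,
    layer: str,
    covariates: Sequence[str] = ("age", "gender"),
    group_col: str = "group",
    case_label: str = "case",
    corr: str = "exchangeable",
) -> ComparisonResult:
    """Case-vs-control adjusted mean difference for one metric cell.

    Fits ``metric ~ group + covariates`` with subject clusters; the group
    coefficient is the adjusted mean difference (case minus reference).
    Missing metric rows are dropped, never imputed.
    """
    df = _cell(table, region, layer).dropna(subset=[metric])
    for label, sub in df.groupby(group_col):
        if sub["subject_id"].nunique() < 2:
            raise ValueError(f"need >= 2 clusters in group {label!r}")
    coef, se, p, n = _fit_gee(df, metric, group_col, case_label, covariates, corr)
    return ComparisonResult(
        metric=metric,
        region=region,
        layer=layer,
        amd=coef,
        ci_low=coef - Z95 * se,
        ci_high=coef + Z95 * se,
        p=p,
        n_obs=n,
    )


def sidak_adjust(pvals: Iterable[float], m: int | None = None) -> np.ndarray:
    """Sidak correction p_adj = 1 - (1 - p)^m, clipped to [0, 1].

    ``m`` defaults to the number of p-values (the family size).
    """
    p = np.asarray(list(pvals), dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < 1:
        raise ValueError("family size m must be >= 1")
    with np.errstate(divide="ignore"):  # p = 1 -> log1p(-1) = -inf is fine
        adj = -np.expm1(m * np.log1p(-p))
    return np.clip(adj, 0.0, 1.0)


def cas_association(
    table: pd.DataFrame,
    metric: str,
    region: str,
    layer: str,
    covariates: Sequence[str] = ("age", "gender"),
    corr: str = "exchangeable",
) -> RegressionResult:
    """Per-CAS-unit slope of a metric among diseased eyes.

    Linear model of metric on CAS + age + gender with subject-clustered
    robust errors (the same GEE machinery as the group comparison).
    """
    df = _cell(table, region, layer)
    df = df[df["cas"].notna()].dropna(subset=[metric])
    if df.empty or df["cas"].nunique() < 2:
        raise ValueError("CAS is constant (or absent); association undefined")
    df = df.assign(cas=df["cas"].astype(float))

    dfc = df.dropna(subset=[metric, "cas", *covariates]).copy()
    X, _ = _design(dfc, dfc["cas"].to_numpy(dtype=float), "cas", covariates)
    res = sm.GEE(
        dfc[metric].to_numpy(dtype=float),
        X,
        groups=dfc["subject_id"].to_numpy(),
        family=sm.families.Gaussian(),
        cov_struct=_cov_struct(corr),
    ).fit()
    coef, se, p = float(res.params[1]), float(res.bse[1]), float(res.pvalues[1])
    return RegressionResult(
        metric=metric,
        region=region,
        layer=layer,
        coef=coef,
        ci_low=coef - Z95 * se,
        ci_high=coef + Z95 * se,
        p=p,
        n_obs=len(dfc),
    )


def descriptive_table(table: pd.DataFrame, group_col: str = "group") -> pd.DataFrame:
    """Per-group demographics: n (subjects and eyes), female %, age mean/SD.

    Gender is compared with a chi-square test on subject counts and age with
    a two-sample t-test; female percentages are reported at both the subject
    and the eye level (they differ when eye counts are unbalanced).  SD is
    the sample SD (ddof=1), NaN for a single subject.
    """
    from scipy import stats as sps

    subj = table.drop_duplicates("subject_id")
    rows = []
    for label, sub in subj.groupby(group_col, sort=True):
        eyes = table[table[group_col] == label].drop_duplicates(["subject_id", "eye"])
        n_subj = len(sub)
        age = sub["age"].to_numpy(dtype=float)
        rows.append(
            {
                group_col: label,
                "n_subjects": n_subj,
                "n_eyes": len(eyes),
                "female_pct_subjects": 100.0 * (sub["gender"] == "female").mean(),
                "female_pct_eyes": 100.0 * (eyes["gender"] == "female").mean(),
                "age_mean": float(age.mean()),
                "age_sd": float(age.std(ddof=1)) if n_subj > 1 else float("nan"),
            }
        )
    out = pd.DataFrame(rows)

    if out.shape[0] == 2:
        ct = pd.crosstab(subj[group_col], subj["gender"])
        if ct.shape == (2, 2):
            out["gender_p"] = sps.chi2_contingency(ct.to_numpy(), correction=False)[1]
        groups = [g["age"].to_numpy(dtype=float) for _, g in subj.groupby(group_col)]
        if all(len(g) > 1 for g in groups):
            out["age_p"] = sps.ttest_ind(*groups).pvalue
    return out


def comparison_table(
    table: pd.DataFrame,
    metrics: Sequence[str] = METRICS,
    group_col: str = "group",
    case_label: str = "case",
    corr: str = "exchangeable",
    sidak_m: int | None = None,
) -> pd.DataFrame:
    """All region x layer comparisons per metric, Sidak-corrected per metric.

    The Sidak family defaults to the number of region x layer cells tested
    for each metric (4).  Used both for case-vs-control and, with
    ``group_col="activity"``, for active-vs-inactive among diseased eyes.
    """
    rows: list[ComparisonResult] = []
    for metric in metrics:
        fam: list[ComparisonResult] = []
        for region in REGIONS:
            for layer in LAYERS:
                fam.append(
                    gee_compare(
                        table, metric, region, layer,
                        group_col=group_col, case_label=case_label, corr=corr,
                    )
                )
        m = sidak_m if sidak_m is not None else len(fam)
        adj = sidak_adjust([r.p for r in fam], m=m)
        for r, pa in zip(fam, adj):
            r.p_adj = float(pa)
        rows.extend(fam)
    return pd.DataFrame([vars(r) for r in rows])


def association_table(
    table: pd.DataFrame,
    metrics: Sequence[str] = METRICS,
    corr: str = "exchangeable",
) -> pd.DataFrame:
    """CAS-association slopes for every metric x region x layer cell."""
    rows = [
        vars(cas_association(table, metric, region, layer, corr=corr))
        for metric in metrics
        for region in REGIONS
        for layer in LAYERS
    ]
    return pd.DataFrame(rows)
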