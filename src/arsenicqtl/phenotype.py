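"""Urine arsenic species phenotypes and the two-stage trait transform.

Urinary inorganic arsenic (iAs), monomethylarsonate (MMA) and dimethylarsinate
(DMA) concentrations are turned into relative percentages (%iAs, %MMA, %DMA,
summing to 100), described by median/IQR subgroup tables and Spearman
correlations, and prepared for variance-component analysis by a two-stage
transform: (1) logit of the percentage regressed on covariates jointly with a
polygenic variance component by ML, (2) rank-based inverse normal (Blom) of
the fixed-effect residuals.  The final trait is standard-normal by
construction, which keeps residual kurtosis near zero for the boundary LRT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit as _logit

from .varcomp import VarCompModel, fit_ml

__all__ = [
    "DETECTION_LIMITS",
    "DESIGN_VARIANTS",
    "TransformedTrait",
    "filter_detectable",
    "compute_percentages",
    "creatinine_standardize",
    "descriptive_table",
    "spearman_matrix",
    "logit_percent",
    "inverse_logit_percent",
    "build_design_matrix",
    "first_stage_adjust",
    "inverse_normal",
    "transform_trait",
]

#: Species detection limits, ug/L.
DETECTION_LIMITS = {"iAs": 0.1, "MMA": 0.1, "DMA": 0.1, "total_arsenic": 0.2}

SPECIES = ("iAs", "MMA", "DMA")

DESIGN_VARIANTS = (
    "base",
    "bmi_continuous",
    "bmi_sex_interaction",
    "selenium_adjusted",
    "creatinine_covariate",
    "no_dilution",
)


def filter_detectable(records: pd.DataFrame, limits: dict | None = None):
    """Drop records with any species at/below its detection limit.

    Returns ``(retained, tally)`` where tally counts exclusions per species
    (a record below several limits is tallied under each).
    """
    limits = dict(DETECTION_LIMITS if limits is None else limits)
    if any(v < 0 for v in limits.values()):
        raise ValueError("detection limits must be >= 0")
    tally = {}
    keep = np.ones(len(records), dtype=bool)
    for sp in SPECIES:
        below = records[sp].to_numpy(float) <= limits[sp]
        tally[sp] = int(below.sum())
        keep &= ~below
    tally["retained"] = int(keep.sum())
    tally["excluded"] = int((~keep).sum())
    return records.loc[keep].copy(), tally


def compute_percentages(records: pd.DataFrame) -> pd.DataFrame:
    """%species = 100 * species / (iAs + MMA + DMA); columns pct_iAs etc."""
    conc = records[list(SPECIES)].to_numpy(float)
    if np.any(conc <= 0):
        bad = int(np.flatnonzero((conc <= 0).any(axis=1))[0])
        raise ValueError(
            f"nonpositive species concentration in record {records.index[bad]!r}"
        )
    total = conc.sum(axis=1, keepdims=True)
    out = pd.DataFrame(
        100.0 * conc / total,
        columns=[f"pct_{sp}" for sp in SPECIES],
        index=records.index,
    )
    return out


def creatinine_standardize(conc, creatinine):
    """ug/L divided by creatinine g/L -> ug/g creatinine."""
    conc = np.asarray(conc, float)
    creat = np.asarray(creatinine, float)
    if np.any(creat <= 0):
        raise ValueError("creatinine must be > 0 for standardization")
    return conc / creat


_STRATIFIERS = {
    "age": lambda df: np.where(df["age"] <= 55, "<=55", ">55"),
    "sex": lambda df: df["sex"].astype(str),
    "region": lambda df: df["region"].astype(str),
    "education": lambda df: df["education"].astype(str),
    "bmi": lambda df: np.where(df["bmi"] < 30, "<30", ">=30"),
    "smoking": lambda df: df["smoking"].astype(str),
    "alcohol": lambda df: df["alcohol"].astype(str),
    "total_arsenic": lambda df: np.where(
        df["total_arsenic"] < df["total_arsenic"].median(), "<median", ">=median"
    ),
    "arsenobetaine": lambda df: np.where(
        df["arsenobetaine"] < df["arsenobetaine"].median(), "<median", ">=median"
    ),
    "selenium": lambda df: np.where(
        df["selenium"] < df["selenium"].median(), "<median", ">=median"
    ),
}


def descriptive_table(pcts: pd.DataFrame, covariates: pd.DataFrame | None = None,
                      groups: list[str] | None = None) -> pd.DataFrame:
    """Median (IQR) of each percentage overall and by subgroup.

    ``groups`` names stratifiers (age, sex, region, education, bmi, smoking,
    alcohol, total_arsenic, arsenobetaine, selenium); continuous ones are cut
    at the conventional thresholds (age 55, BMI 30) or at their median.
    Empty cells are reported with n = 0 and NaN statistics.
    """
    rows = []

    def cell(label, level, sub):
        r = {"group": label, "level": level, "n": int(len(sub))}
        for sp in SPECIES:
            col = sub[f"pct_{sp}"]
            if len(sub):
                r[f"pct_{sp}_median"] = float(col.median())
                r[f"pct_{sp}_q25"] = float(col.quantile(0.25))
                r[f"pct_{sp}_q75"] = float(col.quantile(0.75))
            else:
                r[f"pct_{sp}_median"] = r[f"pct_{sp}_q25"] = r[f"pct_{sp}_q75"] = np.nan
        rows.append(r)

    cell("overall", "", pcts)
    for g in groups or []:
        if g not in _STRATIFIERS:
            raise KeyError(f"unknown stratifier {g!r}")
        lab = _STRATIFIERS[g](covariates)
        for level in pd.unique(lab):
            cell(g, str(level), pcts.loc[np.asarray(lab) == level])
    return pd.DataFrame(rows)


def spearman_matrix(pcts: pd.DataFrame) -> pd.DataFrame:
    """3x3 Spearman rank-correlation matrix of the species percentages."""
    cols = [f"pct_{sp}" for sp in SPECIES]
    if len(pcts) < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    for c in cols:
        if pcts[c].nunique() < 2:
            raise ValueError(f"column {c} is constant; correlation undefined")
    rho = stats.spearmanr(pcts[cols].to_numpy()).statistic
    return pd.DataFrame(rho, index=cols, columns=cols)


def logit_percent(p):
    """ln[(p/100) / (1 - p/100)] for p in percent, 0 < p < 100."""
    p = np.asarray(p, float)
    if np.any((p <= 0) | (p >= 100)):
        raise ValueError("percentages must lie strictly between 0 and 100")
    return _logit(p / 100.0)


def inverse_logit_percent(x):
    return 100.0 * expit(np.asarray(x, float))


# reference levels fixed so column meanings are deterministic
_REFERENCE = {"sex": "F", "smoking": "never", "alcohol": "never",
              "education": "<12", "region": "AZ"}
_LEVELS = {"sex": ("F", "M"), "smoking": ("never", "former", "current"),
           "alcohol": ("never", "former", "current"),
           "education": ("<12", ">=12"), "region": ("AZ", "OK", "DK")}


def build_design_matrix(cov: pd.DataFrame, variant: str = "base") -> pd.DataFrame:
    """Covariate design for the stage-1 adjustment.

    Base variant: intercept + centered age, age^2, male indicator, age x sex,
    age^2 x sex, smoking (former, current), education >= 12 y, BMI >= 30,
    alcohol (former, current), region (OK, DK), log total arsenic — the 14
    non-intercept columns of the primary adjustment.  Variants alter one
    term each: BMI continuous, BMI x sex interaction, added urine selenium,
    creatinine as a covariate, or no dilution adjustment (total arsenic in
    ug/L, uncorrected).
    """
    if variant not in DESIGN_VARIANTS:
        raise ValueError(f"unknown design variant {variant!r}")
    for col, levels in _LEVELS.items():
        bad = set(cov[col].astype(str)) - set(levels)
        if bad:
            raise ValueError(f"unknown {col} level(s) {sorted(bad)}; expected {levels}")
    if np.any(cov["age"].to_numpy(float) <= 0):
        raise ValueError("age must be positive")

    X = pd.DataFrame(index=cov.index)
    X["intercept"] = 1.0
    age_c = cov["age"].to_numpy(float) - float(cov["age"].mean())
    male = (cov["sex"].astype(str) == "M").astype(float).to_numpy()
    X["age"] = age_c
    X["age2"] = age_c**2
    X["sex_M"] = male
    X["age_x_sex"] = age_c * male
    X["age2_x_sex"] = age_c**2 * male
    X["smoking_former"] = (cov["smoking"] == "former").astype(float)
    X["smoking_current"] = (cov["smoking"] == "current").astype(float)
    X["education_ge12"] = (cov["education"].astype(str) == ">=12").astype(float)
    if variant == "bmi_continuous":
        X["bmi"] = cov["bmi"].to_numpy(float) - float(cov["bmi"].mean())
    else:
        X["bmi_ge30"] = (cov["bmi"].to_numpy(float) >= 30).astype(float)
        if variant == "bmi_sex_interaction":
            X["bmi_ge30_x_sex"] = X["bmi_ge30"] * male
    X["alcohol_former"] = (cov["alcohol"] == "former").astype(float)
    X["alcohol_current"] = (cov["alcohol"] == "current").astype(float)
    X["region_OK"] = (cov["region"].astype(str) == "OK").astype(float)
    X["region_DK"] = (cov["region"].astype(str) == "DK").astype(float)
    if variant == "no_dilution":
        X["log_total_arsenic"] = np.log(cov["total_arsenic_ugL"].to_numpy(float))
    else:
        X["log_total_arsenic"] = np.log(cov["total_arsenic"].to_numpy(float))
    if variant == "selenium_adjusted":
        X["log_selenium"] = np.log(cov["selenium"].to_numpy(float))
    if variant == "creatinine_covariate":
        X["log_creatinine"] = np.log(cov["creatinine"].to_numpy(float))
    return X


@dataclass
class TransformedTrait:
    """Output of the two-stage transform for one species percentage."""

    stage1_residuals: np.ndarray
    final_trait: np.ndarray
    pct_variance_explained: float
    beta: np.ndarray
    columns: list[str]
    n: int


def first_stage_adjust(trait, X: pd.DataFrame, relationship: np.ndarray,
                       blocks=None) -> TransformedTrait:
    """Stage 1: fixed effects jointly with a polygenic component by ML.

    Residuals are trait minus the fixed-effect predictions (not BLUP
    corrected); pct_variance_explained = 1 - var(residuals)/var(trait).
    """
    y = np.asarray(trait, float)
    Xm = np.asarray(X, float)
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # name the offending columns for the error message
        _, r = np.linalg.qr(Xm)
        small = np.abs(np.diag(r)) < 1e-8 * np.abs(np.diag(r)).max()
        cols = [c for c, s in zip(X.columns, small) if s]
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {cols}")
    model = VarCompModel(y, Xm, {"additive": relationship}, blocks=blocks)
    fit = fit_ml(model)
    resid = y - Xm @ fit.beta
    pve = 1.0 - np.var(resid) / np.var(y)
    return TransformedTrait(
        stage1_residuals=resid,
        final_trait=np.full_like(resid, np.nan),
        pct_variance_explained=float(pve),
        beta=fit.beta,
        columns=list(X.columns),
        n=len(y),
    )


def inverse_normal(values) -> np.ndarray:
    """Rank-based inverse normal scores with the Blom offset.

    value_i = Probit[(rank_i - 3/8) / (n + 1/4)], average ranks for ties.
    """
    x = np.asarray(values, float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("inverse normal transform needs n >= 2")
    if np.all(x == x[0]):
        raise ValueError("all values identical; ranks undefined")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def transform_trait(pct, cov: pd.DataFrame, relationship: np.ndarray,
                    variant: str = "base", blocks=None) -> TransformedTrait:
    """Full two-stage transform of one species percentage."""
    y = logit_percent(pct)
    X = build_design_matrix(cov, variant=variant)
    tt = first_stage_adjust(y, X, relationship, blocks=blocks)
    z = inverse_normal(tt.stage1_residuals)
    # Blom scores have variance slightly under 1 at finite n; standardize so
    # the final trait is exactly mean-0 variance-1 (rank order unchanged)
    tt.final_trait = (z - z.mean()) / z.std()
    return tt
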