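"""Covariate-adjusted group comparison of brain-age gaps.

The group contrast is an ANCOVA realised as ordinary least squares of the
outcome on a CSVD indicator plus nuisance covariates — chronological age,
age squared, sex, education years, EFC image-quality index, TIV and the
four vascular risk flags.  Including age and age² among the covariates is
what corrects the well-known age bias of brain-age predictions, so no
separate bias-correction step is applied to the BAG values themselves.
The effect size is the partial eta squared of the single-df group term,
SS_group / (SS_group + SS_residual); regional tests are Bonferroni
corrected for the number of regions, while the single global test is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .atlas import AtlasSpec
from .brain_age import BagResult

__all__ = [
    "ANCOVA_COVARIATES",
    "MEDIATION_COVARIATES",
    "build_covariates",
    "RegionComparison",
    "ancova_group_effect",
    "bonferroni_threshold",
    "RegionalComparisonResult",
    "regional_bag_comparison",
    "cohort_summary",
]

#: nuisance variables of the BAG group comparison
ANCOVA_COVARIATES = (
    "age", "age_sq", "sex", "education_years", "efc", "tiv_l",
    "hypertension", "diabetes", "dyslipidemia", "smoking",
)

#: confounders of the mediation models (no vascular risk flags)
MEDIATION_COVARIATES = ("age", "age_sq", "sex", "education_years", "efc", "tiv_l")


def build_covariates(subjects: pd.DataFrame,
                     include=ANCOVA_COVARIATES) -> pd.DataFrame:
    """Assemble the covariate design from a subject table.

    ``age_sq`` is derived as age² exactly.  Raises if a needed column is
    missing or contains missing values.
    """
    cols = {}
    missing = []
    for name in include:
        src = "age" if name == "age_sq" else name
        if src not in subjects.columns:
            missing.append(src)
            continue
        v = subjects[src].to_numpy(dtype=float)
        cols[name] = v**2 if name == "age_sq" else v
    if missing:
        raise ValueError(f"subject table missing covariate columns: {sorted(set(missing))}")
    out = pd.DataFrame(cols, index=subjects.index)
    if out.isna().any().any():
        bad = out.columns[out.isna().any()].tolist()
        raise ValueError(f"missing values in covariates: {bad}")
    return out


@dataclass
class RegionComparison:
    """Group contrast for one outcome: coefficient, test and effect size."""

    region_id: str
    coef: float  # adjusted group difference (CSVD - non-CSVD), outcome units
    tstat: float
    pvalue: float
    partial_eta_sq: float
    df_resid: int
    n: int
    significant: bool | None = None


def _check_design(X: np.ndarray, names: list[str]) -> None:
    """Full-rank check; on failure name the first offending column."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    r = 0
    for j in range(X.shape[1]):
        rj = np.linalg.matrix_rank(X[:, : j + 1])
        if rj == r:
            raise ValueError(
                f"collinear design: column {names[j]!r} is linearly dependent "
                "on the preceding columns"
            )
        r = rj
    raise ValueError("collinear design matrix")


def ancova_group_effect(y, group, covariates: pd.DataFrame,
                        region_id: str = "") -> RegionComparison:
    """ANCOVA group effect: OLS of y on group + covariates.

    The p-value is the two-sided single-df t test of the group indicator;
    partial η² = SS_group / (SS_group + SS_residual) where SS_group is the
    partial (last-entry) sum of squares of the group term.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(group, dtype=float)
    C = covariates.to_numpy(dtype=float)
    n = len(y)
    if len(g) != n or len(C) != n:
        raise ValueError("y, group and covariates must be aligned")
    if np.ptp(g) == 0:
        raise ValueError("group indicator is constant")
    if np.ptp(y) == 0:
        raise ValueError("outcome y is constant")
    names = ["const", "group"] + list(covariates.columns)
    X = np.column_stack([np.ones(n), g, C])
    if n <= X.shape[1] + 1:
        raise ValueError(f"need n > {X.shape[1] + 1} rows, got {n}")
    _check_design(X, names)

    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, np.delete(X, 1, axis=1)).fit()
    ss_group = max(float(reduced.ssr - full.ssr), 0.0)
    denom = ss_group + float(full.ssr)
    sst = float(np.sum((y - y.mean()) ** 2))
    # perfect covariate fit: both sums of squares are numerical dust
    eta = 0.0 if denom <= 1e-12 * sst else ss_group / denom
    return RegionComparison(
        region_id=region_id,
        coef=float(full.params[1]),
        tstat=float(full.tvalues[1]),
        pvalue=float(full.pvalues[1]),
        partial_eta_sq=float(eta),
        df_resid=int(full.df_resid),
        n=n,
    )


def bonferroni_threshold(alpha: float, k: int) -> float:
    """Family-wise corrected per-test threshold alpha / k."""
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if int(k) != k or k < 1:
        raise ValueError(f"k must be an integer >= 1, got {k}")
    return alpha / k


@dataclass
class RegionalComparisonResult:
    """Per-region ANCOVA table plus the Bonferroni threshold and tallies."""

    table: pd.DataFrame
    alpha: float
    threshold: float

    @property
    def significant_regions(self) -> list[str]:
        return self.table.loc[self.table["significant"], "region_id"].tolist()

    def summary(self) -> dict:
        sig = self.table[self.table["significant"]]
        by_comp = sig.groupby("compartment")["region_id"].count().to_dict() \
            if "compartment" in sig.columns else {}
        by_net = sig.groupby("network")["region_id"].count().to_dict() \
            if "network" in sig.columns else {}
        return {
            "n_regions": int(len(self.table)),
            "n_significant": int(len(sig)),
            "alpha": self.alpha,
            "bonferroni_threshold": self.threshold,
            "significant_by_compartment": {k: int(v) for k, v in by_comp.items()},
            "significant_by_network": {k: int(v) for k, v in by_net.items()},
        }


def regional_bag_comparison(
    bag: BagResult,
    subjects: pd.DataFrame,
    group,
    atlas: AtlasSpec | None = None,
    alpha: float = 0.05,
    covariates: pd.DataFrame | None = None,
) -> RegionalComparisonResult:
    """One ANCOVA per regional BAG, Bonferroni-corrected over regions.

    ``group`` is a boolean/0-1 series indexed by subject_id (e.g. the
    flags from the CSVD classifier).  Subjects are aligned by subject_id
    across the BAG table, the subject table and the group flags.
    """
    ids = subjects["subject_id"].to_numpy()
    group = pd.Series(group)
    miss = [s for s in ids if s not in group.index]
    if miss:
        raise ValueError(f"group flags missing for subjects: {miss[:5]}")
    g = group.loc[ids].to_numpy(dtype=float)
    covs = covariates if covariates is not None else build_covariates(subjects)

    regions = [s for s in bag.scopes if s != "global"]
    if not regions:
        raise ValueError("BAG table contains no regional scopes")
    wide = bag.wide("bag")
    miss_rows = [s for s in ids if s not in wide.index]
    if miss_rows:
        raise ValueError(f"BAG values missing for subjects: {miss_rows[:5]}")
    wide = wide.loc[ids]

    threshold = bonferroni_threshold(alpha, len(regions))
    rows = []
    for rid in regions:
        res = ancova_group_effect(wide[rid].to_numpy(), g, covs, region_id=rid)
        res.significant = bool(res.pvalue < threshold)
        row = {
            "region_id": rid,
            "coef": res.coef,
            "tstat": res.tstat,
            "pvalue": res.pvalue,
            "partial_eta_sq": res.partial_eta_sq,
            "significant": res.significant,
        }
        if atlas is not None:
            row["compartment"] = atlas.compartment_of(rid)
            row["network"] = atlas.network_of(rid)
        rows.append(row)
    return RegionalComparisonResult(table=pd.DataFrame(rows), alpha=alpha,
                                    threshold=threshold)


def cohort_summary(subjects: pd.DataFrame, group,
                   cognitive_columns=("mmse", "cvvlt", "vft", "cdt")) -> pd.DataFrame:
    """Demographics-table-style comparison of CSVD vs non-CSVD groups.

    Continuous variables: two-sample t test; categorical flags: chi-square;
    cognitive scores: ANCOVA adjusted for age, sex and education years.
    """
    from scipy import stats as sps

    ids = subjects["subject_id"].to_numpy()
    g = pd.Series(group).loc[ids].to_numpy(dtype=bool)
    rows = []

    continuous = ["age", "education_years", "efc", "tiv_l"]
    categorical = ["sex", "hypertension", "diabetes", "dyslipidemia", "smoking"]
    for col in continuous:
        if col not in subjects.columns:
            continue
        v = subjects[col].to_numpy(dtype=float)
        t, p = sps.ttest_ind(v[g], v[~g], equal_var=True)
        rows.append({"variable": col, "test": "t",
                     "csvd_mean": v[g].mean(), "csvd_sd": v[g].std(ddof=1),
                     "noncsvd_mean": v[~g].mean(), "noncsvd_sd": v[~g].std(ddof=1),
                     "pvalue": float(p)})
    for col in categorical:
        if col not in subjects.columns:
            continue
        v = subjects[col].to_numpy(dtype=int)
        tab = np.array([
            [np.sum(v[g] == 1), np.sum(v[g] == 0)],
            [np.sum(v[~g] == 1), np.sum(v[~g] == 0)],
        ])
        if tab.min() == 0 and (tab.sum(axis=0) == 0).any():
            p = float("nan")
        else:
            p = float(sps.chi2_contingency(tab, correction=False).pvalue)
        rows.append({"variable": col, "test": "chi2",
                     "csvd_mean": v[g].mean(), "csvd_sd": float("nan"),
                     "noncsvd_mean": v[~g].mean(), "noncsvd_sd": float("nan"),
                     "pvalue": p})
    covs = build_covariates(subjects, include=("age", "sex", "education_years"))
    for col in cognitive_columns:
        if col not in subjects.columns:
            continue
        v = subjects[col].to_numpy(dtype=float)
        res = ancova_group_effect(v, g.astype(float), covs, region_id=col)
        rows.append({"variable": col, "test": "ancova",
                     "csvd_mean": v[g].mean(), "csvd_sd": v[g].std(ddof=1),
                     "noncsvd_mean": v[~g].mean(), "noncsvd_sd": v[~g].std(ddof=1),
                     "pvalue": res.pvalue})
    return pd.DataFrame(rows)
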