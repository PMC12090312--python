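"""Correlation of adjusted weighted degree with clinical scores.

For each clinical variable, both the per-region WD values and the variable
are residualized on the same covariates (partial-correlation semantics) and
Pearson's r is computed per region, with p-values from Student's t on
n - 2 - k_cov degrees of freedom and BH-FDR applied across the 84 regions
within each variable (one family per variable, one sorted p-value curve per
variable). Analyses run within the patient group, within controls, or with
both groups combined; illness duration, S-FMDRS and CGI exist only for
patients. Region-level findings can then be filtered to the regions already
showing group differences in WD.

Two covariate models are standard: age + sex, and age + sex + BDI + STAI-T.
A variable that is itself part of the adjustment set would have an exactly
zero residual, so it is skipped with a notice rather than tested.

Patients with an S-FMDRS score of 0 have no motor symptoms; they can be
excluded from severity scatter plots, while statistics by default use the
full sample (exclusion is visualization-only, configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectome_io import ValidationError, region_names
from .group_stats import bh_fdr

#: clinical variables available for correlation, mapped to cohort columns
VARIABLE_COLUMNS = {
    "sf36_physical_health": "sf36_physical_health",
    "sf36_mental_health": "sf36_mental_health",
    "sf36_general_health": "sf36_general_health",
    "sf36_physical_functioning": "sf36_physical_functioning",
    "bdi": "bdi",
    "stai_trait": "stai_trait",
    "stai_state": "stai_state",
    "illness_duration": "illness_duration_months",
    "sfmdrs": "sfmdrs",
    "cgi": "cgi",
}

FND_ONLY_VARIABLES = ("illness_duration", "sfmdrs", "cgi")

ADJUSTMENTS = {
    "age_sex": ("age", "sex"),
    "age_sex_bdi_stait": ("age", "sex", "bdi", "stai_trait"),
}

GROUP_SCOPES = ("HC", "FND", "combined")

MIN_SUBJECTS = 5


@dataclass(frozen=True)
class CorrelationSpec:
    """Which variables to correlate, on which subjects, under which adjustment."""

    clinical_variables: tuple[str, ...]
    group_scope: str = "FND"
    adjustment: str = "age_sex_bdi_stait"
    q_fdr: float = 0.05
    method: str = "pearson"
    #: residualize the clinical variable too (partial correlation); if False
    #: only WD is adjusted
    adjust_variable: bool = True
    #: include a group indicator in the combined-scope covariates
    group_covariate: bool = False

    def __post_init__(self) -> None:
        unknown = [v for v in self.clinical_variables if v not in VARIABLE_COLUMNS]
        if unknown:
            raise ValidationError(f"unknown clinical variable(s) {unknown}")
        if self.group_scope not in GROUP_SCOPES:
            raise ValidationError(f"group_scope must be one of {GROUP_SCOPES}")
        if self.adjustment not in ADJUSTMENTS:
            raise ValidationError(f"adjustment must be one of {tuple(ADJUSTMENTS)}")
        if self.group_scope != "FND":
            bad = [v for v in self.clinical_variables if v in FND_ONLY_VARIABLES]
            if bad:
                raise ValidationError(
                    f"variable(s) {bad} exist only for FND patients; group_scope is "
                    f"{self.group_scope!r}")
        if self.method not in ("pearson", "spearman"):
            raise ValidationError("method must be 'pearson' or 'spearman'")
        if not 0.0 < self.q_fdr < 1.0:
            raise ValidationError("q_fdr must lie in (0, 1)")


def residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of y (vector or n x m matrix) on [intercept, covariates].

    Residuals are orthogonal to the intercept and every covariate column.
    Rank-deficient covariates are an error.
    """
    y = np.asarray(y, dtype=float)
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    n = y.shape[0]
    X = np.column_stack([np.ones(n), covariates]) if covariates.size else np.ones((n, 1))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("covariate matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _covariate_matrix(cohort: pd.DataFrame, covariates: tuple[str, ...],
                      add_group: bool = False) -> np.ndarray:
    cols = []
    for cov in covariates:
        if cov == "sex":
            cols.append((cohort["sex"] == "male").to_numpy(float))
        else:
            cols.append(cohort[cov].to_numpy(float))
    if add_group:
        cols.append((cohort["group"] == "FND").to_numpy(float))
    return np.column_stack(cols) if cols else np.empty((len(cohort), 0))


def correlate_wd_clinical(wd: pd.DataFrame, cohort: pd.DataFrame,
                          spec: CorrelationSpec) -> dict[str, pd.DataFrame]:
    """Per-region correlation of adjusted WD with each clinical variable.

    Returns {variable: DataFrame(node, variable, n, r, p_unc, p_adj,
    significant)}, each frame sorted by p_unc (the per-variable sorted
    p-value curve). Subjects missing a variable are dropped pairwise per
    variable. Variables in the adjustment set are skipped with a warning.
    """
    if len(wd) != len(cohort):
        raise ValidationError("wd rows must align with cohort subjects")
    if spec.group_scope in ("HC", "FND"):
        scope = (cohort["group"] == spec.group_scope).to_numpy()
    else:
        scope = np.ones(len(cohort), dtype=bool)
    covs = ADJUSTMENTS[spec.adjustment]

    results: dict[str, pd.DataFrame] = {}
    for var in spec.clinical_variables:
        if var in covs:
            warnings.warn(f"variable {var!r} is in the adjustment set; skipped")
            continue
        col = VARIABLE_COLUMNS[var]
        keep = scope & cohort[col].notna().to_numpy()
        n = int(keep.sum())
        if n < MIN_SUBJECTS:
            raise ValidationError(f"variable {var!r}: only {n} usable subjects (< {MIN_SUBJECTS})")
        y = cohort.loc[keep, col].to_numpy(float)
        if np.ptp(y) == 0:
            raise ValidationError(f"variable {var!r} is constant after filtering")
        W = wd.to_numpy(float)[keep]
        if spec.method == "spearman":
            y = stats.rankdata(y)
            W = np.apply_along_axis(stats.rankdata, 0, W)
        C = _covariate_matrix(cohort.loc[keep], covs,
                              add_group=(spec.group_scope == "combined" and spec.group_covariate))
        W_res = residualize(W, C)
        y_res = residualize(y, C) if spec.adjust_variable else y - y.mean()
        r = _pearson_columns(W_res, y_res)
        dof = n - 2 - C.shape[1]
        if dof < 1:
            raise ValidationError(f"variable {var!r}: not enough subjects for the adjustment")
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt(dof / np.clip(1.0 - r ** 2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), dof)
        p_adj, reject = bh_fdr(p, spec.q_fdr)
        frame = pd.DataFrame({
            "node": list(wd.columns),
            "variable": var,
            "n": n,
            "r": r,
            "p_unc": p,
            "p_adj": p_adj,
            "significant": reject,
        }).sort_values("p_unc", kind="stable").reset_index(drop=True)
        results[var] = frame
    return results


def _pearson_columns(W: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between each column of W and y (both already centered or not)."""
    Wc = W - W.mean(axis=0)
    yc = y - y.mean()
    num = Wc.T @ yc
    den = np.sqrt((Wc ** 2).sum(axis=0) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return np.clip(r, -1.0, 1.0)


def sorted_p_curves(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Long-format table of each variable's sorted p-value curve (rank, p_unc)."""
    frames = []
    for var, frame in results.items():
        p_sorted = np.sort(frame["p_unc"].to_numpy())
        frames.append(pd.DataFrame({
            "variable": var,
            "rank": np.arange(1, len(p_sorted) + 1),
            "p_unc": p_sorted,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["variable", "rank", "p_unc"])


def filter_to_regions(results: pd.DataFrame, regions: set[str]) -> pd.DataFrame:
    """Keep significant correlations whose region was a group-difference finding.

    ``results`` is a (possibly concatenated) correlation frame; returns its
    significant rows with node in ``regions``. Per-variable counts are then
    ``filtered.groupby("variable").size()``.
    """
    unknown = set(regions) - set(region_names())
    if unknown:
        raise ValidationError(f"unknown region name(s): {sorted(unknown)}")
    out = results[results["significant"] & results["node"].isin(regions)]
    return out.reset_index(drop=True)


def exclude_zero_sfmdrs(cohort: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """FND patients with motor symptoms (S-FMDRS > 0), for severity plots.

    Returns (subset, number excluded). Statistics elsewhere use the full
    sample by default; this exclusion mirrors scatter-plot practice where
    zero-score (symptom-free) patients are uninformative about severity.
    """
    fnd = cohort[cohort["group"] == "FND"]
    zero = fnd["sfmdrs"].fillna(0) == 0
    n_excluded = int(zero.sum())
    subset = fnd[~zero].reset_index(drop=True)
    if len(fnd) and subset.empty:
        warnings.warn("all FND patients have S-FMDRS = 0; severity plot set is empty")
    return subset, n_excluded
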