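"""Covariate-adjusted directional group comparison with BH-FDR control.

Node level: one ordinary-least-squares GLM per region's weighted degree,
``y ~ intercept + group(FND=1) + covariates``; the group coefficient's t
statistic is tested one-sided ("directional") against Student's t with
n - k residual degrees of freedom. "Reduced" and "heightened" integrity are
probed as two separate one-sided families, each FDR-corrected on its own.

Link level: the same regression applied to every region pair's weight
(FA, streamline count, or mean fiber length). A link enters the tested
family only if it is present (nonzero) in at least a configurable fraction
of subjects *in each group* (default 0.5); FDR is computed over the tested
family. Significant links are then hierarchically restricted to those
touching regions already flagged at the node level, and per-node altered
link counts are reported out of the 83 candidate links per node.

With no covariates the group-coefficient t is algebraically the classical
pooled-variance two-sample t, which is used as an equivalence oracle in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .connectome_io import ValidationError, region_names
from .graph_metrics import LINKS_PER_NODE, LinkTable

#: cohort columns allowed as GLM covariates
ALLOWED_COVARIATES = ("age", "sex", "medication_any_psychotropic", "bdi", "stai_trait")

DIRECTIONS = ("fnd_lower", "fnd_higher", "two_sided")

MIN_GROUP_SIZE = 3


@dataclass(frozen=True)
class DesignSpec:
    """Covariate set, test direction and FDR level of one group comparison."""

    covariates: tuple[str, ...] = ("age", "sex")
    direction: str = "fnd_lower"
    q_fdr: float = 0.05

    def __post_init__(self) -> None:
        if len(set(self.covariates)) != len(self.covariates):
            raise ValidationError("covariate names must be unique")
        unknown = [c for c in self.covariates if c not in ALLOWED_COVARIATES]
        if unknown:
            raise ValidationError(f"unknown covariate(s) {unknown}; allowed: {ALLOWED_COVARIATES}")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"direction must be one of {DIRECTIONS}")
        if not 0.0 < self.q_fdr < 1.0:
            raise ValidationError("q_fdr must lie in (0, 1)")


def build_design_matrix(cohort: pd.DataFrame, covariates: tuple[str, ...]) -> np.ndarray:
    """Design matrix [intercept, group(FND=1), covariates] with a rank check.

    Sex is coded male=1, medication True=1. Rank deficiency raises an error
    naming the offending column.
    """
    n = len(cohort)
    cols = [np.ones(n), (cohort["group"] == "FND").to_numpy(float)]
    names = ["intercept", "group"]
    for cov in covariates:
        if cov == "sex":
            cols.append((cohort["sex"] == "male").to_numpy(float))
        elif cov == "medication_any_psychotropic":
            cols.append(cohort["medication_any_psychotropic"].to_numpy(float))
        else:
            vals = cohort[cov].to_numpy(float)
            if np.isnan(vals).any():
                raise ValidationError(f"covariate {cov!r} has missing values")
            cols.append(vals)
        names.append(cov)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the latest redundant column (the user-supplied covariate,
        # not the intercept it collides with)
        for k in reversed(range(X.shape[1])):
            reduced = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValidationError(f"design matrix rank deficient: column {names[k]!r}")
        raise ValidationError("design matrix rank deficient")
    return X


def _check_groups(cohort: pd.DataFrame) -> None:
    counts = cohort["group"].value_counts()
    for g in ("FND", "HC"):
        if counts.get(g, 0) < MIN_GROUP_SIZE:
            raise ValidationError(f"group {g} has {counts.get(g, 0)} subjects; need >= {MIN_GROUP_SIZE}")


def _ols_group_t(X: np.ndarray, Y: np.ndarray, direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS of each column of Y on X; t and p of the group coefficient.

    Y has shape (n, m); returns (t, p) of shape (m,). The group indicator is
    column 1 of X. One OLS solve serves all m outcomes since X is shared.
    """
    n, k = X.shape
    if Y.ndim == 1:
        Y = Y[:, None]
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - k
    rss = (resid ** 2).sum(axis=0)
    # an (essentially) perfect fit leaves only rounding error in the
    # residuals; the group effect is then exactly absorbed and t is 0
    scale = np.maximum(((Y - Y.mean(axis=0)) ** 2).sum(axis=0), (Y ** 2).sum(axis=0))
    perfect = rss <= scale * 1e-20 + 1e-280
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(perfect | (se == 0), 0.0, beta[1] / np.where(se > 0, se, 1.0))
    if direction == "fnd_lower":
        p = stats.t.cdf(t, dof)
    elif direction == "fnd_higher":
        p = stats.t.sf(t, dof)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    return t, p


def fit_group_glm(y: np.ndarray, cohort: pd.DataFrame, design: DesignSpec) -> tuple[float, float]:
    """GLM group comparison of one outcome; returns (t_stat, p_unc).

    OLS of y on [intercept, group(FND=1), covariates]; p from Student's t
    with n - k residual degrees of freedom, one-sided when the design is
    directional (fnd_lower tests the lower tail of the group coefficient).
    """
    _check_groups(cohort)
    y = np.asarray(y, dtype=float)
    if y.shape != (len(cohort),):
        raise ValidationError("y must have one value per cohort subject")
    X = build_design_matrix(cohort, design.covariates)
    t, p = _ols_group_t(X, y, design.direction)
    return float(t[0]), float(p[0])


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR correction.

    Returns (adjusted p, decisions). Adjusted p_(k) = min_{k' >= k}
    p_(k') * m / k' capped at 1; a test is a discovery iff its adjusted
    p <= q. Ties share a rank (the procedure is stable under ties).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def test_nodes(wd: pd.DataFrame, cohort: pd.DataFrame, design: DesignSpec) -> pd.DataFrame:
    """Directional group GLM on every region's WD, BH-FDR over the 84 nodes.

    ``wd`` rows must align with ``cohort`` rows (same subjects, same order).
    Returns a DataFrame (node, t_stat, p_unc, p_adj, significant,
    direction_tested) sorted by p_unc; the 84 node p-values form one FDR
    family.
    """
    if len(wd) != len(cohort):
        raise ValidationError("wd rows must align with cohort subjects")
    _check_groups(cohort)
    X = build_design_matrix(cohort, design.covariates)
    t, p = _ols_group_t(X, wd.to_numpy(float), design.direction)
    p_adj, reject = bh_fdr(p, design.q_fdr)
    out = pd.DataFrame({
        "node": list(wd.columns),
        "t_stat": t,
        "p_unc": p,
        "p_adj": p_adj,
        "significant": reject,
        "direction_tested": design.direction,
    })
    return out.sort_values("p_unc", kind="stable").reset_index(drop=True)


def test_links(links: LinkTable, cohort: pd.DataFrame, design: DesignSpec,
               presence_threshold: float = 0.5) -> pd.DataFrame:
    """Directional group regression on every tested link, BH-FDR over the family.

    A link is tested only if nonzero in at least ``presence_threshold``
    fraction of subjects in each group (0 tests all 3486 pairs). Untested
    links are returned flagged ``tested=False`` with NaN statistics —
    absent, not failed.
    """
    if not 0.0 <= presence_threshold <= 1.0:
        raise ValidationError("presence_threshold must lie in [0, 1]")
    if len(links.subject_ids) != len(cohort):
        raise ValidationError("link table rows must align with cohort subjects")
    _check_groups(cohort)
    values = links.values
    present = values != 0
    fnd = (cohort["group"] == "FND").to_numpy()
    frac_fnd = present[fnd].mean(axis=0)
    frac_hc = present[~fnd].mean(axis=0)
    tested = (frac_fnd >= presence_threshold) & (frac_hc >= presence_threshold)

    names = region_names()
    n_links = values.shape[1]
    t_all = np.full(n_links, np.nan)
    p_all = np.full(n_links, np.nan)
    p_adj_all = np.full(n_links, np.nan)
    sig_all = np.zeros(n_links, dtype=bool)
    if tested.any():
        X = build_design_matrix(cohort, design.covariates)
        t, p = _ols_group_t(X, values[:, tested], design.direction)
        p_adj, reject = bh_fdr(p, design.q_fdr)
        t_all[tested], p_all[tested] = t, p
        p_adj_all[tested], sig_all[tested] = p_adj, reject
    out = pd.DataFrame({
        "region_a": [names[i] for i in links.pairs[:, 0]],
        "region_b": [names[j] for j in links.pairs[:, 1]],
        "weight_kind": links.weight_kind,
        "tested": tested,
        "t_stat": t_all,
        "p_unc": p_all,
        "p_adj": p_adj_all,
        "significant": sig_all,
        "direction_tested": design.direction,
    })
    return out


def restrict_links_to_nodes(link_results: pd.DataFrame,
                            nodes: set[str]) -> tuple[pd.DataFrame, pd.Series]:
    """Keep significant links touching a node-level finding; count per node.

    Returns (filtered link results, per-node counts). A link is kept iff it
    is significant and at least one endpoint is in ``nodes``; each node's
    count is the number of kept links incident to it, out of the 83
    candidate links per node.
    """
    unknown = set(nodes) - set(region_names())
    if unknown:
        raise ValidationError(f"unknown region name(s): {sorted(unknown)}")
    sig = link_results[link_results["significant"]]
    keep = sig[sig["region_a"].isin(nodes) | sig["region_b"].isin(nodes)]
    counts = pd.Series(0, index=sorted(nodes), dtype=int, name=f"n_of_{LINKS_PER_NODE}")
    for node in counts.index:
        counts[node] = int(((keep["region_a"] == node) | (keep["region_b"] == node)).sum())
    return keep.reset_index(drop=True), counts
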