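import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from fndconn.clinical_corr import (
    CorrelationSpec,
    correlate_wd_clinical,
    exclude_zero_sfmdrs,
    filter_to_regions,
    residualize,
    sorted_p_curves,
)
from fndconn.connectome_io import ValidationError, region_names
from fndconn.group_stats import bh_fdr
from fndconn.synthetic import GeneratorConfig, default_scenarios, generate_tables
from conftest import make_cohort


class TestResidualize:
    def test_intercept_only_centers(self, rng):
        y = rng.normal(5, 2, size=40)
        res = residualize(y, np.empty((40, 0)))
        np.testing.assert_allclose(res, y - y.mean(), atol=1e-12)

    def test_exact_linear_dependence_gives_zero(self, rng):
        age = rng.uniform(20, 60, 50)
        y = 3.0 + 0.5 * age
        res = residualize(y, age)
        assert np.abs(res).max() < 1e-9

    def test_orthogonality(self, rng):
        C = rng.normal(size=(60, 3))
        y = rng.normal(size=60)
        res = residualize(y, C)
        assert abs(res.sum()) < 1e-8
        assert np.abs(C.T @ res).max() < 1e-8

    def test_rank_deficiency_rejected(self, rng):
        C = np.ones((20, 1))  # duplicates the intercept
        with pytest.raises(ValidationError, match="rank"):
            residualize(rng.normal(size=20), C)


class TestCorrelateWdClinical:
    def test_exact_negative_coupling(self, rng):
        cohort = make_cohort(30, 3, rng)
        wd = pd.DataFrame(rng.normal(20, 2, size=(33, 84)), columns=region_names())
        node = "ctx-lh-precuneus"
        sev = np.full(33, np.nan)
        sev[:30] = -1.0 * wd[node].to_numpy()[:30] + 100
        cohort["sfmdrs"] = sev
        spec = CorrelationSpec(clinical_variables=("sfmdrs",), group_scope="FND",
                               adjustment="age_sex")
        res = correlate_wd_clinical(wd, cohort, spec)["sfmdrs"]
        top = res.iloc[0]
        assert top["node"] == node
        assert top["r"] == pytest.approx(-1.0, abs=1e-6)
        assert top["p_unc"] < 1e-20

    def test_partial_correlation_matches_pingouin(self, rng):
        cohort = make_cohort(40, 3, rng)
        wd = pd.DataFrame(rng.normal(20, 2, size=(43, 84)), columns=region_names())
        spec = CorrelationSpec(clinical_variables=("sfmdrs",), group_scope="FND",
                               adjustment="age_sex")
        res = correlate_wd_clinical(wd, cohort, spec)["sfmdrs"].set_index("node")
        fnd = cohort[cohort["group"] == "FND"]
        for node in ("ctx-lh-precuneus", "Right-Putamen", "ctx-rh-insula"):
            frame = pd.DataFrame({
                "wd": wd[node].to_numpy()[:40],
                "sev": fnd["sfmdrs"].to_numpy(),
                "age": fnd["age"].to_numpy(),
                "male": (fnd["sex"] == "male").astype(float).to_numpy(),
            })
            ref = pg.partial_corr(frame, x="wd", y="sev", covar=["age", "male"])
            assert res.loc[node, "r"] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
            assert res.loc[node, "p_unc"] == pytest.approx(
                float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_affine_rescaling_invariance(self, rng):
        cohort = make_cohort(30, 3, rng)
        wd = pd.DataFrame(rng.normal(20, 2, size=(33, 84)), columns=region_names())
        spec = CorrelationSpec(clinical_variables=("sfmdrs",), group_scope="FND",
                               adjustment="age_sex")
        base = correlate_wd_clinical(wd, cohort, spec)["sfmdrs"]
        cohort2 = cohort.copy()
        cohort2["sfmdrs"] = 7.0 * cohort2["sfmdrs"] + 3.0
        scaled = correlate_wd_clinical(wd, cohort2, spec)["sfmdrs"]
        np.testing.assert_allclose(base["r"], scaled["r"], atol=1e-10)

    def test_variable_in_adjustment_is_skipped(self, rng):
        cohort = make_cohort(20, 20, rng)
        wd = pd.DataFrame(rng.normal(size=(40, 84)), columns=region_names())
        spec = CorrelationSpec(clinical_variables=("bdi", "sf36_mental_health"),
                               group_scope="combined", adjustment="age_sex_bdi_stait")
        with pytest.warns(UserWarning, match="adjustment"):
            res = correlate_wd_clinical(wd, cohort, spec)
        assert set(res) == {"sf36_mental_health"}

    def test_fnd_only_variable_needs_fnd_scope(self):
        with pytest.raises(ValidationError, match="FND"):
            CorrelationSpec(clinical_variables=("cgi",), group_scope="combined")

    def test_constant_variable_rejected(self, rng):
        cohort = make_cohort(10, 3, rng)
        cohort.loc[cohort["group"] == "FND", "sfmdrs"] = 4.0
        wd = pd.DataFrame(rng.normal(size=(13, 84)), columns=region_names())
        spec = CorrelationSpec(clinical_variables=("sfmdrs",), group_scope="FND",
                               adjustment="age_sex")
        with pytest.raises(ValidationError, match="constant"):
            correlate_wd_clinical(wd, cohort, spec)

    def test_null_coupling_fdr_control(self):
        # no planted WD-severity coupling: per-variable family FDP stays near q
        cfg = default_scenarios()["null"]
        spec = CorrelationSpec(clinical_variables=("sfmdrs",), group_scope="FND",
                               adjustment="age_sex_bdi_stait")
        fdps = []
        for seed in range(150):
            wd, _, _, cohort, _ = generate_tables(cfg, seed=40_000 + seed)
            res = correlate_wd_clinical(wd, cohort, spec)["sfmdrs"]
            n_disc = int(res["significant"].sum())
            fdps.append(0.0 if n_disc == 0 else 1.0)  # all discoveries false
        assert np.mean(fdps) <= 0.05 + 0.04

    def test_coupled_nodes_recovered(self):
        cfg = default_scenarios()["paper_like"]
        spec = CorrelationSpec(clinical_variables=("sfmdrs",), group_scope="FND",
                               adjustment="age_sex_bdi_stait")
        hits = 0
        reps = 50
        for seed in range(reps):
            wd, _, _, cohort, truth = generate_tables(cfg, seed=50_000 + seed)
            res = correlate_wd_clinical(wd, cohort, spec)["sfmdrs"]
            hits += set(res["node"].iloc[:2]) == set(truth.coupled_nodes)
        assert hits >= int(0.8 * reps)

    def test_combined_group_simpson_behavior(self, rng):
        # a pure between-group mean shift in both WD and the score produces
        # combined-group correlation with null within-group correlation
        n = 40
        cohort = make_cohort(n, n, rng)
        wd = pd.DataFrame(rng.normal(20, 1, size=(2 * n, 84)), columns=region_names())
        wd.iloc[:n] -= 5.0  # FND lower WD everywhere
        score = rng.normal(50, 5, size=2 * n)
        score[:n] += 30.0  # FND higher score, no within-group coupling
        cohort["sf36_mental_health"] = score
        combined = correlate_wd_clinical(
            wd, cohort, CorrelationSpec(clinical_variables=("sf36_mental_health",),
                                        group_scope="combined", adjustment="age_sex"))
        within = correlate_wd_clinical(
            wd, cohort, CorrelationSpec(clinical_variables=("sf36_mental_health",),
                                        group_scope="FND", adjustment="age_sex"))
        assert combined["sf36_mental_health"]["significant"].sum() > 40
        assert within["sf36_mental_health"]["significant"].sum() <= 4


class TestFilterAndExclusion:
    def _results(self, rng):
        frames = []
        for var in ("sfmdrs", "cgi"):
            frames.append(pd.DataFrame({
                "node": region_names(),
                "variable": var,
                "significant": rng.random(84) < 0.3,
            }))
        return pd.concat(frames, ignore_index=True)

    def test_all_regions_keeps_significant_subset(self, rng):
        res = self._results(rng)
        out = filter_to_regions(res, set(region_names()))
        assert len(out) == int(res["significant"].sum())

    def test_empty_region_set(self, rng):
        assert filter_to_regions(self._results(rng), set()).empty

    def test_counts_match_bruteforce_intersection(self, rng):
        res = self._results(rng)
        regions = set(rng.choice(region_names(), size=20, replace=False))
        out = filter_to_regions(res, regions)
        for var in ("sfmdrs", "cgi"):
            sub = res[(res["variable"] == var) & res["significant"]]
            expected = len(set(sub["node"]) & regions)
            assert (out["variable"] == var).sum() == expected

    def test_unknown_region_rejected(self, rng):
        with pytest.raises(ValidationError, match="unknown"):
            filter_to_regions(self._results(rng), {"nope"})

    def test_exclude_zero_sfmdrs_default_rate(self):
        wd, _, _, cohort, _ = generate_tables(GeneratorConfig(), seed=11)
        subset, n_excluded = exclude_zero_sfmdrs(cohort)
        assert 10 <= n_excluded <= 35  # ~21/85 censoring rate
        assert len(subset) + n_excluded == 85
        assert (subset["sfmdrs"] > 0).all()

    def test_no_zero_scores(self, rng):
        cohort = make_cohort(10, 5, rng)
        cohort.loc[cohort["group"] == "FND", "sfmdrs"] = 5.0
        subset, n_excluded = exclude_zero_sfmdrs(cohort)
        assert n_excluded == 0 and len(subset) == 10

    def test_all_zero_warns(self, rng):
        cohort = make_cohort(6, 3, rng)
        cohort.loc[cohort["group"] == "FND", "sfmdrs"] = 0.0
        with pytest.warns(UserWarning, match="S-FMDRS"):
            subset, n_excluded = exclude_zero_sfmdrs(cohort)
        assert n_excluded == 6 and subset.empty


def test_sorted_p_curves_shape(rng):
    cohort = make_cohort(20, 3, rng)
    wd = pd.DataFrame(rng.normal(size=(23, 84)), columns=region_names())
    spec = CorrelationSpec(clinical_variables=("sfmdrs", "cgi"), group_scope="FND",
                           adjustment="age_sex")
    curves = sorted_p_curves(correlate_wd_clinical(wd, cohort, spec))
    assert set(curves["variable"]) == {"sfmdrs", "cgi"}
    for _, grp in curves.groupby("variable"):
        assert grp["p_unc"].is_monotonic_increasing
        assert len(grp) == 84
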