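import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from fndconn.connectome_io import SubjectConnectome, ValidationError, region_names
from fndconn.graph_metrics import LinkTable, link_values
from fndconn.group_stats import (
    DesignSpec,
    bh_fdr,
    build_design_matrix,
    fit_group_glm,
    restrict_links_to_nodes,
)
from fndconn.group_stats import test_links as run_link_tests
from fndconn.group_stats import test_nodes as run_node_tests
from conftest import make_cohort, random_symmetric_fa
from oracles import bh_stepup_bruteforce, pooled_two_sample_t


class TestBhFdr:
    def test_single_small_p(self):
        p_adj, reject = bh_fdr([0.01], q=0.05)
        assert p_adj[0] == pytest.approx(0.01)
        assert reject[0]

    def test_matches_bruteforce_definition(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 101))
            p = rng.random(m) ** rng.uniform(0.5, 3)
            p_adj, reject = bh_fdr(p, q=0.05)
            adj_ref, rej_ref = bh_stepup_bruteforce(p, q=0.05)
            np.testing.assert_allclose(p_adj, adj_ref, atol=1e-12, rtol=0)
            np.testing.assert_array_equal(reject, rej_ref)

    def test_stated_example_vector(self):
        p_adj, reject = bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.05)
        adj_ref, rej_ref = bh_stepup_bruteforce(np.array([0.01, 0.02, 0.03, 0.5]), q=0.05)
        np.testing.assert_allclose(p_adj, adj_ref, atol=1e-12, rtol=0)
        np.testing.assert_array_equal(reject, rej_ref)

    def test_all_equal_at_stepup_boundary(self):
        # p_(m) = 0.04 <= q m/m, so the step-up rejects everything
        p_adj, reject = bh_fdr(np.full(84, 0.04), q=0.05)
        assert reject.all()

    def test_adjusted_at_least_raw(self, rng):
        p = rng.random(50)
        p_adj, _ = bh_fdr(p, q=0.05)
        assert np.all(p_adj >= p - 1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2], q=0.05)

    @settings(deadline=None, max_examples=50)
    @given(st.data())
    def test_monotone_in_p(self, data):
        # decreasing any single p never turns a discovery into a non-discovery
        m = data.draw(st.integers(2, 30))
        p = np.array(data.draw(st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=m, max_size=m)))
        idx = data.draw(st.integers(0, m - 1))
        lowered = p.copy()
        lowered[idx] = data.draw(st.floats(0.0, float(p[idx]), allow_nan=False))
        _, before = bh_fdr(p, q=0.05)
        _, after = bh_fdr(lowered, q=0.05)
        assert np.all(after | ~before)


class TestFitGroupGlm:
    def test_identical_groups_give_half_p(self, rng):
        cohort = make_cohort(5, 5, rng)
        y = np.ones(10) * 3.3
        t, p = fit_group_glm(y, cohort, DesignSpec(covariates=(), direction="fnd_lower"))
        assert t == 0.0
        assert p == pytest.approx(0.5)

    def test_no_covariates_equals_pooled_t(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(4, 20, size=2)
            cohort = make_cohort(int(n1), int(n2), rng)
            y = rng.normal(size=n1 + n2)
            t, _ = fit_group_glm(y, cohort, DesignSpec(covariates=(), direction="two_sided"))
            t_ref = pooled_two_sample_t(y[:n1], y[n1:])
            assert abs(t - t_ref) < 1e-9

    def test_matches_statsmodels_ols(self, rng):
        cohort = make_cohort(20, 15, rng)
        y = rng.normal(size=35) + 0.02 * cohort["age"].to_numpy()
        design = DesignSpec(covariates=("age", "sex", "bdi"), direction="two_sided")
        t, p = fit_group_glm(y, cohort, design)
        X = build_design_matrix(cohort, design.covariates)
        fit = sm.OLS(y, X).fit()
        assert t == pytest.approx(fit.tvalues[1], abs=1e-10)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_outcome_fully_explained_by_covariate(self, rng):
        cohort = make_cohort(10, 10, rng)
        y = cohort["age"].to_numpy().copy()
        t, p = fit_group_glm(y, cohort, DesignSpec(covariates=("age",), direction="fnd_lower"))
        assert abs(t) < 1e-8
        assert p == pytest.approx(0.5, abs=1e-8)

    def test_rank_deficiency_names_column(self, rng):
        cohort = make_cohort(5, 5, rng)
        cohort["bdi"] = 7.0  # constant covariate
        with pytest.raises(ValidationError, match="bdi"):
            fit_group_glm(np.ones(10), cohort, DesignSpec(covariates=("bdi",)))

    def test_too_small_group_rejected(self, rng):
        cohort = make_cohort(2, 8, rng)
        with pytest.raises(ValidationError, match="FND"):
            fit_group_glm(np.zeros(10), cohort, DesignSpec(covariates=()))

    def test_orthogonal_covariate_barely_changes_t(self, rng):
        # robustness: a covariate orthogonal to group and outcome only
        # perturbs t through one residual degree of freedom
        n1 = n2 = 1000
        cohort = make_cohort(n1, n2, rng)
        y = rng.normal(size=n1 + n2)
        X = build_design_matrix(cohort, ("age",))
        z = rng.normal(size=n1 + n2)
        basis = np.column_stack([X, y])
        z -= basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        cohort2 = cohort.copy()
        cohort2["bdi"] = z - z.min() + 1.0  # reuse an allowed covariate slot
        t1, _ = fit_group_glm(y, cohort, DesignSpec(covariates=("age",)))
        t2, _ = fit_group_glm(y, cohort2, DesignSpec(covariates=("age", "bdi")))
        assert abs(t1 - t2) < 1e-2


class TestTestNodes:
    def test_family_and_ordering(self, rng):
        cohort = make_cohort(10, 10, rng)
        wd = pd.DataFrame(rng.normal(10, 1, size=(20, 84)), columns=region_names())
        res = run_node_tests(wd, cohort, DesignSpec(covariates=("age", "sex")))
        assert len(res) == 84
        assert res["p_unc"].is_monotonic_increasing
        assert np.all(res["p_adj"] >= res["p_unc"] - 1e-15)
        assert (res["significant"] == (res["p_adj"] <= 0.05)).all()

    def test_misaligned_rows_rejected(self, rng):
        cohort = make_cohort(5, 5, rng)
        wd = pd.DataFrame(rng.normal(size=(9, 84)), columns=region_names())
        with pytest.raises(ValidationError, match="align"):
            run_node_tests(wd, cohort, DesignSpec())


class TestTestLinks:
    def _link_table(self, rng, n_subjects):
        conns = [SubjectConnectome(f"s{i}", "fa", random_symmetric_fa(rng))
                 for i in range(n_subjects)]
        return link_values(conns)

    def test_identical_matrices_give_no_findings(self, rng):
        mat = random_symmetric_fa(rng)
        conns = [SubjectConnectome(f"s{i}", "fa", mat.copy()) for i in range(12)]
        cohort = make_cohort(6, 6, rng)
        res = run_link_tests(link_values(conns), cohort, DesignSpec(covariates=()))
        assert not res["significant"].any()

    def test_planted_link_has_minimum_p(self, rng):
        hits = 0
        reps = 30
        for rep in range(reps):
            r = np.random.default_rng(rep)
            cohort = make_cohort(20, 20, r)
            values = r.normal(0.5, 0.05, size=(40, 3486))
            values[:20, 7] -= 0.12  # strong FND deficit on one link
            table = LinkTable(subject_ids=list(cohort["subject_id"]), weight_kind="fa",
                              values=values)
            res = run_link_tests(table, cohort, DesignSpec(covariates=(), direction="fnd_lower"))
            tested = res[res["tested"]]
            best = tested.loc[tested["p_unc"].idxmin()]
            names = region_names()
            hits += (best["region_a"], best["region_b"]) == (names[0], names[8])
        assert hits >= int(0.9 * reps)

    def test_presence_threshold_excludes_zeroed_link(self, rng):
        cohort = make_cohort(5, 5, rng)
        values = rng.uniform(0.2, 0.8, size=(10, 3486))
        values[0, 5] = 0.0
        table = LinkTable(subject_ids=list(cohort["subject_id"]), weight_kind="fa",
                          values=values)
        res = run_link_tests(table, cohort, DesignSpec(covariates=()), presence_threshold=1.0)
        assert not res.loc[5, "tested"]
        assert np.isnan(res.loc[5, "p_unc"])  # absent, not failed
        assert res.drop(index=5)["tested"].all()

    def test_fdr_family_is_tested_links_only(self, rng):
        cohort = make_cohort(5, 5, rng)
        values = rng.uniform(0.2, 0.8, size=(10, 3486))
        values[:, :3000] = 0.0
        table = LinkTable(subject_ids=list(cohort["subject_id"]), weight_kind="fa",
                          values=values)
        res = run_link_tests(table, cohort, DesignSpec(covariates=()), presence_threshold=0.5)
        assert res["tested"].sum() == 486


class TestRestriction:
    def _random_results(self, rng):
        names = region_names()
        pairs = [(names[i], names[j]) for i in range(84) for j in range(i + 1, 84)]
        return pd.DataFrame({
            "region_a": [a for a, _ in pairs],
            "region_b": [b for _, b in pairs],
            "significant": rng.random(len(pairs)) < 0.1,
        })

    def test_empty_node_set(self, rng):
        kept, counts = restrict_links_to_nodes(self._random_results(rng), set())
        assert kept.empty
        assert counts.empty

    def test_single_region_all_significant(self, rng):
        res = self._random_results(rng)
        res["significant"] = True
        node = region_names()[17]
        kept, counts = restrict_links_to_nodes(res, {node})
        assert counts[node] == 83

    def test_counts_match_bruteforce(self, rng):
        res = self._random_results(rng)
        nodes = set(rng.choice(region_names(), size=10, replace=False))
        kept, counts = restrict_links_to_nodes(res, nodes)
        sig = res[res["significant"]]
        for node in nodes:
            expected = sum(1 for _, row in sig.iterrows()
                           if (row["region_a"] in nodes or row["region_b"] in nodes)
                           and node in (row["region_a"], row["region_b"]))
            assert counts[node] == expected

    def test_unknown_region_rejected(self, rng):
        with pytest.raises(ValidationError, match="unknown"):
            restrict_links_to_nodes(self._random_results(rng), {"not-a-region"})
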