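"""Rank-based association tests, BH dialects and cohort-level screening."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ifnstab.screen import (
    ClinicalCohort,
    DEFAULT_VARIABLE_SPEC,
    add_derived_columns,
    bh_adjust,
    group_compare,
    mann_whitney_test,
    screen_cohort,
    spearman_test,
    subgroup_filter,
)


class TestSpearman:
    @pytest.mark.parametrize(
        "y,expected",
        [([1, 2, 3, 4], 1.0), ([4, 3, 2, 1], -1.0)],
    )
    def test_perfect_monotone(self, y, expected):
        out = spearman_test([1, 2, 3, 4], y)
        assert out.statistic == pytest.approx(expected)
        assert out.p == pytest.approx(0.0)

    def test_exact_p_matches_permutation_enumeration(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        out = spearman_test(x, y, method="exact")
        assert out.statistic == pytest.approx(0.6)  # 1 - 6*4/(4*15)
        # independent oracle: enumerate all 24 orderings of y
        rx = np.asarray(x, dtype=float)
        count = total = 0
        for perm in itertools.permutations(y):
            r = np.corrcoef(
                stats.rankdata(rx), stats.rankdata(perm)
            )[0, 1]
            total += 1
            count += abs(r) >= 0.6 - 1e-12
        assert out.p == pytest.approx(count / total)

    def test_not_computable_cases(self):
        assert not spearman_test([1, 2, 3], [1, 2, 3]).computable  # n < 4
        assert not spearman_test([1, 1, 1, 1], [1, 2, 3, 4]).computable

    def test_missing_removed_pairwise(self):
        out = spearman_test(
            [1, 2, 3, 4, np.nan], [1, 2, 3, np.nan, 5]
        )
        assert out.n_used == 3  # -> flagged, not crashed
        assert not out.computable

    @given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=5, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_antisymmetric_in_y(self, y):
        x = list(range(len(y)))
        a = spearman_test(x, y)
        b = spearman_test(x, [-v for v in y])
        if a.computable:
            assert b.statistic == pytest.approx(-a.statistic, abs=1e-9)

    def test_asymptotic_close_to_exact_at_n7(self, rng):
        # t approximation vs full enumeration; deviation bound measured
        # on this family of draws with generous headroom
        for _ in range(15):
            x, y = rng.normal(size=7), rng.normal(size=7)
            pa = spearman_test(x, y).p
            pe = spearman_test(x, y, method="exact").p
            assert abs(pa - pe) < 0.05


class TestMannWhitney:
    def test_complete_separation_exact(self):
        out = mann_whitney_test([1, 2, 3], [4, 5, 6], method="exact")
        assert out.statistic == 0.0
        assert out.p == pytest.approx(0.1)  # 2 of C(6,3)=20 assignments

    def test_identical_groups_give_central_u(self):
        a = [1.0, 2.0, 5.5]
        out = mann_whitney_test(a, a)
        assert out.statistic == pytest.approx(len(a) ** 2 / 2)

    def test_empty_group_flagged(self):
        assert not mann_whitney_test([], [1.0, 2.0]).computable

    @given(
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8),
        st.lists(st.floats(-50, 50, allow_nan=False), min_size=2, max_size=8),
    )
    @settings(max_examples=40, deadline=None)
    def test_u_statistics_sum_to_product(self, a, b):
        ua = mann_whitney_test(a, b).statistic
        ub = mann_whitney_test(b, a).statistic
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_asymptotic_within_002_of_enumeration(self, rng):
        for _ in range(15):
            a, b = rng.normal(size=5), rng.normal(size=6)
            pa = mann_whitney_test(a, b).p
            pe = mann_whitney_test(a, b, method="exact").p
            assert abs(pa - pe) < 0.02

    def test_exact_mode_handles_ties(self):
        out = mann_whitney_test([1, 1, 2], [1, 2, 2, 3], method="exact")
        assert 0.0 < out.p <= 1.0


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.04], m=1).tolist() == [0.04]

    def test_plain_equals_monotone_for_increasing_p(self):
        p = [0.001, 0.01, 0.02, 0.5, 0.9]
        np.testing.assert_allclose(
            bh_adjust(p, mode="plain"), bh_adjust(p, mode="monotone")
        )

    def test_plain_ties_share_smaller_rank(self):
        q = bh_adjust([0.2, 0.2, 0.01], mode="plain")
        assert q[0] == q[1] == pytest.approx(0.2 * 3 / 2)

    def test_monotone_matches_definitional_oracle(self, rng):
        p = rng.random(30)
        m = 35
        q = bh_adjust(p, m=m, mode="monotone")
        # brute force: min over suffix of p_(j) * m / j
        order = np.argsort(p)
        for pos, idx in enumerate(order):
            expected = min(
                min(p[j] * m / (rank + 1) for rank, j in enumerate(order) if rank >= pos),
                1.0,
            )
            assert q[idx] == pytest.approx(expected, abs=1e-12)

    def test_monotone_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(25)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p, mode="monotone"), q_sm, atol=1e-12)

    def test_family_size_may_exceed_list_but_not_undercut(self):
        q = bh_adjust([0.001, 0.04], m=25, mode="plain")
        assert q[0] == pytest.approx(0.025)
        with pytest.raises(ValueError, match="smaller"):
            bh_adjust([0.1, 0.2, 0.3], m=2)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([0.5, np.nan])


def _toy_cohort(rng, n=60):
    ids = [f"P{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "cont_a": rng.normal(size=n),
            "cont_b": rng.normal(size=n),
            "flag_a": (rng.random(n) < 0.4).astype(float),
            "flag_b": (rng.random(n) < 0.3).astype(float),
        },
        index=pd.Index(ids, name="patient_id"),
    )
    types = {
        "cont_a": "continuous",
        "cont_b": "continuous",
        "flag_a": "dichotomous",
        "flag_b": "dichotomous",
    }
    scores = pd.Series(rng.normal(size=n), index=ids, name="ifn_score")
    return scores, ClinicalCohort(data=df, types=types)


class TestScreenCohort:
    SPEC = [
        ("cont_a", "spearman"),
        ("cont_b", "spearman"),
        ("flag_a", "mann_whitney"),
        ("flag_b", "mann_whitney"),
    ]

    def test_each_p_matches_single_test_recomputation(self, rng):
        scores, cohort = _toy_cohort(rng)
        results = screen_cohort(scores, cohort, self.SPEC)
        for r in results:
            v = cohort.data[r.variable]
            if r.test == "spearman":
                expected = spearman_test(scores.to_numpy(), v.to_numpy())
            else:
                s = scores.to_numpy()
                expected = mann_whitney_test(s[v == 1], s[v == 0])
            assert r.p == pytest.approx(expected.p, abs=1e-14)
            assert r.statistic == pytest.approx(expected.statistic, abs=1e-12)

    def test_variable_equal_to_score_is_perfect(self, rng):
        scores, cohort = _toy_cohort(rng)
        cohort.data["cont_a"] = scores
        r = screen_cohort(scores, cohort, [("cont_a", "spearman")])[0]
        assert r.statistic == pytest.approx(1.0)
        assert r.p == pytest.approx(0.0)

    def test_not_computable_entries_still_count_in_family_size(self, rng):
        scores, cohort = _toy_cohort(rng)
        cohort.data["all_missing"] = np.nan
        cohort.types["all_missing"] = "continuous"
        spec = self.SPEC + [("all_missing", "spearman")]
        results = screen_cohort(scores, cohort, spec, bh_mode="plain")
        dead = results[-1]
        assert not dead.computable and np.isnan(dead.q)
        live_p = [r.p for r in results[:-1]]
        expected_q = bh_adjust(live_p, m=5, mode="plain")
        np.testing.assert_allclose([r.q for r in results[:-1]], expected_q)

    def test_row_order_invariance(self, rng):
        scores, cohort = _toy_cohort(rng)
        shuffled = ClinicalCohort(
            data=cohort.data.sample(frac=1, random_state=1), types=cohort.types
        )
        a = screen_cohort(scores, cohort, self.SPEC)
        b = screen_cohort(scores, shuffled, self.SPEC)
        for ra, rb in zip(a, b):
            assert ra.p == pytest.approx(rb.p, abs=1e-12)

    def test_unknown_variable_rejected(self, rng):
        scores, cohort = _toy_cohort(rng)
        with pytest.raises(KeyError, match="nope"):
            screen_cohort(scores, cohort, [("nope", "spearman")])

    def test_default_spec_runs_on_synthetic_cohort(self, null_cohort, null_scores):
        _, cohort, _ = null_cohort
        results = screen_cohort(null_scores, cohort)
        assert [r.variable for r in results] == [v for v, _ in DEFAULT_VARIABLE_SPEC]
        assert all(r.computable for r in results)


class TestSubgroupFilter:
    def _flags(self, rows):
        df = pd.DataFrame(
            rows, columns=["prednisone_use", "hcq_use", "ssz_use"]
        ).astype(float)
        df.index = [f"P{i}" for i in range(len(df))]
        types = {c: "dichotomous" for c in df.columns}
        return ClinicalCohort(data=df, types=types)

    def test_all_untreated_is_identity(self):
        cohort = self._flags([[0, 0, 0]] * 5)
        assert len(subgroup_filter(cohort)) == 5

    def test_all_treated_empties_cohort(self):
        cohort = self._flags([[1, 0, 0], [0, 1, 1]])
        assert len(subgroup_filter(cohort)) == 0

    def test_missing_flags_excluded(self):
        cohort = self._flags([[0, 0, 0], [0, np.nan, 0], [1, 0, 0]])
        assert subgroup_filter(cohort).patient_ids == ["P0"]

    def test_retained_count_matches_row_scan(self, null_cohort):
        _, cohort, _ = null_cohort
        sub = subgroup_filter(cohort)
        expected = sum(
            1
            for _, row in cohort.data.iterrows()
            if row["prednisone_use"] == 0 and row["hcq_use"] == 0 and row["ssz_use"] == 0
        )
        assert len(sub) == expected


class TestGroupCompare:
    def test_all_untreated_single_stratum(self, rng):
        n = 20
        ids = [f"P{i}" for i in range(n)]
        df = pd.DataFrame(
            {"prednisone_use": 0.0, "hcq_use": 0.0, "ssz_use": 0.0}, index=ids
        )
        cohort = ClinicalCohort(df, {c: "dichotomous" for c in df.columns})
        scores = pd.Series(rng.normal(size=n), index=ids)
        gc = group_compare(scores, cohort)
        assert gc.strata.loc["0", "n"] == n
        assert not gc.pairwise["computable"].any()

    def test_stratum_assignment_matches_flag_count(self, null_cohort, null_scores):
        _, cohort, _ = null_cohort
        gc = group_compare(null_scores, cohort)
        counts = cohort.data[["prednisone_use", "hcq_use", "ssz_use"]].sum(axis=1)
        assert gc.strata.loc["0", "n"] == int((counts == 0).sum())
        assert gc.strata.loc["1", "n"] == int((counts == 1).sum())
        assert gc.strata.loc["2+", "n"] == int((counts >= 2).sum())


class TestDerivedColumns:
    def test_rules_recomputed_from_parents(self):
        df = pd.DataFrame(
            {
                "esr": [25.0, 10.0, np.nan],
                "crp": [10.0, 9.9, 11.0],
                "acpa_titer": [2000.0, 100.0, np.nan],
                "rf_positive": [1.0, 0.0, np.nan],
                "acpa_positive": [1.0, 0.0, 1.0],
                "prednisone_use": [1.0, 0.0, 0.0],
                "hcq_use": [0.0, 0.0, np.nan],
                "ssz_use": [0.0, 0.0, 0.0],
            },
            index=["a", "b", "c"],
        )
        types = {
            "esr": "continuous",
            "crp": "continuous",
            "acpa_titer": "continuous",
            "rf_positive": "dichotomous",
            "acpa_positive": "dichotomous",
            "prednisone_use": "dichotomous",
            "hcq_use": "dichotomous",
            "ssz_use": "dichotomous",
        }
        out = add_derived_columns(ClinicalCohort(df, types), acpa_cutoff=500.0).data
        assert out["esr_gt20"].tolist()[:2] == [1.0, 0.0]
        assert np.isnan(out["esr_gt20"].iloc[2])
        assert out["crp_ge10"].tolist() == [1.0, 0.0, 1.0]
        assert out["acpa_high"].iloc[0] == 1.0 and out["acpa_high"].iloc[1] == 0.0
        assert out["rf_and_acpa_positive"].iloc[0] == 1.0
        assert np.isnan(out["rf_and_acpa_positive"].iloc[2])
        assert out["rf_and_acpa_negative"].iloc[1] == 1.0
        # treated with prednisone: any_suppressor certain despite nothing missing
        assert out["any_suppressor"].iloc[0] == 1.0
        assert out["any_suppressor"].iloc[1] == 0.0
        # unknown HCQ, no observed use -> unknown overall
        assert np.isnan(out["any_suppressor"].iloc[2])

    def test_dichotomous_validation(self):
        df = pd.DataFrame({"flag": [0.0, 2.0]})
        with pytest.raises(ValueError, match="dichotomous"):
            ClinicalCohort(df, {"flag": "dichotomous"})
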