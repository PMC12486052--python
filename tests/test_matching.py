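import itertools

import numpy as np
import pandas as pd
import pytest

from orncausal.cohort import CohortSchema, CohortTable
from orncausal.matching import (MatchedCohort, SeparationError, balance_tests,
                                estimate_propensity, match_cohort,
                                optimal_match)
from orncausal.synthetic import SimConfig, generate


def _scores_series(vmat, pbspt):
    ids = [f"v{i}" for i in range(len(vmat))] + [f"p{i}" for i in range(len(pbspt))]
    scores = pd.Series(list(vmat) + list(pbspt), index=ids)
    groups = pd.Series(["VMAT"] * len(vmat) + ["PBSPT"] * len(pbspt), index=ids)
    return scores, groups


def _brute_force_total(vmat, pbspt, distance="raw"):
    """Exhaustive minimum total |score difference| over 1:1 assignments."""
    a, b = (vmat, pbspt) if len(vmat) <= len(pbspt) else (pbspt, vmat)
    best = np.inf
    for subset in itertools.permutations(range(len(b)), len(a)):
        best = min(best, sum(abs(a[i] - b[j]) for i, j in enumerate(subset)))
    return best


class TestOptimalMatch:
    def test_beats_greedy_on_crossing_example(self):
        scores, groups = _scores_series([0.1, 0.5], [0.45, 0.15])
        m = optimal_match(scores, groups, distance="raw")
        assert set(m.pairs) == {("v0", "p1"), ("v1", "p0")}
        total = sum(abs(scores[a] - scores[b]) for a, b in m.pairs)
        assert total == pytest.approx(0.10)  # greedy-from-0.5 would give 0.40

    def test_identical_multisets_have_zero_distance(self):
        scores, groups = _scores_series([0.2, 0.6, 0.4], [0.4, 0.2, 0.6])
        m = optimal_match(scores, groups, distance="raw")
        assert sum(abs(scores[a] - scores[b]) for a, b in m.pairs) == pytest.approx(0.0)

    @pytest.mark.parametrize("n_vmat,n_pbspt", [(3, 3), (5, 4), (7, 7), (2, 6)])
    def test_matches_brute_force_minimum(self, n_vmat, n_pbspt):
        rng = np.random.default_rng(n_vmat * 10 + n_pbspt)
        for _ in range(5):
            sv = rng.uniform(0.05, 0.95, n_vmat)
            sp = rng.uniform(0.05, 0.95, n_pbspt)
            scores, groups = _scores_series(sv, sp)
            m = optimal_match(scores, groups, distance="raw")
            total = sum(abs(scores[a] - scores[b]) for a, b in m.pairs)
            assert total == pytest.approx(_brute_force_total(list(sv), list(sp)))

    def test_each_patient_matched_at_most_once(self):
        rng = np.random.default_rng(0)
        scores, groups = _scores_series(rng.uniform(0.1, 0.9, 30),
                                        rng.uniform(0.1, 0.9, 12))
        m = optimal_match(scores, groups)
        assert len(m.pairs) == 12
        assert len(set(m.matched_ids)) == 24

    def test_empty_group_raises(self):
        scores, groups = _scores_series([0.5], [])
        with pytest.raises(ValueError):
            optimal_match(scores, groups)


class TestPropensity:
    def test_unconfounded_scores_center_on_group_fraction(self):
        t = generate(SimConfig(seed=31, confounding_strength=0.0,
                               n_vmat=600, n_pbspt=400))
        scores = estimate_propensity(t)
        assert scores.between(0, 1).all()
        assert abs(scores.mean() - 0.4) < 0.03

    def test_perfectly_predictive_covariate_raises_separation(self):
        t = generate(SimConfig(seed=3, n_per_modality=50))
        df = t.df.copy()
        df["diabetes"] = np.where(df["modality"] == "PBSPT", "yes", "no")
        with pytest.raises(SeparationError, match="diabetes"):
            estimate_propensity(CohortTable(df, t.schema))

    def test_duplicate_rows_get_identical_scores(self):
        t = generate(SimConfig(seed=5, n_per_modality=60))
        df = t.df.copy()
        clone = df.iloc[[0]].assign(patient_id="clone-of-0")
        t2 = CohortTable(pd.concat([df, clone], ignore_index=True), t.schema)
        scores = estimate_propensity(t2)
        assert scores.loc[df.loc[0, "patient_id"]] == pytest.approx(
            scores.loc["clone-of-0"], abs=1e-12)


class TestBalanceTests:
    def test_equal_contingency_table_gives_p_one(self, small_cohort):
        df = small_cohort.df.head(40).copy()
        df["modality"] = ["VMAT", "PBSPT"] * 20
        df["diabetes"] = (["yes"] * 10 + ["no"] * 10) * 2
        t = CohortTable(df, small_cohort.schema, validate=False)
        res = balance_tests(t)
        row = res[res.covariate == "diabetes"].iloc[0]
        assert row.statistic == pytest.approx(0.0)
        assert row.p_value == pytest.approx(1.0)

    def test_identical_age_distributions_give_p_one(self, small_cohort):
        df = small_cohort.df.head(40).copy()
        df["modality"] = ["VMAT"] * 20 + ["PBSPT"] * 20
        df["age"] = list(range(20)) * 2
        t = CohortTable(df, small_cohort.schema, validate=False)
        row = balance_tests(t).query("covariate == 'age'").iloc[0]
        assert row.statistic == pytest.approx(0.0, abs=1e-12)
        assert row.p_value == pytest.approx(1.0)

    def test_single_level_covariate_warns_and_reports_one(self, small_cohort):
        df = small_cohort.df.copy()
        df["diabetes"] = "no"
        t = CohortTable(df, small_cohort.schema, validate=False)
        with pytest.warns(UserWarning, match="single level"):
            res = balance_tests(t)
        assert res.query("covariate == 'diabetes'").iloc[0].p_value == 1.0


class TestMatchCohort:
    def test_confounded_cohort_balances_after_matching(self):
        """Pre-match imbalance (p < 0.001 somewhere) disappears after 1:1
        optimal matching (all p > 0.05) - the classic before/after
        balance-table pattern of a matched-cohort study."""
        improved = 0
        for s in range(3):
            t = generate(SimConfig(seed=600 + s, n_vmat=931, n_pbspt=335))
            m = match_cohort(t)
            before = m.balance_before.p_value.min()
            after = m.balance_after.p_value.min()
            if before < 0.001 and after > 0.05:
                improved += 1
        assert improved >= 2

    def test_matching_never_worsens_propensity_balance(self):
        t = generate(SimConfig(seed=77, n_vmat=500, n_pbspt=250))
        m = match_cohort(t)
        s = m.propensity
        g = t.modality.set_axis(s.index)

        def std_diff(ids):
            a = s[ids][g[ids] == "VMAT"]
            b = s[ids][g[ids] == "PBSPT"]
            pooled = np.sqrt((a.var() + b.var()) / 2)
            return abs(a.mean() - b.mean()) / pooled

        assert std_diff(s.index) >= std_diff(pd.Index(m.matched_ids)) - 1e-9
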