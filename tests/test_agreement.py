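"""Agreement statistics: Wilson intervals, Cohen's kappa, report, power."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magicperf.agreement import (RatingTableError, agreement_report,
                                 cohens_kappa_ci, kappa_and_se,
                                 kappa_power_simulation, percent_agreement_ci,
                                 validate_rating_table)

import oracles


def _pairs(matches, n, mismatch_cat=2):
    a = np.ones(n, dtype=int)
    b = np.concatenate([np.ones(matches, dtype=int),
                        np.full(n - matches, mismatch_cat, dtype=int)])
    return a, b


class TestPercentAgreement:
    @pytest.mark.parametrize("k,n,lo,hi", [
        (113, 140, 73.39, 86.39),
        (127, 140, 84.76, 94.49),
        (133, 140, 90.04, 97.56),
    ])
    def test_wilson_interval_reference_values(self, k, n, lo, hi):
        a, b = _pairs(k, n)
        p, ci_lo, ci_hi = percent_agreement_ci(a, b)
        assert 100 * p == pytest.approx(100 * k / n, abs=0.005)
        assert 100 * ci_lo == pytest.approx(lo, abs=0.005)
        assert 100 * ci_hi == pytest.approx(hi, abs=0.005)

    def test_zero_matches_lower_bound_is_zero(self):
        a, b = _pairs(0, 25)
        _, lo, _ = percent_agreement_ci(a, b)
        assert lo == 0.0

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            percent_agreement_ci(np.array([]), np.array([]))

    @given(st.integers(min_value=0, max_value=60),
           st.integers(min_value=1, max_value=60))
    @settings(max_examples=60, deadline=None, derandomize=True,
              database=None)
    def test_wilson_interval_contains_p_hat(self, k, n):
        k = min(k, n)
        a, b = _pairs(k, n)
        p, lo, hi = percent_agreement_ci(a, b)
        assert lo - 1e-12 <= p <= hi + 1e-12

    def test_width_shrinks_like_inverse_sqrt_n(self):
        widths = []
        for n in (50, 200, 800):
            a, b = _pairs(int(0.8 * n), n)
            _, lo, hi = percent_agreement_ci(a, b)
            widths.append(hi - lo)
        # quadrupling n should roughly halve the width
        assert widths[1] == pytest.approx(widths[0] / 2, rel=0.1)
        assert widths[2] == pytest.approx(widths[1] / 2, rel=0.1)


class TestCohensKappa:
    def test_perfect_diagonal_gives_one(self):
        a = np.array([1, 2, 3] * 8)
        k, lo, hi = cohens_kappa_ci(a, a.copy())
        assert k == 1.0 and hi == 1.0

    def test_degenerate_margin_gives_zero_kappa(self):
        # one arm constant: expected chance agreement equals observed
        a, b = _pairs(133, 140)
        k, lo, hi = cohens_kappa_ci(a, b)
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_fully_degenerate_table_zero_width_ci(self):
        a = np.ones(20, dtype=int)
        k, lo, hi = cohens_kappa_ci(a, a.copy())
        assert (k, lo, hi) == (0.0, 0.0, 0.0)

    def test_matches_hand_summed_marginals_and_sklearn(self, rng):
        from sklearn.metrics import cohen_kappa_score
        a = rng.integers(0, 3, 200)
        b = rng.integers(0, 3, 200)
        k, _ = kappa_and_se(a, b)
        assert k == pytest.approx(oracles.kappa_by_hand(a, b), rel=1e-12)
        assert k == pytest.approx(cohen_kappa_score(a, b), rel=1e-9)

    def test_invariant_to_category_relabeling(self, rng):
        a = rng.integers(0, 4, 150)
        b = rng.integers(0, 4, 150)
        relabel = {0: 7, 1: 3, 2: 9, 3: 1}
        a2 = np.vectorize(relabel.get)(a)
        b2 = np.vectorize(relabel.get)(b)
        assert kappa_and_se(a, b)[0] == pytest.approx(
            kappa_and_se(a2, b2)[0], rel=1e-12)

    def test_kappa_never_exceeds_one(self, rng):
        for _ in range(20):
            a = rng.integers(0, 3, 30)
            b = rng.integers(0, 3, 30)
            k, lo, hi = cohens_kappa_ci(a, b)
            assert k <= 1.0 and -1.0 <= lo <= k <= hi <= 1.0


class TestAgreementReport:
    @staticmethod
    def _table(n_raters=7, n_patients=20, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for r in range(n_raters):
            for p in range(n_patients):
                for q in ("1", "2A", "3"):
                    truth = int(rng.integers(1, 4))
                    for arm in ("synthetic", "real"):
                        resp = truth if rng.random() < 0.8 \
                            else int(rng.integers(1, 4))
                        rows.append(dict(rater=f"r{r}", patient=f"p{p}",
                                         question=q, arm=arm, response=resp))
        return pd.DataFrame(rows)

    def test_full_design_yields_n_140(self):
        report = agreement_report(self._table())
        assert (report["n_pairs"] == 140).all()

    def test_known_match_counts_reproduced(self):
        rows = []
        for i in range(10):
            resp_s = 1
            resp_r = 1 if i < 7 else 2
            rows.append(dict(rater="r0", patient=f"p{i}", question="1",
                             arm="synthetic", response=resp_s))
            rows.append(dict(rater="r0", patient=f"p{i}", question="1",
                             arm="real", response=resp_r))
        report = agreement_report(pd.DataFrame(rows))
        assert report.loc[0, "agreement_pct"] == pytest.approx(70.0)

    def test_row_order_invariance(self):
        t = self._table(seed=3)
        r1 = agreement_report(t)
        r2 = agreement_report(t.sample(frac=1.0, random_state=9))
        pd.testing.assert_frame_equal(r1.reset_index(drop=True),
                                      r2.reset_index(drop=True))

    def test_missing_arm_dropped_and_counted(self):
        t = self._table()
        drop = (t["question"] == "1") & (t["patient"] == "p0") \
            & (t["rater"] == "r0") & (t["arm"] == "real")
        report = agreement_report(t[~drop])
        q1 = report[report["question"] == "1"].iloc[0]
        assert q1["n_pairs"] == 139 and q1["n_dropped"] == 1

    def test_unknown_question_rejected(self):
        t = pd.DataFrame([dict(rater="r", patient="p", question="9",
                               arm="real", response=1)])
        with pytest.raises(RatingTableError, match="question"):
            validate_rating_table(t)

    def test_duplicate_rating_rejected(self):
        t = pd.DataFrame([dict(rater="r", patient="p", question="1",
                               arm="real", response=1)] * 2)
        with pytest.raises(RatingTableError, match="duplicate"):
            validate_rating_table(t)


class TestKappaPower:
    MARGINALS = (0.5, 0.3, 0.2)

    def test_null_power_matches_alpha(self):
        power, se = kappa_power_simulation(0.0, 140, self.MARGINALS,
                                           reps=600, seed=11)
        assert abs(power - 0.05) <= 3 * max(se, 0.01)

    def test_power_non_decreasing_in_n(self):
        powers = [kappa_power_simulation(0.35, n, self.MARGINALS,
                                         reps=400, seed=5)[0]
                  for n in (50, 140, 500)]
        assert powers[0] <= powers[1] + 0.05
        assert powers[1] <= powers[2] + 0.05

    def test_moderate_kappa_well_powered_at_study_size(self):
        power, _ = kappa_power_simulation(0.35, 140, self.MARGINALS,
                                          reps=400, seed=7)
        assert power > 0.8

    def test_deterministic_for_fixed_seed(self):
        a = kappa_power_simulation(0.2, 100, self.MARGINALS, reps=200, seed=3)
        b = kappa_power_simulation(0.2, 100, self.MARGINALS, reps=200, seed=3)
        assert a == b

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(ValueError):
            kappa_power_simulation(0.2, 100, [1.0], reps=200, seed=0)
        with pytest.raises(ValueError):
            kappa_power_simulation(0.2, 100, [0.7, 0.2], reps=200, seed=0)
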