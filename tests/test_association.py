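"""2x2 tests against enumeration oracles, KM closed form, log-rank checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from clonedivergence import (
    Cohort,
    Contingency2x2,
    GeneratorConfig,
    clinical_response_association,
    gene_response_screen,
    generate_cohort,
    km_curve,
    logrank_test,
)
from clonedivergence.association import (
    AssociationError,
    fisher_exact_bruteforce,
    test_2x2 as run_2x2,
)

from conftest import make_clinical, make_pair


class TestTwoByTwo:
    def test_printed_parallel_vs_linear_response_p(self):
        """72.2% of 18 vs 40.0% of 20 responders: Fisher p = 0.059."""
        res = run_2x2(Contingency2x2(13, 5, 8, 12), method="fisher")
        assert res.p_value == pytest.approx(0.059, abs=1e-3)

    def test_printed_ihc_chi2_and_p(self):
        """12/38 vs 7/23 positive: chi2 = 0.009, p = 0.925 (no correction)."""
        res = run_2x2(Contingency2x2(12, 26, 7, 16), method="chi2")
        assert round(res.statistic, 3) == 0.009
        assert round(res.p_value, 3) == 0.925

    def test_balanced_table_no_association(self):
        tab = Contingency2x2(5, 5, 5, 5)
        assert run_2x2(tab, method="fisher").p_value == pytest.approx(1.0)
        assert run_2x2(tab, method="chi2").statistic == pytest.approx(0.0)

    def test_auto_selects_fisher_on_small_expected_counts(self):
        small = Contingency2x2(1, 2, 3, 4)
        large = Contingency2x2(20, 20, 20, 20)
        assert run_2x2(small).method == "fisher_two_sided"
        assert run_2x2(large).method == "chi2_pearson"

    def test_invariant_to_simultaneous_row_and_column_swap(self):
        tab = Contingency2x2(7, 2, 3, 9)
        swapped = Contingency2x2(9, 3, 2, 7)
        for method in ("fisher", "chi2"):
            assert run_2x2(tab, method).p_value == pytest.approx(
                run_2x2(swapped, method).p_value
            )

    def test_all_zero_rejected(self):
        with pytest.raises(AssociationError):
            Contingency2x2(0, 0, 0, 0)

    @given(st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=80, deadline=None)
    def test_fisher_equals_bruteforce_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        tab = Contingency2x2(a, b, c, d)
        assert run_2x2(tab, method="fisher").p_value == pytest.approx(
            fisher_exact_bruteforce(tab), abs=1e-10
        )

    def test_odds_ratio_cross_product(self):
        assert run_2x2(Contingency2x2(6, 2, 3, 4), "fisher").odds_ratio == pytest.approx(4.0)
        assert run_2x2(Contingency2x2(5, 0, 3, 4), "fisher").odds_ratio == np.inf


class TestGeneResponseScreen:
    def _cohort(self, gene_in_ineffective_only=6, n_eff=41, n_ineff=33):
        pairs = []
        for i in range(n_eff):
            pid = f"E{i}"
            pairs.append(make_pair(pid, {(1, i + 1)}, {(1, i + 1)},
                                   clinical=make_clinical(pid, response="PR")))
        for i in range(n_ineff):
            pid = f"I{i}"
            sites = {(1, 1000 + i)}
            if i < gene_in_ineffective_only:
                sites.add((9, 500))  # the screened gene: G9_500
            pairs.append(make_pair(pid, sites, sites,
                                   clinical=make_clinical(pid, response="PD")))
        return Cohort(pairs=tuple(pairs))

    def test_gene_private_to_ineffective_group(self):
        """0/41 effective vs 6/33 ineffective: Fisher p ~ 0.0060."""
        screen = gene_response_screen(self._cohort(), min_count=3)
        row = screen.set_index("gene").loc["G9_500"]
        assert row["p_value"] == pytest.approx(0.0060, abs=5e-4)
        assert row["direction"] == "ineffective_enriched"

    def test_gene_only_in_effective_is_effective_enriched(self):
        pairs = []
        for i in range(6):
            pid = f"P{i}"
            resp = "PR" if i < 3 else "SD"
            sites = {(2, 100 + i)} | ({(5, 7)} if i < 3 else set())
            pairs.append(make_pair(pid, sites, sites,
                                   clinical=make_clinical(pid, response=resp)))
        screen = gene_response_screen(Cohort(pairs=tuple(pairs)), min_count=3)
        assert screen.set_index("gene").loc["G5_7", "direction"] == "effective_enriched"

    def test_min_count_omits_rare_genes(self):
        screen = gene_response_screen(self._cohort(gene_in_ineffective_only=2),
                                      min_count=3)
        assert "G9_500" not in set(screen["gene"])

    def test_missing_response_patients_counted_excluded(self):
        pairs = [
            make_pair("A", {(1, 1)}, {(1, 1)},
                      clinical=make_clinical("A", response="PR")),
            make_pair("B", {(1, 1)}, {(1, 1)},
                      clinical=make_clinical("B", response="SD")),
            make_pair("C", {(1, 1)}, {(1, 1)},
                      clinical=make_clinical("C", response=None)),
        ]
        screen = gene_response_screen(Cohort(pairs=tuple(pairs)), min_count=1)
        assert screen.attrs["n_excluded"] == 1
        assert screen.set_index("gene").loc["G1_1", "n_effective"] == 1


class TestKaplanMeier:
    def test_no_events_constant_one(self):
        curve = km_curve([5, 10, 15], [False, False, False])
        assert curve.survival_at(0) == 1.0
        assert curve.survival_at(20) == 1.0

    def test_half_after_single_death_of_two(self):
        curve = km_curve([12, 30], [True, False])
        assert curve.survival_at(12) == pytest.approx(0.5)
        assert curve.survival_at(11.9) == 1.0

    def test_hand_product_two_deaths_of_four(self):
        # deaths at 10 and 20, censored later: S(20) = (3/4)(2/3) = 0.5
        curve = km_curve([10, 20, 25, 30], [True, True, False, False])
        assert curve.survival_at(10) == pytest.approx(0.75)
        assert curve.survival_at(20) == pytest.approx(0.5)

    def test_equals_closed_form_product_on_random_data(self):
        rng = np.random.default_rng(3)
        times = rng.exponential(12, 40).round(1)
        events = rng.random(40) < 0.7
        curve = km_curve(times, events)
        # closed-form product over distinct event times
        order = np.argsort(times, kind="stable")
        t_sorted, e_sorted = times[order], events[order]
        for t_query in np.unique(t_sorted[e_sorted]):
            s = 1.0
            for t in np.unique(t_sorted[e_sorted & (t_sorted <= t_query)]):
                d = int(((t_sorted == t) & e_sorted).sum())
                n_at_risk = int((t_sorted >= t).sum())
                s *= 1 - d / n_at_risk
            assert curve.survival_at(t_query) == pytest.approx(s, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(AssociationError):
            km_curve([-1.0], [True])


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        t = [5.0, 10.0, 15.0]
        e = [True, True, False]
        res = logrank_test({"a": t, "b": t}, {"a": e, "b": e})
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_tabulated_two_group_example(self):
        """Deaths A at 1,2 and B at 3,4: enumerate the O-E/V table by hand."""
        times = {"A": [1.0, 2.0], "B": [3.0, 4.0]}
        events = {"A": [True, True], "B": [True, True]}
        # risk sets: t=1 (2A,2B) e_A=1/2; t=2 (1A,2B) e_A=1/3;
        #            t=3 (0A,2B) e_A=0;   t=4 (0A,1B) e_A=0
        o_minus_e = (1 - 0.5) + (1 - 1 / 3) + (0 - 0.0) + (0 - 0.0)
        v = (0.5 * 0.5) + (1 / 3 * 2 / 3)  # single-death hypergeometric variance
        expected_chi2 = o_minus_e**2 / v
        res = logrank_test(times, events)
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-9)
        assert res.df == 1

    def test_three_groups_df_two(self):
        groups = {g: [1.0 + i, 5.0 + i] for i, g in enumerate("abc")}
        events = {g: [True, False] for g in "abc"}
        assert logrank_test(groups, events).df == 2

    def test_no_events_anywhere_p_one_with_note(self):
        res = logrank_test({"a": [1.0], "b": [2.0]},
                           {"a": [False], "b": [False]})
        assert res.chi2 == 0.0 and res.p_value == 1.0 and res.note

    def test_null_calibration_uniform_p(self):
        """Two identical exponential groups: p-values ~ U(0,1) over 1000 reps."""
        rng = np.random.default_rng(77)
        ps = []
        for _ in range(1000):
            t1, t2 = rng.exponential(10, 25), rng.exponential(10, 25)
            horizon = 30.0
            res = logrank_test(
                {"a": np.minimum(t1, horizon), "b": np.minimum(t2, horizon)},
                {"a": t1 < horizon, "b": t2 < horizon},
            )
            ps.append(res.p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestClinicalAssociation:
    def test_generated_subtype_effect_detected(self):
        """Response tied to class, class tied to subtype: detectable at n=200."""
        cfg = GeneratorConfig(
            n_patients=200, seed=31, burden_mean=20.0,
            response_model={"parallel": 0.9, "intermediate": 0.5, "linear": 0.15},
            subtype_model={"parallel": 0.05, "intermediate": 0.5, "linear": 0.95},
        )
        cohort, _, _ = generate_cohort(cfg)
        res = clinical_response_association(cohort, "metastasis_subtype")
        assert res.p_value < 0.05

    def test_constant_factor_rejected(self):
        pairs = tuple(
            make_pair(f"P{i}", {(1, i + 1)}, {(1, i + 1)},
                      clinical=make_clinical(f"P{i}", "synchronous", "PR"))
            for i in range(4)
        )
        with pytest.raises(AssociationError, match="not binary"):
            clinical_response_association(Cohort(pairs=pairs), "metastasis_subtype")

    def test_type_i_error_calibrated_under_null(self):
        """No subtype-response link: Fisher p approximately uniform."""
        rng = np.random.default_rng(55)
        ps = []
        for _ in range(400):
            eff = rng.random(60) < 0.5
            sub = rng.random(60) < 0.5
            a = int((eff & sub).sum()); b = int((~eff & sub).sum())
            c = int((eff & ~sub).sum()); d = int((~eff & ~sub).sum())
            if min(a + b, c + d) == 0:
                continue
            ps.append(run_2x2(Contingency2x2(a, b, c, d), "fisher").p_value)
        # Fisher p is discrete and conservative: check it is not
        # anti-conservative (no excess of small p-values) and holds size
        assert stats.kstest(ps, "uniform", alternative="greater").pvalue > 0.01
        assert np.mean(np.asarray(ps) < 0.05) <= 0.07
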