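"""Moment formulas, method-of-moments inversion, and the discrimination rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtsticks import (
    AxonGeometry,
    MTSet,
    SectionPlan,
    SummaryStats,
    bootstrap_moment_fit,
    discriminate_change,
    expected_moments,
    fit_moments,
    power_simulation,
    predict_variance_number_only,
    simulate_experiment,
)
from mtsticks.synthetic import mutant_like_scenario, wt_like_scenario


class TestExpectedMoments:
    def test_direct_formula(self):
        mp = expected_moments(100, 5.0, 10.0)
        assert mp.mean == 50.0
        assert mp.variance == 25.0

    def test_full_length_sticks_are_deterministic(self):
        mp = expected_moments(42, 10.0, 10.0)
        assert mp.mean == 42.0
        assert mp.variance == 0.0

    def test_mutant_fit_round_trip_value(self):
        """The moment fit of (85, 25) pushed back through the forward
        formulas reproduces the input moments."""
        est = fit_moments(85.0, 25.0, 100.0)
        mp = expected_moments(est.m_hat, est.h_hat, 100.0)
        assert mp.mean == pytest.approx(85.0)
        assert mp.variance == pytest.approx(25.0)
        assert est.m_hat == pytest.approx(120.42, abs=0.01)
        assert est.h_hat == pytest.approx(70.59, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            expected_moments(10, 0.0, 5.0)
        with pytest.raises(ValueError):
            expected_moments(10, 6.0, 5.0)


class TestFitMoments:
    @settings(derandomize=True, max_examples=200)
    @given(
        m=st.floats(0.5, 1e4),
        p=st.floats(1e-6, 1 - 1e-6),
        L=st.floats(1e-2, 1e4),
    )
    def test_round_trip_is_exact(self, m, p, L):
        """fit_moments inverts expected_moments for every interior (m, h, L)."""
        h = p * L
        mp = expected_moments(m, h, L)
        est = fit_moments(mp.mean, mp.variance, L)
        assert est.feasible
        assert est.m_hat == pytest.approx(m, rel=1e-9)
        assert est.h_hat == pytest.approx(h, rel=1e-9)

    @settings(derandomize=True, max_examples=200)
    @given(
        mean=st.floats(0.1, 1e4),
        ratio=st.floats(0.0, 3.0),
    )
    def test_feasibility_characterizes_underdispersion(self, mean, ratio):
        """Feasible exactly when 0 < variance < mean."""
        variance = mean * ratio
        est = fit_moments(mean, variance, 100.0)
        assert est.feasible == (0.0 < variance < mean)

    def test_wild_type_summaries_are_overdispersed(self):
        """Printed wild-type moments (67, 81): variance > mean forces a
        negative p-hat, i.e. no fixed-m model fits."""
        est = fit_moments(67.0, 81.0, 100.0)
        assert not est.feasible
        assert est.p_hat < 0
        assert "overdispersed" in est.diagnosis

    def test_zero_variance_boundary(self):
        est = fit_moments(50.0, 0.0, 100.0)
        assert not est.feasible
        assert est.p_hat == 1.0

    def test_recovery_from_simulated_sections(self, axon):
        """From 10,000 fixed-m simulated sections the fit recovers m and h
        within 5% relative error."""
        m, h = 120, 70.0
        df = simulate_experiment(
            MTSet.fixed(m, h), axon, SectionPlan.random(10_000),
            n_animals=1, seed=23,
        )
        x = df["count"].to_numpy()
        est = fit_moments(float(x.mean()), float(x.var(ddof=1)),
                          axon.length_um)
        assert est.feasible
        assert est.m_hat == pytest.approx(m, rel=0.05)
        assert est.h_hat == pytest.approx(h, rel=0.05)

    def test_bootstrap_brackets_truth(self):
        est = fit_moments(85.0, 25.0, 100.0)
        boot = bootstrap_moment_fit(est, n_sections=200, L=100.0,
                                    reps=300, seed=5)
        assert boot["m_hat"]["q025"] < est.m_hat < boot["m_hat"]["q975"]
        assert boot["h_hat"]["q025"] < est.h_hat < boot["h_hat"]["q975"]


class TestPredictVarianceNumberOnly:
    def test_printed_summaries(self, wt_summary):
        """If only m rose to push the mean from 67 to 85, the variance must
        rise to 81·85/67 ≈ 102.76."""
        pred = predict_variance_number_only(wt_summary, 85.0)
        assert pred == pytest.approx(81.0 * 85.0 / 67.0)
        assert pred == pytest.approx(102.76, abs=0.01)

    def test_identity_at_reference_mean(self, wt_summary):
        assert predict_variance_number_only(wt_summary, 67.0) == pytest.approx(81.0)

    @settings(derandomize=True, max_examples=100)
    @given(scale=st.floats(0.1, 10.0), target=st.floats(0.1, 500.0))
    def test_linear_in_target_mean(self, scale, target):
        ref = SummaryStats(50.0, 6.0, 8)
        assert predict_variance_number_only(ref, scale * target) == pytest.approx(
            scale * predict_variance_number_only(ref, target), rel=1e-12
        )

    def test_doubling_m_doubles_variance_in_simulation(self, axon):
        """Oracle: at fixed h, doubling m doubles the empirical variance
        (Monte-Carlo, 20,000 sections per group)."""
        h = 70.0
        groups = {}
        for m, seed in ((60, 41), (120, 43)):
            df = simulate_experiment(
                MTSet.fixed(m, h), axon, SectionPlan.random(20_000),
                n_animals=1, seed=seed,
            )
            groups[m] = df["count"].to_numpy()
        v60 = groups[60].var(ddof=1)
        v120 = groups[120].var(ddof=1)
        se = v120 * np.sqrt(2 / groups[120].size) + 2 * v60 * np.sqrt(
            2 / groups[60].size
        )
        assert abs(v120 - 2 * v60) < 4 * se


class TestDiscriminateChange:
    def test_printed_summaries_favor_length(self, wt_summary, mut_summary):
        """Mean up (p=2e-4) but variance down: a number-only change would
        require the variance to rise, so the change in length is favored."""
        res = discriminate_change(wt_summary, mut_summary, alpha=0.05)
        assert res.verdict == "length-favored"
        assert res.product_inequality
        assert res.mean_test.p_value < 0.001
        assert res.predicted_variance_number_only == pytest.approx(102.76,
                                                                   abs=0.01)
        assert res.variance_test.p_value > 0.05

    def test_identical_summaries_give_no_change(self, wt_summary):
        res = discriminate_change(wt_summary, wt_summary)
        assert res.verdict == "no-change"
        assert not res.product_inequality

    def test_degenerate_constant_groups(self):
        s = SummaryStats(5.0, 0.0, 8)
        res = discriminate_change(s, s)
        assert res.verdict == "no-change"
        assert "degenerate" in res.note

    def test_group_swap_mirrors_the_one_sided_gate(self, wt_summary,
                                                   mut_summary):
        """Swapping the groups makes the one-sided mean gate fail, so the
        reversed comparison reports no-change."""
        res = discriminate_change(mut_summary, wt_summary)
        assert res.verdict == "no-change"
        assert res.mean_test.p_value > 0.999

    def test_number_only_change_is_called_number_consistent(self):
        """End-to-end oracle: simulate m doubled at fixed h, n=200 sections
        per group; the majority of replicates must come out
        number-consistent."""
        from mtsticks.synthetic import (
            FixedCount, FixedLength, ScenarioConfig, generate_counts,
            summarize_counts,
        )
        axon = AxonGeometry(100.0)
        plan = SectionPlan.random(1)

        def config(name, m, n):
            return ScenarioConfig(
                genotype=name, n_animals=n, m_dist=FixedCount(m),
                length_dist=FixedLength(70.0), axon=axon, plan=plan,
            )

        reps = 200
        ss = np.random.SeedSequence(77)
        verdicts = []
        for child in ss.spawn(reps):
            c1, c2 = child.spawn(2)
            g1 = summarize_counts(
                generate_counts(config("wt", 60, 200), seed=c1))["wt"]
            g2 = summarize_counts(
                generate_counts(config("mut", 120, 200), seed=c2))["mut"]
            verdicts.append(discriminate_change(g1, g2).verdict)
        frac = verdicts.count("number-consistent") / reps
        assert frac > 0.5


class TestPowerSimulation:
    def test_type_one_calibration_under_identical_scenarios(self):
        """With identical scenarios the one-sided mean test should reject at
        ~alpha (binomial 3 SE band)."""
        cfg, _ = mutant_like_scenario(n_sections=8)
        report = power_simulation(cfg, cfg, reps=400, alpha=0.05, seed=3)
        se = np.sqrt(0.05 * 0.95 / 400)
        assert abs(report.mean_test_rejection_rate - 0.05) < 3 * se

    def test_larger_length_effect_is_easier_to_detect(self):
        """Length-favored frequency is non-decreasing in the length effect
        (wild-type-like reference vs fixed-m mutants of growing mean)."""
        wt_cfg, _ = wt_like_scenario(n_sections=8)
        freqs = []
        for target_mean in (70.0, 85.0, 100.0):
            mut_cfg, _ = mutant_like_scenario(n_sections=8,
                                              target_mean=target_mean)
            rep = power_simulation(wt_cfg, mut_cfg, reps=150, seed=9)
            freqs.append(rep.frequency("length-favored"))
        assert freqs[0] <= freqs[1] + 0.1
        assert freqs[1] <= freqs[2] + 0.1
        assert freqs[2] > freqs[0]

    def test_frequencies_sum_to_one(self):
        wt_cfg, _ = wt_like_scenario(n_sections=8)
        mut_cfg, _ = mutant_like_scenario(n_sections=8)
        report = power_simulation(wt_cfg, mut_cfg, reps=50, seed=1)
        assert sum(report.frequencies.values()) == pytest.approx(1.0)
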