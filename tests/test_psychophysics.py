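"""Staircase engine, Gumbel ML fitting, bootstrap and zonal/global analysis."""

import numpy as np
import pytest

from blurfield.blur import sigmoid_profile
from blurfield.psychophysics import (FitError, GumbelPsychometric,
                                     SimulatedObserver, Staircase,
                                     compare_zonal_global, fit_gumbel,
                                     gumbel_function, run_session)


class TestStaircase:
    def test_bothersome_lowers_level_by_step(self):
        st = Staircase("z", 2.0)
        st.update(True)
        assert st.level_D == pytest.approx(1.85)
        st.update(False)
        assert st.level_D == pytest.approx(2.0)

    def test_clamped_at_bounds(self):
        st = Staircase("z", 0.0)
        st.update(True)
        assert st.level_D == 0.0
        st = Staircase("z", 5.0)
        st.update(False)
        assert st.level_D == 5.0

    def test_alternating_responses_oscillate_with_period_two_steps(self):
        st = Staircase("z", 2.0)
        for i in range(10):
            st.update(i % 2 == 0)
        levels = [h[0] for h in st.history]
        assert np.allclose(levels[::2], 2.0)
        assert np.allclose(levels[1::2], 1.85)
        assert np.ptp(levels) == pytest.approx(st.step_D)

    def test_non_binary_response_rejected(self):
        with pytest.raises(ValueError):
            Staircase("z", 2.0).update(0.5)

    def test_reversal_mean_converges_to_fifty_percent_point(self):
        """One-down/one-up fixed point: the mean reversal level approaches
        the observer's 50% point within one step size."""
        obs = SimulatedObserver({"c": 2.0}, true_beta=3.0, seed=12)
        records = run_session(["c"], obs, 200, seed=4, start_levels={"c": 1.0})
        st = Staircase("c", 1.0)
        for r in records:
            st.level_D = r.level_D
            st.history.append((r.level_D, r.bothersome))
        reversals = st.reversals()[2:]        # drop the approach phase
        p50 = 2.0 + np.log10(np.log(2.0)) / 3.0   # F(x)=0.5 for the Gumbel
        assert np.mean(reversals) == pytest.approx(p50, abs=st.step_D)


class TestSession:
    def test_seeded_sessions_identical(self):
        mk = lambda: SimulatedObserver({"a": 2.0, "b": 3.0}, seed=9)
        r1 = run_session(["a", "b"], mk(), 50, seed=2)
        r2 = run_session(["a", "b"], mk(), 50, seed=2)
        assert r1 == r2

    def test_zero_trials_empty_log(self):
        obs = SimulatedObserver({"a": 2.0}, seed=0)
        assert run_session(["a"], obs, 0, seed=0) == []

    def test_no_conditions_rejected(self):
        with pytest.raises(ValueError):
            run_session([], SimulatedObserver({"a": 1.0}), 10)

    def test_step_observer_brackets_threshold(self):
        """A near-deterministic observer with threshold 2.0 D keeps the
        staircase reversals within one step of 2.0."""
        obs = SimulatedObserver({"c": 2.0}, true_beta=40.0, seed=1)
        records = run_session(["c"], obs, 150, seed=3, start_levels={"c": 1.0})
        levels = [r.level_D for r in records[30:]]
        assert min(levels) >= 2.0 - 2 * 0.15
        assert max(levels) <= 2.0 + 2 * 0.15


class TestGumbelFit:
    def test_sixty_three_percent_identity(self):
        """With gamma = lambda = 0 the threshold is alpha and the function
        value there is 1 - 1/e, printed as 63%."""
        obs = SimulatedObserver({"c": 2.5}, true_beta=3.0, seed=7)
        records = run_session(["c"], obs, 150, seed=5, start_levels={"c": 1.5})
        fit = fit_gumbel(records, "c")
        assert fit.threshold_D == fit.alpha_D
        value = gumbel_function(fit.alpha_D, fit.alpha_D, fit.beta)
        assert value == pytest.approx(1 - np.exp(-1))
        assert round(100 * value) == 63

    def test_identical_responses_rejected(self):
        with pytest.raises(FitError):
            GumbelPsychometric([1.0, 1.15, 1.3], [1, 1, 1])

    def test_single_level_rejected(self):
        with pytest.raises(FitError):
            GumbelPsychometric([2.0, 2.0, 2.0, 2.0], [0, 1, 0, 1])

    def test_complete_separation_rejected(self):
        with pytest.raises(FitError):
            GumbelPsychometric([1.0, 1.15, 1.3, 1.45], [0, 0, 1, 1])

    def test_parameter_recovery_rate(self):
        """alpha = 2.0, beta = 3, 200 staircase trials: the fit recovers
        alpha within +/-0.15 D in at least 95% of 100 seeded replicates."""
        hits = 0
        for rep in range(100):
            obs = SimulatedObserver({"c": 2.0}, true_beta=3.0, seed=1000 + rep)
            records = run_session(["c"], obs, 200, seed=rep,
                                  start_levels={"c": 1.0})
            try:
                fit = fit_gumbel(records, "c")
                hits += abs(fit.alpha_D - 2.0) <= 0.15
            except FitError:
                pass
        assert hits >= 95

    def test_summary_mentions_estimates(self):
        obs = SimulatedObserver({"c": 2.0}, seed=3)
        records = run_session(["c"], obs, 120, seed=6, start_levels={"c": 1.0})
        fit = fit_gumbel(records, "c")
        text = fit.summary()
        assert "alpha" in text and "threshold" in text and "63%" in text


class TestBootstrap:
    @pytest.fixture(scope="class")
    def fitted(self):
        obs = SimulatedObserver({"c": 2.0}, true_beta=3.0, seed=21)
        records = run_session(["c"], obs, 200, seed=8, start_levels={"c": 1.0})
        return fit_gumbel(records, "c")

    def test_seeded_bootstrap_reproducible(self, fitted):
        se1 = fitted.bootstrap_se(n_boot=50, seed=11)
        se2 = fitted.bootstrap_se(n_boot=50, seed=11)
        assert se1 == se2

    def test_se_below_step_for_steep_observer(self):
        obs = SimulatedObserver({"c": 2.0}, true_beta=8.0, seed=2)
        records = run_session(["c"], obs, 250, seed=9, start_levels={"c": 1.0})
        fit = fit_gumbel(records, "c")
        se = fit.bootstrap_se(n_boot=100, seed=1)
        assert se < 0.15

    def test_single_bootstrap_is_zero_with_warning(self, fitted):
        with pytest.warns(UserWarning):
            se = fitted.bootstrap_se(n_boot=1, seed=0)
        assert se == 0.0

    def test_coverage_and_bias(self):
        """Bootstrap +/-1.96 SE intervals cover the true threshold ~95% of
        the time and the estimator bias stays below 0.05 D."""
        alphas, covered = [], 0
        n_rep = 120
        for rep in range(n_rep):
            obs = SimulatedObserver({"c": 2.0}, true_beta=3.0, seed=5000 + rep)
            records = run_session(["c"], obs, 150, seed=300 + rep,
                                  start_levels={"c": 1.0})
            fit = fit_gumbel(records, "c")
            se = fit.bootstrap_se(n_boot=100, seed=rep)
            alphas.append(fit.alpha_D)
            covered += abs(fit.alpha_D - 2.0) <= 1.96 * se
        assert abs(np.mean(alphas) - 2.0) < 0.05
        assert 0.90 <= covered / n_rep <= 1.0


class TestCompareZonalGlobal:
    ZONES = (1.5, 3.0, 4.5, 6.0, 7.5)

    def test_identity_when_global_matches_zonal(self):
        """If each zone's ring-averaged global defocus equals its zonal
        threshold, the differences vanish."""
        K, a = 0.0, 3.0
        outer = np.arange(1, 21) * 0.375
        table = a * sigmoid_profile(outer / 7.5, K)
        zonal = {z: table[(outer > z - 1.5) & (outer <= z)].mean()
                 for z in self.ZONES}
        cmp = compare_zonal_global(zonal, {K: a})
        assert np.allclose(cmp.differences.values, 0.0, atol=1e-12)

    def test_outer_zone_equals_ring_table_average_oracle(self):
        K, a = 4.0, 5.0
        zonal = {z: 1.0 for z in self.ZONES}
        cmp = compare_zonal_global(zonal, {K: a})
        outer = np.arange(1, 21) * 0.375
        brute = np.mean([a * sigmoid_profile(e / 7.5, K)
                         for e in outer[(outer > 6.0) & (outer <= 7.5)]])
        assert cmp.global_zone_equivalent.loc[7.5, K] == pytest.approx(brute)
        assert cmp.differences.loc[7.5, K] == pytest.approx(brute - 1.0)

    def test_zone_centers_printed_values(self):
        cmp = compare_zonal_global({z: 1.0 for z in self.ZONES}, {4.0: 2.0})
        assert cmp.zone_centers_deg == (0.75, 2.25, 3.75, 5.25, 6.75)

    def test_four_rings_per_zone_default_five_optional(self):
        cmp4 = compare_zonal_global({z: 1.0 for z in self.ZONES}, {4.0: 2.0})
        assert all(len(r) == 4 for r in cmp4.rings_per_zone.values())
        cmp5 = compare_zonal_global({z: 1.0 for z in self.ZONES}, {4.0: 2.0},
                                    rings_mode=5)
        lens = [len(r) for z, r in sorted(cmp5.rings_per_zone.items())]
        assert lens == [4, 5, 5, 5, 5]       # innermost zone has no ring at 0

    def test_missing_fits_rejected(self):
        with pytest.raises(ValueError):
            compare_zonal_global({1.5: None}, {4.0: 2.0})
        with pytest.raises(ValueError):
            compare_zonal_global({}, {4.0: 2.0})
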