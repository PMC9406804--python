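"""Subject- and population-level simulation of reserve decay and ANM."""

import math

import numpy as np
import pytest
from scipy import stats

from pfwalk import (
    ContinuousParams,
    DriftSchedule,
    InterventionEvent,
    SubjectSpec,
    SupplyDistribution,
    apply_acute_loss,
    drift_at_age,
    expected_reserve,
    sample_drift_multipliers,
    sample_starting_supply,
    schedule_survival,
    simulate_population,
    simulate_subject,
    survival,
)
from .conftest import HUMAN, MEDIAN_SUPPLY, THRESHOLD

MEDIAN_SUPPLY_INT = round(math.exp(12.686))  # 323,191


class TestStartingSupply:
    def test_degenerate_distribution_gives_median(self, rng):
        draws = sample_starting_supply(100, SupplyDistribution(sigma=0.0), rng)
        assert np.all(draws == MEDIAN_SUPPLY_INT)
        assert f"{draws[0]:.3g}" == f"{3.23e5:.3g}"

    def test_median_of_draws_near_exp_mu(self, rng):
        draws = sample_starting_supply(200_000, SupplyDistribution(), rng)
        assert abs(np.median(draws) / math.exp(12.686) - 1) < 0.01

    def test_log_draws_are_normal(self, rng):
        draws = sample_starting_supply(300_000, SupplyDistribution(), rng)
        assert abs(stats.skew(np.log(draws))) < 0.02


class TestDriftHeterogeneity:
    def test_zero_cv_gives_unit_multipliers(self, rng):
        assert np.all(sample_drift_multipliers(50, 0.0, rng) == 1.0)

    def test_moments(self, rng):
        m = sample_drift_multipliers(100_000, 0.03, rng)
        n = m.size
        assert abs(m.mean() - 1.0) < 3 * 0.03 / np.sqrt(n)
        assert abs(m.std(ddof=1) - 0.03) < 3 * 0.03 / np.sqrt(2 * n)


class TestDriftSchedule:
    def test_published_acceleration_schedule(self):
        sched = DriftSchedule.amh_acceleration()
        assert drift_at_age(sched, 37.0) == 0.024
        assert drift_at_age(sched, 39.0) == 0.033
        assert drift_at_age(sched, 38.0) == 0.033  # left-closed at the breakpoint

    def test_constant_schedule(self):
        sched = DriftSchedule.constant(0.051)
        ages = np.array([0.0, 20.0, 80.0])
        np.testing.assert_array_equal(drift_at_age(sched, ages), 0.051)

    def test_shape_validation(self):
        with pytest.raises(Exception):
            DriftSchedule(breakpoints=(38.0,), values=(0.024,))


class TestSimulateSubject:
    def test_supply_below_threshold_is_immediate(self):
        traj = simulate_subject(SubjectSpec(starting_supply=500), HUMAN, rng=0)
        assert traj.anm == 0.0 and not traj.censored

    @pytest.mark.parametrize("method", ["binomial_thinning", "per_follicle"])
    def test_median_woman_reaches_menopause_at_51(self, method):
        spec = SubjectSpec(starting_supply=MEDIAN_SUPPLY_INT)
        traj = simulate_subject(spec, HUMAN, method=method, rng=1)
        assert round(traj.anm) == 51
        assert traj.reserve[0] == MEDIAN_SUPPLY_INT
        assert np.all(np.diff(traj.reserve) <= 0)

    def test_deterministic_drift_limit(self):
        """As D -> 0 every exit concentrates at t = x0/V ~ 19.6 yr."""
        p = ContinuousParams(D=1e-6, V=0.051)
        spec = SubjectSpec(starting_supply=100_000, menopause_threshold=1)
        traj = simulate_subject(spec, p, rng=2)
        f = traj.reserve
        i19, i21 = 19 * 12, 21 * 12
        assert f[i19] > 0.99 * f[0]
        assert f[i21] < 0.01 * f[0]

    def test_expected_trajectory_matches_closed_form(self):
        """Mean monthly reserve tracks N * S(t) within binomial error."""
        n_rep, N = 40, 50_000
        spec = SubjectSpec(starting_supply=N)
        acc = np.zeros(120 * 12 + 1)
        for r in range(n_rep):
            acc += simulate_subject(spec, HUMAN, rng=100 + r).reserve
        mean_f = acc / n_rep
        ages = np.arange(120 * 12 + 1) / 12
        expect = expected_reserve(ages, N, HUMAN)
        se = np.sqrt(np.maximum(expect * (1 - expect / N), 1.0) / n_rep)
        assert np.all(np.abs(mean_f - expect) < 5 * se + 1.0)

    def test_monotone_in_supply_with_common_randomness(self):
        for seed in range(5):
            a = simulate_subject(
                SubjectSpec(starting_supply=200_000), HUMAN,
                method="per_follicle", rng=seed,
            )
            b = simulate_subject(
                SubjectSpec(starting_supply=400_000), HUMAN,
                method="per_follicle", rng=seed,
            )
            assert b.anm >= a.anm

    def test_monotone_in_drift_with_common_randomness(self):
        for seed in range(5):
            slow = simulate_subject(
                SubjectSpec(starting_supply=MEDIAN_SUPPLY_INT, drift_multiplier=0.95),
                HUMAN, method="per_follicle", rng=seed,
            )
            fast = simulate_subject(
                SubjectSpec(starting_supply=MEDIAN_SUPPLY_INT, drift_multiplier=1.05),
                HUMAN, method="per_follicle", rng=seed,
            )
            assert fast.anm <= slow.anm


class TestAcuteLoss:
    def test_full_survival_leaves_reserve_unchanged(self):
        base = np.array([1000, 900, 800, 700], dtype=np.int64)
        ages = np.array([0.0, 1.0, 2.0, 3.0])
        out = apply_acute_loss(base, ages, InterventionEvent(2.0, 1.0))
        np.testing.assert_array_equal(out, base)

    def test_total_loss_sets_anm_at_event(self):
        spec = SubjectSpec(
            starting_supply=MEDIAN_SUPPLY_INT,
            interventions=(InterventionEvent(12.0, 0.0),),
        )
        traj = simulate_subject(spec, HUMAN, rng=0)
        assert traj.anm == 12.0

    @pytest.mark.parametrize("method", ["binomial_thinning", "per_follicle"])
    def test_half_loss_accelerates_menopause(self, method):
        anm_loss, anm_base = [], []
        for seed in range(30):
            spec_l = SubjectSpec(
                starting_supply=MEDIAN_SUPPLY_INT,
                interventions=(InterventionEvent(12.0, 0.5),),
            )
            spec_b = SubjectSpec(starting_supply=MEDIAN_SUPPLY_INT)
            anm_loss.append(simulate_subject(spec_l, HUMAN, method, seed).anm)
            anm_base.append(simulate_subject(spec_b, HUMAN, method, seed).anm)
        assert np.mean(anm_loss) < np.mean(anm_base)

    def test_fraction_validated(self):
        with pytest.raises(Exception):
            InterventionEvent(12.0, 1.5)


class TestPopulation:
    def test_degenerate_population_is_median_woman(self):
        res = simulate_population(
            1, dist=SupplyDistribution(sigma=0.0), c=0.0, seed=9,
            keep_quantile_trajectories=False,
        )
        assert round(float(res.anm_samples[0])) == 51

    def test_seed_reproducibility(self):
        a = simulate_population(300, seed=4, keep_quantile_trajectories=False)
        b = simulate_population(300, seed=4, keep_quantile_trajectories=False)
        np.testing.assert_array_equal(a.anm_samples, b.anm_samples)

    def test_anm_on_monthly_grid(self):
        res = simulate_population(500, seed=2, keep_quantile_trajectories=False)
        anm = res.anm_samples[np.isfinite(res.anm_samples)]
        np.testing.assert_allclose(np.round(anm * 12), anm * 12, atol=1e-9)

    def test_summary_recomputable_from_samples(self):
        res = simulate_population(2000, seed=5, keep_quantile_trajectories=False)
        s = res.summary()
        anm = res.anm_samples[np.isfinite(res.anm_samples)]
        assert s["median_anm"] == pytest.approx(np.median(anm))
        assert s["quantiles"]["q25"] == pytest.approx(np.quantile(anm, 0.25))
        assert s["iqr"] == pytest.approx(
            np.quantile(anm, 0.75) - np.quantile(anm, 0.25)
        )

    def test_quantile_trajectories_are_scaled_survival(self):
        res = simulate_population(50, seed=1)
        qt = res.quantile_trajectories
        dist = SupplyDistribution()
        s = survival(qt["ages"], HUMAN)
        np.testing.assert_allclose(
            qt["expected"]["q50"], dist.median() * s, rtol=1e-10
        )
        assert np.all(qt["expected"]["q01"] <= qt["expected"]["q99"])

    def test_heterogeneous_drift_curves_can_cross(self):
        """A high-supply fast-drift woman eventually holds fewer follicles
        than a low-supply slow-drift woman; with identical drift the curves
        never cross."""
        dist = SupplyDistribution()
        n_hi, n_lo = dist.quantile(0.75), dist.quantile(0.25)
        ages = np.linspace(0.0, 80.0, 500)
        fast = n_hi * survival(ages, HUMAN.with_drift(0.051 * 1.09))
        slow = n_lo * survival(ages, HUMAN.with_drift(0.051 * 0.91))
        diff = fast - slow
        assert diff[0] > 0 and diff[-1] < 0  # curves cross
        same_hi = n_hi * survival(ages, HUMAN)
        same_lo = n_lo * survival(ages, HUMAN)
        assert np.all(same_hi > same_lo)  # homogeneous drift: parallel decay


class TestScheduleSurvival:
    def test_constant_schedule_matches_closed_form(self):
        s_occ = schedule_survival(
            HUMAN, DriftSchedule.constant(0.051), max_age=60.0
        )[::4]
        ages = np.arange(60 * 12 + 1) / 12
        s_cf = survival(ages, HUMAN)
        assert np.max(np.abs(s_occ - s_cf)) < 0.01

    def test_acceleration_reduces_late_survival(self):
        sched = DriftSchedule.amh_acceleration()
        s_var = schedule_survival(HUMAN, sched, max_age=80.0)
        s_const = schedule_survival(
            HUMAN, DriftSchedule.constant(0.024), max_age=80.0
        )
        k38 = int(38 * 48)
        np.testing.assert_allclose(s_var[: k38 + 1], s_const[: k38 + 1], rtol=1e-10)
        assert s_var[-1] < s_const[-1]

    def test_population_under_schedule_runs_and_is_monotone_in_drift(self):
        res = simulate_population(
            200,
            base_schedule=DriftSchedule.amh_acceleration(),
            c=0.03,
            seed=6,
            keep_quantile_trajectories=False,
        )
        assert np.isfinite(res.anm_samples).sum() > 0
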