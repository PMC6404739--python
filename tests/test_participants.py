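"""Cohort-generator tests: baselines, adherence rules, trajectories, items."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efmt.participants import (
    HAMD_ITEM_MAX,
    HAMD_MAX_TOTAL,
    CohortConfig,
    TrajectoryModel,
    compound_symmetry_cov,
    decompose_hamd_items,
    default_trajectory_model,
    default_weekly_means,
    sample_participant,
    simulate_adherence,
    simulate_trajectory,
    wais_composite,
)


class TestBaselines:
    def test_monte_carlo_mean_matches_configured_mean(self):
        rng = np.random.default_rng(42)
        vals = [sample_participant("EFMT", rng).baseline_hamd for _ in range(10_000)]
        assert abs(np.mean(vals) - 19.25) < 0.2

    def test_zero_sd_gives_rounded_mean(self, rng):
        cfg = CohortConfig(hamd_sd={"EFMT": 0.0, "CT": 0.0})
        for _ in range(5):
            assert sample_participant("EFMT", rng, cfg).baseline_hamd == 19
            assert sample_participant("CT", rng, cfg).baseline_hamd == 19

    def test_all_draws_respect_eligibility_window(self):
        rng = np.random.default_rng(1)
        for _ in range(2000):
            p = sample_participant("CT", rng)
            assert 16 <= p.baseline_hamd <= 27

    def test_wais_composite_is_arithmetic_mean(self):
        assert wais_composite(10, 10, 10) == 10.0
        assert wais_composite(12, 10, 11) == 11.0
        assert round(wais_composite(11, 11, 12), 2) == 11.33


def adherence_oracle(sessions, per_week=3):
    """Brute-force re-application of the two discontinuation rules."""
    missed = 0
    for w, s in enumerate(sessions, start=1):
        missed += per_week - s
        if s < 2 or missed > 3:
            return True, w
    return False, None


class TestAdherence:
    def test_full_attendance_completes_18_sessions(self, rng):
        rec = simulate_adherence(rng, attendance_prob=1.0)
        assert rec.total_sessions == 18 and not rec.discontinued

    def test_week_with_one_session_discontinues(self):
        class Scripted:
            def __init__(self, vals):
                self.vals = list(vals)

            def binomial(self, n, p):
                return self.vals.pop(0)

        rec = simulate_adherence(Scripted([3, 3, 1, 3, 3, 3]), attendance_prob=0.9)
        assert rec.discontinued and rec.discontinuation_week == 3
        assert rec.sessions_by_week == (3, 3, 1, 0, 0, 0)

    def test_flag_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(10_000):
            rec = simulate_adherence(rng, attendance_prob=0.8)
            disc, week = adherence_oracle(rec.sessions_by_week)
            assert disc == rec.discontinued
            assert week == rec.discontinuation_week


class TestTrajectories:
    def _profile(self, rng, group="EFMT", sd=0.0):
        cfg = CohortConfig(hamd_sd={"EFMT": sd, "CT": sd})
        return sample_participant(group, rng, cfg)

    def test_zero_noise_reproduces_configured_means_exactly(self, rng):
        model = default_trajectory_model(residual_sd=0.0, dose_effect=0.0)
        prof = self._profile(rng)
        recs = simulate_trajectory(prof, model, [3] * 6, rng)
        expect = np.round(model.weekly_means["EFMT"]).astype(int)
        assert [r.hamd_total for r in recs] == list(expect)

    def test_monte_carlo_week6_mean_matches_configuration(self):
        model = default_trajectory_model(dose_effect=0.0)
        rng = np.random.default_rng(99)
        vals = []
        for _ in range(1000):
            prof = self._profile(rng, sd=2.55)
            vals.append(simulate_trajectory(prof, model, [3] * 6, rng)[6].hamd_total)
        assert abs(np.mean(vals) - model.weekly_means["EFMT"][6]) < 0.5

    def test_dose_effect_yields_negative_sessions_outcome_correlation(self):
        model = default_trajectory_model(dose_effect=-0.7)
        rng = np.random.default_rng(5)
        sessions, pct = [], []
        for _ in range(1000):
            prof = self._profile(rng, sd=2.55)
            adher = simulate_adherence(rng, 0.88)
            recs = simulate_trajectory(prof, model, adher.sessions_by_week, rng,
                                       discontinuation_week=adher.discontinuation_week)
            if recs[-1].week == 0:
                continue   # not m-ITT
            # last observation carried forward to the outcome, as analyzed
            sessions.append(adher.total_sessions)
            pct.append(100 * (recs[-1].hamd_total - recs[0].hamd_total)
                       / recs[0].hamd_total)
        r = np.corrcoef(sessions, pct)[0, 1]
        assert r < -0.2

    def test_discontinued_participant_stops_before_that_week(self, rng):
        model = default_trajectory_model()
        prof = self._profile(rng, sd=2.55)
        recs = simulate_trajectory(prof, model, (3, 3, 0, 0, 0, 0), rng,
                                   discontinuation_week=3)
        assert [r.week for r in recs] == [0, 1, 2]
        assert recs[-1].status == "discontinued"

    def test_efmt_mean_curve_declines_monotonically(self):
        mu = default_weekly_means()
        assert (np.diff(mu["EFMT"]) < 0).all()
        assert (np.diff(mu["CT"]) < 0).all()

    def test_non_psd_covariance_rejected(self):
        bad = compound_symmetry_cov()
        bad[0, 1] = bad[1, 0] = -100.0
        with pytest.raises(ValueError, match="positive semi-definite"):
            TrajectoryModel(weekly_means=default_weekly_means(), residual_cov=bad)


class TestItemDecomposition:
    def test_zero_total_gives_all_zero_items(self, rng):
        assert decompose_hamd_items(0, np.ones(17), rng).sum() == 0

    @settings(max_examples=150, derandomize=True)
    @given(total=st.integers(0, 52), seed=st.integers(0, 10_000))
    def test_conservation_and_ranges(self, total, seed):
        rng = np.random.default_rng(seed)
        profile = rng.dirichlet(np.ones(17))
        items = decompose_hamd_items(total, profile, rng)
        assert items.sum() == total
        assert (items >= 0).all() and (items <= np.array(HAMD_ITEM_MAX)).all()

    def test_maximum_total_saturates_every_item(self, rng):
        items = decompose_hamd_items(HAMD_MAX_TOTAL, np.ones(17), rng)
        assert tuple(items) == HAMD_ITEM_MAX

    def test_uniform_profile_mean_item_score(self, rng):
        vals = np.array([decompose_hamd_items(17, np.ones(17), rng) for _ in range(200)])
        assert vals.mean() == pytest.approx(1.0)   # conservation: 17 points / 17 items

    def test_total_above_instrument_maximum_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            decompose_hamd_items(53, np.ones(17), rng)
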