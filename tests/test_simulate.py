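"""Synthetic ambulatory data: movement, episodes, beat synthesis, self-reports."""

import numpy as np
import pandas as pd
import pytest

from addhrvr import (
    EffectParams,
    MetModel,
    MovementCalibration,
    PersonParams,
    TriggerConfig,
    generate_ibis,
    generate_met_series,
    generate_selfreports,
    place_episodes,
    segment_minutes,
    simulate_person_day,
    simulate_study,
)
from addhrvr.simulate import _minute_targets

DAY = (9 * 3600, 21 * 3600)


class TestMet:
    def test_sedentary_scenario_bounds(self, rng):
        model = MetModel(levels=(1.3,), within_sd=(0.1,), dwell_minutes=(30.0,),
                         switch_to=((1.0,),))
        vals = generate_met_series(DAY, rng, model)
        assert vals.min() >= 0.9 and vals.max() <= 1.8

    def test_deterministic_under_seed(self):
        a = generate_met_series(DAY, np.random.default_rng(3))
        b = generate_met_series(DAY, np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_long_run_mean_matches_mixture(self):
        model = MetModel()
        vals = np.concatenate(
            [generate_met_series(DAY, np.random.default_rng(s)) for s in range(30)]
        )
        assert vals.mean() == pytest.approx(model.mean(), rel=0.10)


class TestEpisodes:
    def test_rate_zero_empty(self, rng):
        p = PersonParams(episode_rate=0.0)
        assert place_episodes(p, DAY, rng) == []

    def test_disjoint_and_inside(self, rng):
        p = PersonParams(episode_rate=3.0)
        for _ in range(50):
            eps = place_episodes(p, DAY, rng)
            for (s, e), nxt in zip(eps, eps[1:] + [None]):
                assert 0 <= s < e <= 720
                if nxt is not None:
                    assert e + p.episode_gap <= nxt[0]

    def test_poisson_mean(self):
        p = PersonParams(episode_rate=2.0)
        counts = [
            len(place_episodes(p, DAY, np.random.default_rng(s))) for s in range(400)
        ]
        assert np.mean(counts) == pytest.approx(2.0, abs=0.2)

    def test_mean_length(self):
        p = PersonParams(episode_rate=2.0)
        lengths = [
            e - s
            for seed in range(300)
            for s, e in place_episodes(p, DAY, np.random.default_rng(seed))
        ]
        assert np.mean(lengths) == pytest.approx(p.episode_len, rel=0.05)
        assert min(lengths) >= p.episode_min_len


class TestIbiSynthesis:
    def test_realized_rmssd_matches_target(self, rng):
        p = PersonParams()
        met = generate_met_series(DAY, rng)
        targets = 30.0 + 40.0 * np.random.default_rng(1).random(met.size)
        series = generate_ibis(p, met, [], EffectParams(), [], rng, targets=targets)
        recs = segment_minutes(series, compute_bands=False)
        realized = np.array([r.rmssd for r in recs])
        valid = np.array([r.valid for r in recs])
        rel = np.abs(realized[valid] - targets[valid]) / targets[valid]
        assert valid.mean() > 0.95
        assert rel.max() < 0.01

    def test_full_chain_recovers_calibration_exactly(self, rng):
        # zero noise, no episodes: beat synthesis -> minute features -> OLS
        p = PersonParams(noise_sd=0.0, episode_rate=0.0)
        met = generate_met_series(DAY, rng)
        series = generate_ibis(p, met, [], EffectParams(), [], rng)
        recs = segment_minutes(series, met=met, compute_bands=False)
        res = MovementCalibration.from_minutes(recs).fit()
        assert res.intercept == pytest.approx(p.intercept, rel=1e-3)
        assert res.slope == pytest.approx(p.slope, rel=1e-3)

    def test_target_floor(self, rng):
        p = PersonParams()
        met = np.full(5, 1.3)
        series = generate_ibis(p, met, [], EffectParams(), [], rng,
                               day_window=(DAY[0], DAY[0] + 300),
                               targets=[-10.0, 0.0, 5.0, 5.0, 5.0])
        recs = segment_minutes(series, day_window=(DAY[0], DAY[0] + 300),
                               compute_bands=False)
        # negative/zero targets are clipped to the floor, not dropped
        assert all(r.n_beats > 0 for r in recs)


class TestClosedLoop:
    def _calibrated_person(self, p, seed=0):
        rng = np.random.default_rng(seed)
        cal_day = simulate_person_day(p, EffectParams(), rng, calibration=None)
        return MovementCalibration.from_minutes(cal_day.minutes).fit(), rng

    def test_trigger_fires_inside_deep_episodes(self):
        p = PersonParams(episode_depth=1.0, episode_rate=1.0)
        hits = trials = 0
        for seed in range(50):
            cal, rng = self._calibrated_person(p, seed)
            res = simulate_person_day(p, EffectParams(), rng, calibration=cal)
            eps = res.minutes["in_episode"].to_numpy()
            if not eps.any():
                continue
            trials += 1
            fired_minutes = [
                int((e.time - DAY[0]) / 60) - 1 for e in res.triggers
            ]
            hits += any(eps[min(m, 719)] for m in fired_minutes)
        assert trials > 20
        assert hits / trials >= 0.9

    def test_no_episodes_trigger_rate_matches_binomial_oracle(self):
        # with a loose flag criterion, no movement structure, no episodes and
        # no interventions, per-minute flags are iid Bernoulli, so the
        # false-trigger rate must match an independent Bernoulli-scan replay
        # at each person's empirical flag rate
        sedentary = MetModel(levels=(1.3,), within_sd=(0.1,), dwell_minutes=(30.0,),
                             switch_to=((1.0,),))
        p = PersonParams(episode_rate=0.0, met_model=sedentary)
        null = EffectParams(during_boost=0, post_boost=0, time_main_during=0,
                            time_main_post=0, smoking_effect=0)
        cfg = TriggerConfig(k=0.1, random_rate=0)
        n_days = 40
        n_trig = 0
        oracle_rng = np.random.default_rng(999)
        oracle_trig = []
        for seed in range(n_days):
            cal, rng = self._calibrated_person(p, seed)
            res = simulate_person_day(p, null, rng, calibration=cal, config=cfg)
            n_trig += len(res.triggers)
            p_flag = res.minutes["flag"].mean()
            for _ in range(4):  # oracle replicates at this person's flag rate
                flags = oracle_rng.random(720) < p_flag
                last = float("-inf")
                cnt = 0
                for i in range(720):
                    lo = max(0, i - 27)
                    if flags[lo: i + 1].sum() >= 13 and (i + 1) * 60 - last >= 3600:
                        cnt += 1
                        last = (i + 1) * 60
                oracle_trig.append(cnt)
        assert n_trig / n_days == pytest.approx(np.mean(oracle_trig), abs=0.75)

    def test_intervention_boost_visible_in_minutes(self):
        p = PersonParams(episode_rate=0.0, noise_sd=0.0)
        eff = EffectParams(time_main_post=0.3, post_boost=0.0, time_main_during=0.0)
        cal, rng = self._calibrated_person(PersonParams(episode_rate=0.0), seed=3)
        cfg = TriggerConfig(random_rate=1, random_min_gap=0.0)
        res = simulate_person_day(p, eff, rng, calibration=cal, config=cfg)
        assert len(res.prompts) == 1
        t = res.prompts["time_seconds"].iloc[0]
        i = int((t - DAY[0]) // 60)
        met = res.minutes["met"].to_numpy()
        line = np.log(np.maximum(p.intercept + p.slope * met, 5.0))
        resid = np.log(res.minutes["rmssd"].to_numpy()) - line
        assert np.allclose(resid[i + 2: i + 11], 0.3, atol=1e-6)
        assert np.allclose(resid[i - 10: i], 0.0, atol=1e-6)


class TestSelfReports:
    def _prompts(self, n=400, kind="random"):
        return pd.DataFrame(
            {
                "person_id": "p0",
                "day": 1,
                "time_seconds": np.linspace(DAY[0] + 600, DAY[1] - 600, n),
                "kind": kind,
                "intervention": "none",
                "in_episode": False,
                "smoking": False,
                "window_flag_count": np.nan,
            }
        )

    def test_zero_noise_shift_is_exact(self, rng):
        eff = EffectParams(time_effect_stress=-0.12, time_effect_rumination=-0.11)
        out = generate_selfreports(
            self._prompts(20), eff, rng, state_sd=0.0, item_sd=0.0, change_sd=0.0,
            disposition_p=(1.0, 0.0, 0.0, 0.0),
        )
        from addhrvr import score_stress

        pre = out[[f"stress_pre_{k}" for k in range(1, 5)]].to_numpy()
        post = out[[f"stress_post_{k}" for k in range(1, 5)]].to_numpy()
        d = [score_stress(b) - score_stress(a) for a, b in zip(pre, post)]
        assert np.allclose(d, -0.12, atol=1e-12)
        assert np.allclose(out["rumination_post"] - out["rumination_pre"], -0.11)

    def test_ceiling_is_clipped(self, rng):
        eff = EffectParams(time_effect_stress=1.0)
        out = generate_selfreports(
            self._prompts(50), eff, rng, stress_baseline=5.0,
            state_sd=0.0, item_sd=0.0, change_sd=0.0,
            disposition_p=(1.0, 0.0, 0.0, 0.0),
        )
        for k in range(1, 5):
            assert out[f"stress_post_{k}"].between(1, 5).all()

    def test_reverse_items_stored_as_collected(self, rng):
        out = generate_selfreports(
            self._prompts(5), EffectParams(), rng, stress_baseline=2.0,
            state_sd=0.0, item_sd=0.0, change_sd=0.0,
            disposition_p=(1.0, 0.0, 0.0, 0.0),
        )
        # latent 2.0: reversed items stored as 6-2=4, the direct item as 2
        assert np.allclose(out["stress_pre_1"], 4.0)
        assert np.allclose(out["stress_pre_4"], 2.0)

    def test_disposition_mix_and_missingness(self, rng):
        out = generate_selfreports(self._prompts(2000), EffectParams(), rng)
        frac = out["disposition"].value_counts(normalize=True)
        assert frac["answered"] == pytest.approx(0.69, abs=3 * np.sqrt(0.69 * 0.31 / 2000))
        no_rating = out["disposition"].isin(["dismissed", "ignored"])
        assert out.loc[no_rating, "stress_pre_1"].isna().all()
        inc = out["disposition"] == "incomplete"
        assert out.loc[inc, "stress_post_1"].isna().all()
        assert out.loc[inc, "stress_pre_1"].notna().all()


class TestStudy:
    def test_master_seed_determinism(self):
        a = simulate_study(3, 1, seed=77)
        b = simulate_study(3, 1, seed=77)
        pd.testing.assert_frame_equal(a.minutes, b.minutes)
        pd.testing.assert_frame_equal(a.prompts, b.prompts)

    def test_person_streams_independent_of_cohort_size(self):
        a = simulate_study(2, 1, seed=5)
        b = simulate_study(4, 1, seed=5)
        pa = a.minutes[a.minutes["person_id"] == "p000"].reset_index(drop=True)
        pb = b.minutes[b.minutes["person_id"] == "p000"].reset_index(drop=True)
        pd.testing.assert_frame_equal(pa, pb)

    def test_calibration_day_present_and_deployed(self, small_study):
        st = small_study
        assert set(st.minutes["day"].unique()) == {0, 1, 2}
        assert len(st.calibrations) == 12
        assert st.prompts["kind"].isin(["addhrvr", "random"]).all()

    def test_slope_recovery_across_persons(self):
        # linear-regime persons (line stays above the RMSSD floor at all MET)
        base = PersonParams(intercept=72.0, episode_rate=0.0,
                            met_model=MetModel(levels=(1.3, 3.0, 4.5),
                                               within_sd=(0.1, 0.3, 0.3)))
        st = simulate_study(30, 0, seed=9, base_person=base, heterogeneous=False)
        est = np.array([c.slope for c in st.calibrations])
        bias = est - base.slope
        assert np.abs(bias.mean()) <= 2 * bias.std() / np.sqrt(30) + 0.02
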