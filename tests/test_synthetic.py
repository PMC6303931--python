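"""Generator tests: determinism, independence nulls, closed-form channels."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from chronocope.errors import ConfigurationError
from chronocope.rhythm import fit_sine24
from chronocope.synthetic import (
    SAMPLING_TIMES_HCT,
    CohortConfig,
    MirrorParams,
    RhythmGenParams,
    generate_cohort,
    make_latency_table,
    simulate_activity_trace,
    simulate_channel_timeseries,
    simulate_emergence_latency,
    simulate_mirror_test,
)
from conftest import make_individual


class TestGenerateCohort:
    def test_seeded_determinism(self, default_config):
        a = generate_cohort(default_config).roster()
        b = generate_cohort(default_config).roster()
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_counts_and_uniqueness(self):
        cohort = generate_cohort(CohortConfig(n_groups=9, group_size=10, seed=1))
        assert len(cohort) == 90
        roster = cohort.roster()
        assert roster["individual_id"].is_unique
        assert roster["boldness"].between(0, 1).all()

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_groups=0)
        with pytest.raises(ConfigurationError):
            CohortConfig(group_size=1)

    def test_body_weight_independent_of_boldness(self):
        # Monte-Carlo under the generative null: 200 seeded cohorts of 144 fish
        rhos = []
        for seed in range(200):
            roster = generate_cohort(
                CohortConfig(n_groups=18, group_size=8, seed=seed)
            ).roster()
            rhos.append(
                spearmanr(roster["boldness"], roster["body_weight_mg"]).statistic
            )
        assert abs(np.mean(rhos)) < 0.1
        assert np.mean(np.abs(rhos)) < 0.1


class TestEmergenceLatency:
    def test_no_session_noise_means_identical_sessions(self):
        cfg = CohortConfig(seed=3, latency_residual_sd=0.0)
        ind = make_individual(0.4)
        assert simulate_emergence_latency(
            ind, cfg, "day1"
        ) == simulate_emergence_latency(ind, cfg, "day2")

    def test_null_model_latency_unrelated_to_boldness(self):
        cfg = CohortConfig(
            n_groups=100,
            group_size=10,
            seed=11,
            latency_boldness_slope=0.0,
            latency_individual_sd=0.0,
        )
        cohort = generate_cohort(cfg)
        table = make_latency_table(cohort)
        roster = cohort.roster()
        merged = table.merge(roster, on="individual_id")
        rho = spearmanr(merged["boldness"], merged["latency_s"]).statistic
        assert abs(rho) < 0.08

    def test_test_retest_consistency_matches_bruteforce_oracle(self):
        # oracle: the same latent model simulated directly at large n
        orng = np.random.default_rng(99)
        n = 10_000
        b = orng.uniform(0, 1, n)
        u = orng.normal(0, 0.3, n)
        x1 = 3.0 * (1 - b) + u + orng.normal(0, 0.15, n)
        x2 = 3.0 * (1 - b) + u + orng.normal(0, 0.15, n)
        oracle_rho = spearmanr(x1, x2).statistic
        rhos = []
        for seed in range(10):
            cohort = generate_cohort(CohortConfig(n_groups=18, group_size=8, seed=seed))
            s1 = make_latency_table(cohort, session="day1")
            s2 = make_latency_table(cohort, session="day2")
            rhos.append(
                spearmanr(np.log(s1["latency_s"]), np.log(s2["latency_s"])).statistic
            )
        assert np.mean(rhos) == pytest.approx(oracle_rho, abs=0.03)


class TestMirror:
    def test_full_freeze_cap_makes_non_responder(self):
        cfg = CohortConfig(seed=1, mirror=MirrorParams(frz_coef=2.0, frz_sd=0.0))
        rec = simulate_mirror_test(make_individual(0.0), cfg)
        assert rec.frz_s == rec.duration
        assert rec.agr_count == 0

    def test_zero_rate_means_zero_aggression(self):
        cfg = CohortConfig(seed=1, mirror=MirrorParams(agr_rate_max=0.0))
        rec = simulate_mirror_test(make_individual(0.9), cfg)
        assert rec.agr_count == 0

    def test_rank_aggression_correlation_matches_simulation_oracle(self):
        # oracle: direct resimulation of 100 ranked groups of 10 (10^3 fish),
        # including the noisy group-emergence ranking step
        orng = np.random.default_rng(5)
        ranks_o, freqs_o = [], []
        for _ in range(100):
            b = orng.uniform(0, 1, 10)
            latent = 3.0 * (1 - b) + orng.normal(0, 0.3, 10) + orng.normal(0, 0.15, 10)
            rank = np.empty(10)
            rank[np.argsort(latent)] = np.arange(1, 11)
            frz = np.clip(1.05 * (1 - b) + orng.normal(0, 0.15, 10), 0, 1) * 600
            responder = frz < 600
            lfa = np.clip(60 * (1 - b) + orng.normal(0, 15, 10), 0, 0.8 * (600 - frz))
            active = 600 - frz - lfa
            agr = orng.poisson(np.clip(0.25 * b * active, 0, None))
            freq = agr / np.where(active > 0, active, np.nan)
            ranks_o.extend(rank[responder])
            freqs_o.extend(freq[responder])
        oracle = spearmanr(ranks_o, freqs_o).statistic
        from chronocope.pipeline import RunConfig, run_full_study

        rhos = []
        for seed in (1, 2, 3):
            res = run_full_study(
                RunConfig(cohort=CohortConfig(seed=seed), channels=())
            )
            row = res.correlations.query("channel == 'mirror'").iloc[0]
            rhos.append(row["rho"])
        assert np.mean(rhos) < -0.4
        assert np.mean(rhos) == pytest.approx(oracle, abs=0.15)


class TestChannelTimeseries:
    def test_noise_free_flat_channel_is_mesor(self):
        cfg = CohortConfig(seed=1).noise_free()
        params = {"flat": RhythmGenParams(3.0, 3.0, 0.0, 0.0, acrophase=0.0)}
        cfg = dataclasses.replace(cfg, channel_params=params, noise_cv={"flat": 0.0})
        ts = simulate_channel_timeseries(
            make_individual(0.5), "flat", SAMPLING_TIMES_HCT, cfg
        )
        np.testing.assert_allclose(ts.values, 3.0)

    def test_cosine_arithmetic_at_sampling_times(self):
        cfg = CohortConfig(seed=1).noise_free()
        params = {"gene": RhythmGenParams(10.0, 10.0, 4.0, 4.0, acrophase=7.0)}
        cfg = dataclasses.replace(cfg, channel_params=params, noise_cv={"gene": 0.0})
        ts = simulate_channel_timeseries(
            make_individual(1.0), "gene", SAMPLING_TIMES_HCT, cfg
        )
        np.testing.assert_allclose(
            ts.values, [10.0, 14.0, 10.0, 8.0, 6.0, 8.0], atol=1e-12
        )

    def test_unknown_channel_rejected(self, default_config):
        with pytest.raises(ConfigurationError):
            simulate_channel_timeseries(
                make_individual(0.5), "nope", SAMPLING_TIMES_HCT, default_config
            )

    def test_ll_damping_quarters_amplitude_after_two_halflives(self):
        cfg = dataclasses.replace(
            CohortConfig(seed=1).noise_free(), ll_damping_halflife=24.0
        )
        ind = make_individual(1.0)
        t = np.arange(0, 144, 0.5)
        ld = simulate_channel_timeseries(ind, "activity", t[t < 24], cfg, regime="LD")
        day3 = (t >= 48) & (t < 72)
        ll = simulate_channel_timeseries(
            ind, "activity", t[day3], cfg, regime="LL", ll_start=0.0
        )
        amp_ld = fit_sine24(ld).amplitude
        amp_ll = fit_sine24(ll).amplitude
        # direct evaluation of the damped cosinor, fitted the same way
        params = cfg.channel("activity")
        direct = params.mesor(1.0) + params.amplitude(1.0) * np.cos(
            2 * np.pi * (t[day3] - params.acrophase) / 24
        ) * 2.0 ** (-t[day3] / 24.0)
        amp_direct = fit_sine24(ld.with_values(direct).__class__(t[day3], direct)).amplitude
        assert amp_ll == pytest.approx(amp_direct, abs=1e-9)
        assert amp_ll / amp_ld == pytest.approx(0.25, rel=0.25)

    def test_generative_monotonicity_noise_free(self):
        cfg = CohortConfig(seed=1).noise_free()
        boldness = np.linspace(0.05, 0.95, 10)
        for channel in ("bmal1a", "cipca", "cortisol", "melatonin", "activity"):
            fits = [
                fit_sine24(
                    simulate_channel_timeseries(
                        make_individual(b, f"G01F{k:02d}"),
                        channel,
                        SAMPLING_TIMES_HCT,
                        cfg,
                    )
                )
                for k, b in enumerate(boldness, start=1)
            ]
            amplitudes = [f.amplitude for f in fits]
            assert np.all(np.diff(amplitudes) > 0), channel
            mesors = np.array([f.mesor for f in fits])
            if channel in ("cortisol", "melatonin"):
                assert np.all(np.diff(mesors) < 0), channel
            elif channel in ("bmal1a", "cipca"):
                assert np.all(np.diff(mesors) > 0), channel

    def test_activity_trace_determinism_and_layout(self, default_config):
        ind = make_individual(0.6)
        a = simulate_activity_trace(ind, default_config)
        b = simulate_activity_trace(ind, default_config)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.times[0] == 7.0
        assert a.times[-1] == pytest.approx(150.5)
        assert len(a) == 288
        assert (a.values >= 0).all()


class TestVmaxNull:
    def test_daily_maximum_velocity_unrelated_to_rank(self):
        """The shared locomotor ceiling makes Vmax personality-independent:
        over 100 seeded cohorts the rank-Vmax correlation is centred on zero
        with a false-positive rate compatible with alpha = 0.05."""
        from chronocope.pipeline import _rank_cohort, _retained_ids
        from chronocope.rhythm import vmax as vmax_of
        from chronocope.synthetic import LL_START_HCT

        rhos, pvals = [], []
        for seed in range(100):
            cfg = CohortConfig(seed=seed)
            cohort = generate_cohort(cfg)
            emergence = _rank_cohort(cohort)
            retained = set(_retained_ids(cohort, emergence, 2))
            rank_of = dict(zip(emergence["individual_id"], emergence["rank"]))
            ranks, values = [], []
            for ind in cohort.individuals:
                if ind.id not in retained:
                    continue
                trace = simulate_activity_trace(ind, cfg)
                ld = trace.window(trace.times[0], LL_START_HCT)
                ranks.append(rank_of[ind.id])
                values.append(vmax_of(ld))
            res = spearmanr(ranks, values)
            rhos.append(res.statistic)
            pvals.append(res.pvalue)
        assert abs(np.mean(rhos)) < 0.05
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.11
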