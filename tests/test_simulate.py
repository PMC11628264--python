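"""Synthetic experiments: single-trial generators, populations, designs."""

import math

import numpy as np
import pandas as pd
import pytest

from tvatoj.inference import aggregate_cells
from tvatoj.io import validate_trials
from tvatoj.model import AttentionalParams, EncodingRates, psychometric_curve
from tvatoj.simulate import (
    EXP3_SOAS_MS,
    AdaptationCurveParams,
    PopulationConfig,
    adaptation_value,
    build_design,
    sample_population,
    simulate_bernoulli_trial,
    simulate_dataset,
    simulate_race_trial,
)


class TestRaceTrial:
    def test_symmetric_race_is_fair(self, rng):
        r = EncodingRates(20.0, 20.0)
        wins = sum(simulate_race_trial(r, 0.0, rng) for _ in range(20000))
        assert abs(wins / 20000 - 0.5) < 3 * math.sqrt(0.25 / 20000)

    def test_probe_long_lead_always_first(self, rng):
        r = EncodingRates(30.0, 30.0)
        wins = sum(simulate_race_trial(r, -10 / 30.0, rng) for _ in range(2000))
        assert wins / 2000 > 0.99

    def test_frequency_matches_closed_form(self, rng):
        # (C=60, w=0.5, soa=+50 ms): closed form 0.5 exp(-1.5)
        r = EncodingRates(30.0, 30.0)
        n = 200_000
        t_probe = 0.05 + rng.exponential(1 / 30.0, n)
        t_ref = rng.exponential(1 / 30.0, n)
        freq = np.mean(t_probe < t_ref)
        p = 0.5 * math.exp(-1.5)
        assert abs(freq - p) < 3 * math.sqrt(p * (1 - p) / n)


class TestBernoulliTrial:
    def test_matches_race_path(self, rng):
        params = AttentionalParams(45.0, 0.6)
        r = EncodingRates(27.0, 18.0)
        n = 100_000
        b = sum(simulate_bernoulli_trial(params, 0.0167, rng) for _ in range(n))
        races = sum(simulate_race_trial(r, 0.0167, rng) for _ in range(n))
        p1, p2 = b / n, races / n
        pooled = (b + races) / (2 * n)
        z = (p1 - p2) / math.sqrt(2 * pooled * (1 - pooled) / n)
        assert abs(z) < 3

    def test_seeded_reproducibility(self):
        params = AttentionalParams(40.0, 0.5)
        a = [simulate_bernoulli_trial(params, 0.01, np.random.default_rng(7))
             for _ in range(1)]
        b = [simulate_bernoulli_trial(params, 0.01, np.random.default_rng(7))
             for _ in range(1)]
        assert a == b


class TestPopulation:
    def test_zero_spread_collapses_to_means(self, rng):
        cfg = PopulationConfig(sd_C=0.0, sd_w=0.0, corr=0.0)
        pop = sample_population(cfg, 10, rng)
        assert np.allclose(pop.C_assertion, cfg.mean_C_assert)
        assert np.allclose(pop.w_negation, cfg.mean_w_negate)

    def test_correlation_recovered(self, rng):
        cfg = PopulationConfig(corr=0.9)
        pop = sample_population(cfg, 500, rng)
        r = np.corrcoef(pop.logC_assertion, pop.logC_negation)[0, 1]
        assert 0.8 < r < 0.96

    def test_draws_satisfy_invariants(self, rng):
        pop = sample_population(PopulationConfig(sd_C=1.0, sd_w=2.0), 500, rng)
        assert (pop.C_assertion > 0).all() and (pop.C_negation > 0).all()
        assert pop.w_assertion.between(0, 1, inclusive="neither").all()

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(corr=1.0)


class TestAdaptationCurve:
    def test_zero_rate_stays_at_start(self):
        c = AdaptationCurveParams(26.1, 31.5, 0.0)
        assert all(adaptation_value(c, r) == 26.1 for r in range(5))

    def test_limit_is_asymptote(self):
        c = AdaptationCurveParams(26.1, 31.5, 0.8)
        assert adaptation_value(c, 1000) == pytest.approx(31.5)

    def test_closed_form_and_monotone(self):
        c = AdaptationCurveParams(26.1, 31.5, 0.8)
        v4 = adaptation_value(c, 4)
        assert v4 == pytest.approx(31.5 + (26.1 - 31.5) * math.exp(-3.2), abs=1e-9)
        assert 26.1 < v4 < 31.5
        vals = adaptation_value(c, np.arange(10))
        assert np.all(np.diff(vals) > 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            AdaptationCurveParams(26.0, 30.0, -0.1)


class TestDesigns:
    def test_exp1_budget_and_structure(self):
        df = build_design("exp1", seed=0, n_participants=2, sessions=1)
        per = df.groupby("participant_id").size()
        assert (per == 244).all()
        assert df.has_distractor_pair.all()
        # every sequence of length L holds exactly one trial per repetition 0..L-1
        runs = df.groupby(["participant_id", "session",
                           (df.condition != df.condition.shift()).cumsum()])
        for _, run in runs:
            L = run.sequence_length.iloc[0]
            assert sorted(run.repetition_index) == list(range(L))

    def test_exp3_blocked_layout(self):
        df = build_design("exp3", seed=0, n_participants=2)
        per_block = df.groupby(["participant_id", "session"])
        for _, block in per_block:
            assert len(block) == 220
            counts = block.soa.value_counts()
            assert len(counts) == 11
            assert (counts == 20).all()
            assert set(block.soa) == set(EXP3_SOAS_MS)
            assert block.condition.nunique() == 1

    def test_deterministic_given_seed(self):
        a = build_design("exp2", seed=9, n_participants=2, sessions=1)
        b = build_design("exp2", seed=9, n_participants=2, sessions=1)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateDataset:
    def test_balanced_null_case(self):
        cfg = PopulationConfig(mean_C_assert=40, mean_C_negate=40,
                               mean_w_assert=0.5, mean_w_negate=0.5,
                               sd_C=0.0, sd_w=0.0, corr=0.0, seed=3)
        df = simulate_dataset("exp2", cfg)
        at_zero = df[df.soa == 0.0]
        p = at_zero.response_probe_first.mean()
        assert abs(p - 0.5) < 3 * math.sqrt(0.25 / len(at_zero))

    def test_reproducible_given_seed(self):
        cfg = PopulationConfig(seed=11)
        design = build_design("exp2", seed=4, n_participants=3, sessions=1)
        a = simulate_dataset(design, cfg, np.random.default_rng(2))
        b = simulate_dataset(design, cfg, np.random.default_rng(2))
        pd.testing.assert_frame_equal(a, b)

    def test_per_soa_rates_track_psychometric_curve(self, rng):
        params = AttentionalParams(44.5, 0.504)
        cfg = PopulationConfig(mean_C_assert=44.5, mean_C_negate=44.5,
                               mean_w_assert=0.504, mean_w_negate=0.504,
                               sd_C=0.0, sd_w=0.0, corr=0.0)
        design = build_design("exp2", seed=1, n_participants=40, sessions=3)
        df = simulate_dataset(design, cfg, rng)
        g = df.groupby("soa")["response_probe_first"].agg(["mean", "count"])
        expected = psychometric_curve(params, g.index.to_numpy() / 1000.0)
        for (soa, row), p in zip(g.iterrows(), expected):
            assert abs(row["mean"] - p) < 3.5 * math.sqrt(p * (1 - p) / row["count"])

    def test_adaptation_orders_repetition_rates(self, rng):
        # strong monotone capacity recovery must show up in per-repetition
        # probe-first rates at trailing SOAs (up to binomial noise)
        curve = AdaptationCurveParams(start=15.0, asymptote=45.0, rate=0.8)
        cfg = PopulationConfig(mean_C_assert=30, mean_C_negate=30,
                               mean_w_assert=0.5, mean_w_negate=0.5,
                               sd_C=0.0, sd_w=0.0, corr=0.0,
                               adaptation={"negation": curve})
        design = build_design("exp1", seed=2, n_participants=40, sessions=3)
        df = simulate_dataset(design, cfg, rng)
        sub = df[(df.condition == "negation") & (df.soa == 100.0)]
        rates = sub.groupby("repetition_index")["response_probe_first"].mean()
        # faster encoding -> reference (leading) wins more often at +100 ms
        assert rates.iloc[4] < rates.iloc[0]

    def test_tables_validate_and_conserve_counts(self):
        df = simulate_dataset("exp3", PopulationConfig(seed=1))
        validate_trials(df)
        cells = aggregate_cells(df, "condition")
        assert cells.n.sum() == len(df)
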