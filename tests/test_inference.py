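"""Hierarchical model construction, sampling correctness, summaries,
contrasts and model comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest

from tvatoj.inference import (
    ConfigurationError,
    ModelSpec,
    aggregate_cells,
    build_model,
    compare_models,
    contrast,
    fit,
    no_pooling_estimates,
)
from tvatoj.simulate import PopulationConfig, build_design, simulate_dataset


def _small_cells(seed=8, participants=4, estimate_w=True):
    cfg = PopulationConfig(sd_C=0.0, sd_w=0.0, corr=0.0, seed=seed)
    design = build_design("exp2", seed=seed, n_participants=participants, sessions=1)
    return aggregate_cells(simulate_dataset(design, cfg), "condition")


FAST = {"chains": 4, "draws_per_chain": 500, "thin": 2, "warmup": 800,
        "ess_target": 500}


class TestAggregateCells:
    def test_single_cell_counts(self):
        trials = pd.DataFrame({
            "participant_id": ["p0"] * 10, "condition": ["assertion"] * 10,
            "soa": [50.0] * 10,
            "response_probe_first": [True] * 7 + [False] * 3,
        })
        cells = aggregate_cells(trials, "condition")
        assert len(cells) == 1
        assert cells.iloc[0].y == 7 and cells.iloc[0].n == 10

    def test_repetition_grouping_bounds(self):
        cfg = PopulationConfig(seed=0)
        trials = simulate_dataset(build_design("exp1", seed=0, n_participants=1,
                                               sessions=1), cfg)
        cells = aggregate_cells(trials, "condition_x_repetition")
        per_part = cells.groupby("participant_id").size()
        assert (per_part <= 2 * 5 * 7).all()
        assert cells.n.sum() == len(trials)

    def test_conditions_never_mixed(self):
        trials = simulate_dataset(build_design("exp2", seed=1, n_participants=2,
                                               sessions=1), PopulationConfig(seed=1))
        cells = aggregate_cells(trials, "condition")
        merged = trials.merge(cells, on=["participant_id", "condition", "soa"])
        assert len(merged) == len(trials)

    def test_window_grouping_uses_window_id(self):
        trials = pd.DataFrame({
            "participant_id": ["p0"] * 8, "condition": ["negation"] * 8,
            "soa": [0.0] * 8, "window_id": [0] * 4 + [1] * 4,
            "response_probe_first": [True, False] * 4,
        })
        cells = aggregate_cells(trials, "condition_x_window")
        assert sorted(cells.rep) == [0, 1]
        assert (cells.n == 4).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            aggregate_cells(pd.DataFrame(columns=["participant_id", "condition",
                                                  "soa", "response_probe_first"]))
        trials = pd.DataFrame({"participant_id": ["a"], "condition": ["assertion"],
                               "soa": [0.0], "response_probe_first": [True]})
        with pytest.raises(ValueError, match="grouping"):
            aggregate_cells(trials, "by_soa")


class TestBuildModel:
    def test_w_fixed_spec_has_no_weight_parameters(self):
        cells = _small_cells()
        m = build_model(cells, ModelSpec(estimate_w=False, pooling="complete"))
        assert not m.has("mu_logitw")
        th = m.theta(m.initial(np.random.default_rng(0))[None])
        assert th.shape == (1, len(cells))

    def test_adaptation_requires_repetition_levels(self):
        cells = _small_cells()  # single rep level
        with pytest.raises(ConfigurationError):
            build_model(cells, ModelSpec(adaptation="curve", pooling="complete"))

    def test_invalid_counts_rejected(self):
        cells = _small_cells().copy()
        cells.loc[0, "y"] = cells.loc[0, "n"] + 1
        with pytest.raises(ValueError):
            build_model(cells, ModelSpec())

    def test_prior_predictive_spans_unit_interval(self):
        m = build_model(_small_cells(), ModelSpec(sampler=FAST))
        theta = m.prior_predictive(np.random.default_rng(0), 300)
        assert theta.min() > 0.0 and theta.max() < 1.0
        assert theta.min() < 0.2 and theta.max() > 0.8  # spans, no bound mass

    def test_cells_adaptation_collapses_when_off(self):
        # adaptation off ignores repetition structure: one C per condition
        trials = simulate_dataset(build_design("exp1", seed=2, n_participants=2,
                                               sessions=1), PopulationConfig(seed=2))
        cells = aggregate_cells(trials, "condition_x_repetition")
        m = build_model(cells, ModelSpec(estimate_w=False, adaptation="off",
                                         pooling="complete"))
        assert m._idx["mu_logC"][1] == (2,)


class TestSamplingCorrectness:
    def test_posterior_matches_grid_integration(self):
        """Dual-route check: ensemble draws vs dense 2-D numeric integration
        of the complete-pooling posterior."""
        cells = _small_cells()
        cells = cells[cells.condition == "assertion"].reset_index(drop=True)
        spec = ModelSpec(pooling="complete",
                         sampler={"chains": 4, "draws_per_chain": 1500,
                                  "thin": 2, "warmup": 1000, "ess_target": 500})
        m = build_model(cells, spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(m, seed=5)
        lc = np.linspace(3.0, 4.8, 301)
        lw = np.linspace(-0.7, 1.1, 301)
        LC, LW = np.meshgrid(lc, lw, indexing="ij")
        lp = m.log_prob(np.stack([LC.ravel(), LW.ravel()], 1)).reshape(LC.shape)
        pz = np.exp(lp - lp.max())
        pz /= pz.sum()
        grid_mean = (pz * LC).sum()
        grid_sd = np.sqrt((pz * (LC - grid_mean) ** 2).sum())
        d = np.log(res.pooled("C_assertion"))
        assert d.mean() == pytest.approx(grid_mean, abs=0.15 * grid_sd)
        assert d.std() == pytest.approx(grid_sd, rel=0.15)

    def test_same_seed_identical_summaries(self):
        cells = _small_cells(participants=2)
        spec = ModelSpec(pooling="complete", sampler=FAST)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(build_model(cells, spec), seed=3)
            b = fit(build_model(cells, spec), seed=3)
        assert a.summary("C_assertion") == b.summary("C_assertion")

    def test_ess_below_target_is_flagged(self):
        cells = _small_cells(participants=2)
        spec = ModelSpec(pooling="complete",
                         sampler={**FAST, "ess_target": 10_000})
        with pytest.warns(UserWarning, match="ESS"):
            res = fit(build_model(cells, spec), seed=3)
        assert any("ESS" in w for w in res.warnings)

    def test_transform_safety_all_draws_legal(self, recovery):
        res = recovery["fit"]
        for cond in ("assertion", "negation"):
            assert (res.pooled(f"C_{cond}") > 0).all()
            w = res.pooled(f"w_{cond}")
            assert ((w > 0) & (w < 1)).all()
            part = res.idata.posterior[f"C_part_{cond}"].to_numpy()
            assert (part > 0).all()

    def test_identifiability_at_zero_soa(self):
        """Data only at SOA=0 pins w but leaves C at its prior."""
        rng = np.random.default_rng(4)
        cells = pd.DataFrame({
            "participant_id": ["all"], "condition": ["assertion"], "rep": [0],
            "soa": [0.0], "y": [int(rng.binomial(2000, 0.55))], "n": [2000]})
        spec = ModelSpec(pooling="complete",
                         sampler={"chains": 4, "draws_per_chain": 1000,
                                  "thin": 3, "warmup": 1000, "ess_target": 500})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(build_model(cells, spec), seed=3)
        sd_logC = np.log(res.pooled("C_assertion")).std()
        w = res.pooled("w_assertion")
        sd_logitw = np.log(w / (1 - w)).std()
        assert sd_logC > 0.35          # prior sd is 0.5: C unidentified
        assert sd_logitw < 0.1         # w sharply identified


class TestShrinkage:
    def test_partial_pooling_lies_between_no_pooling_and_group(self, recovery):
        res, cells = recovery["fit"], recovery["cells"]
        npe = no_pooling_estimates(cells)
        ok = total = 0
        for cond in ("assertion", "negation"):
            part = res.idata.posterior[f"C_part_{cond}"].to_numpy()
            post_log = np.log(part.reshape(-1, part.shape[-1])).mean(0)
            group_log = np.log(res.pooled(f"C_{cond}")).mean()
            for i, pid in enumerate(res.model.participants):
                mle = np.log(float(npe[(npe.participant_id == pid)
                                       & (npe.condition == cond)].C_hat.iloc[0]))
                lo, hi = sorted([mle, group_log])
                total += 1
                # 0.01 log tolerance absorbs Monte-Carlo jitter when the
                # no-pooling estimate already sits at the group mean
                ok += (lo - 0.01 <= post_log[i] <= hi + 0.01)
        assert ok / total >= 0.95


class TestContrast:
    def test_self_contrast_includes_zero(self, recovery):
        s = contrast(recovery["fit"], "C_assertion", "C_assertion")
        assert not s.excludes_zero
        assert s.mode == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetric_modes(self, recovery):
        ab = contrast(recovery["fit"], "C_assertion", "C_negation")
        ba = contrast(recovery["fit"], "C_negation", "C_assertion")
        assert ab.mode == pytest.approx(-ba.mode, abs=1e-9)

    def test_unknown_quantity_rejected(self, recovery):
        with pytest.raises(KeyError):
            contrast(recovery["fit"], "C_assertion", "nonexistent")


class TestCompareModels:
    def test_same_model_twice_is_a_wash(self):
        cells = _small_cells(participants=3)
        spec = ModelSpec(pooling="complete", sampler=FAST)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(build_model(cells, spec), seed=1)
            b = fit(build_model(cells, spec), seed=2)
        rep = compare_models(a, b)
        assert abs(rep.elpd_diff) < max(2 * rep.se_diff, 1.0)

    def test_mismatched_cells_rejected(self):
        spec = ModelSpec(pooling="complete", sampler=FAST)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit(build_model(_small_cells(seed=1, participants=2), spec), seed=1)
            b = fit(build_model(_small_cells(seed=2, participants=3), spec), seed=1)
        with pytest.raises(ValueError, match="identical"):
            compare_models(a, b)


class TestModelSpecValidation:
    def test_bad_settings_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(adaptation="quadratic")
        with pytest.raises(ConfigurationError):
            ModelSpec(pooling="none")
        with pytest.raises(ConfigurationError):
            ModelSpec(lkj_eta=0.0)
        with pytest.raises(ConfigurationError):
            ModelSpec(sampler={"chains": 1})
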