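"""Hierarchical Bayesian estimation of attentional capacity and weight from TOJ counts.

The generative model mirrors the data-producing assumptions of the synthetic
generator: per participant and instruction condition, a capacity ``C`` (log
scale) and probe weight ``w`` (logit scale) deviate from group means, with
the assertion/negation deviations correlated within participants (an
LKJ(eta) prior on the 2x2 correlation, half-normal priors on the spreads).
The parameters map deterministically through the race-model psychometric
function to a probe-first probability, and the observed counts are binomial.

Capacity adaptation over within-sequence repetitions can be modeled either
as an inverse-exponential curve superimposed on the group log-capacity
(``adaptation="curve"``) or as free per-repetition cell means
(``adaptation="cells"``); the two are comparable by PSIS-LOO.

Sampling uses adaptive Metropolis-within-Gibbs on the unconstrained scales
(so every posterior draw satisfies ``C > 0`` and ``0 < w < 1`` by
construction), with three blocks per sweep: group-level means/curves, the
spread/correlation hyper-parameters, and all participant deviations updated
in parallel with per-participant accept/reject.  Several independent chains
are run for rank-based R-hat and ESS diagnostics; an effective-sample-size
target (default 10,000 for the parameters of interest) is enforced as a
surfaced warning.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln, logit

from .posterior import PosteriorSummary, summarize

__all__ = [
    "BinomialCell",
    "ModelSpec",
    "ConfigurationError",
    "DiagnosticError",
    "aggregate_cells",
    "build_model",
    "fit",
    "FitResult",
    "contrast",
    "compare_models",
    "ComparisonReport",
    "no_pooling_estimates",
]

CONDITIONS = ("assertion", "negation")

DEFAULT_PRIORS = {
    # transformed-scale (mean, sd) for group means; scalars are half-normal scales
    "mu_logC": (math.log(40.0), 0.5),
    "mu_logitw": (0.0, 0.5),
    "log_rate": (math.log(0.7), 1.0),
    "sigma_logC": 0.3,
    "sigma_logitw": 0.3,
}

DEFAULT_SAMPLER = {
    "chains": 4,
    "draws_per_chain": 5000,
    "warmup": 2000,
    "thin": 4,
    "ess_target": 10_000,
}

_TARGET_ACCEPT = 0.3


class ConfigurationError(ValueError):
    """Model specification inconsistent with the supplied cells."""


class DiagnosticError(RuntimeError):
    """Sampling failed badly enough that the output should not be used."""


@dataclass(frozen=True)
class BinomialCell:
    """Counts of probe-first responses for one design cell."""

    participant_id: str
    condition: str
    soa: float  # ms
    y: int
    n: int
    rep: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.y <= self.n or self.n < 1:
            raise ValueError("cell requires 0 <= y <= n and n >= 1")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of the hierarchical model and its sampler.

    ``estimate_w=False`` fixes the probe weight at 0.5 (equal-relevance
    layout); ``adaptation`` selects flat, curve, or per-repetition cell-mean
    capacity structure; ``pooling="complete"`` drops the participant level
    (used for small simulation studies).
    """

    estimate_w: bool = True
    adaptation: str = "off"  # off | curve | cells
    lkj_eta: float = 1.0
    pooling: str = "partial"  # partial | complete
    priors: dict = field(default_factory=dict)
    sampler: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.adaptation not in ("off", "curve", "cells"):
            raise ConfigurationError(f"unknown adaptation {self.adaptation!r}")
        if self.pooling not in ("partial", "complete"):
            raise ConfigurationError(f"unknown pooling {self.pooling!r}")
        if self.lkj_eta <= 0:
            raise ConfigurationError("lkj_eta must be positive")
        if self.full_sampler["chains"] < 2:
            raise ConfigurationError("at least two chains are required")

    @property
    def full_priors(self) -> dict:
        return {**DEFAULT_PRIORS, **self.priors}

    @property
    def full_sampler(self) -> dict:
        return {**DEFAULT_SAMPLER, **self.sampler}


# ---------------------------------------------------------------------------
# cell aggregation

_GROUPINGS = {
    "condition": (),
    "condition_x_repetition": ("repetition_index",),
    "condition_x_window": ("window_id",),
}


def aggregate_cells(trials: pd.DataFrame, grouping: str = "condition") -> pd.DataFrame:
    """Collapse a trial table into binomial cells.

    Cells are keyed by participant, condition, SOA and — depending on
    ``grouping`` — the repetition index or sliding-window id (both carried in
    the ``rep`` output column).  The summed ``n`` over cells equals the input
    trial count; a grouping never mixes conditions.
    """
    grouping = grouping.replace("×", "_x_")
    if grouping not in _GROUPINGS:
        raise ValueError(f"unknown grouping {grouping!r}; expected one of {sorted(_GROUPINGS)}")
    if len(trials) == 0:
        raise ValueError("cannot aggregate an empty trial table")
    extra = _GROUPINGS[grouping]
    for col in ("participant_id", "condition", "soa", "response_probe_first") + extra:
        if col not in trials.columns:
            raise ValueError(f"trial table lacks required column {col!r}")
    keys = ["participant_id", "condition", *extra, "soa"]
    g = trials.groupby(keys, sort=True)["response_probe_first"]
    out = g.agg(y="sum", n="count").reset_index()
    out["y"] = out["y"].astype(int)
    if extra:
        out = out.rename(columns={extra[0]: "rep"})
    else:
        out["rep"] = 0
    return out[["participant_id", "condition", "rep", "soa", "y", "n"]]


# ---------------------------------------------------------------------------
# the model


class TOJModel:
    """Log-posterior of the hierarchical TVA-TOJ model, in update blocks.

    Parameters live on unconstrained scales (log C, logit w, log sigma,
    atanh rho); participant deviations are kept on their natural (centered)
    scale with a multivariate-normal prior whose spread/correlation are the
    hyper-parameters.  The flat parameter vector concatenates group-level
    terms, hyper-parameters and deviations; block index arrays drive the
    Gibbs sweep.
    """

    def __init__(self, cells: pd.DataFrame, spec: ModelSpec):
        if len(cells) == 0:
            raise ValueError("no cells supplied")
        cells = cells.reset_index(drop=True)
        bad = cells[(cells["y"] < 0) | (cells["y"] > cells["n"]) | (cells["n"] < 1)]
        if len(bad):
            raise ValueError(f"invalid counts in cells at rows {list(bad.index[:5])}")
        conds = [c for c in CONDITIONS if c in set(cells["condition"])]
        if not conds or set(cells["condition"]) - set(CONDITIONS):
            raise ValueError("conditions must be a subset of {assertion, negation}")
        self.spec = spec
        self.cells = cells
        self.conditions = conds
        self.ncond = len(conds)
        self.participants = sorted(cells["participant_id"].unique())
        self.n_part = len(self.participants)
        self.rep_levels = sorted(cells["rep"].unique()) if spec.adaptation != "off" else [0]
        if spec.adaptation != "off" and len(self.rep_levels) < 2:
            raise ConfigurationError(
                "adaptation model requires cells with at least two repetition levels")
        self.R = len(self.rep_levels)
        self._rvals = np.asarray(self.rep_levels, dtype=float)

        cond_ix = {c: i for i, c in enumerate(conds)}
        part_ix = {p: i for i, p in enumerate(self.participants)}
        rep_ix = {r: i for i, r in enumerate(self.rep_levels)}
        self._ci = cells["condition"].map(cond_ix).to_numpy()
        self._pi = cells["participant_id"].map(part_ix).to_numpy()
        self._ri = (cells["rep"].map(rep_ix).to_numpy()
                    if spec.adaptation != "off" else np.zeros(len(cells), dtype=int))
        self._soa = cells["soa"].to_numpy(dtype=float) / 1000.0  # seconds
        self._y = cells["y"].to_numpy(dtype=float)
        self._n = cells["n"].to_numpy(dtype=float)
        self._lgamma = gammaln(self._n + 1) - gammaln(self._y + 1) - gammaln(self._n - self._y + 1)
        self._build_layout()
        self._crude = self._crude_estimates()

    # -- parameter layout ---------------------------------------------------

    def _build_layout(self) -> None:
        spec, nc, n = self.spec, self.ncond, self.n_part
        self._idx: dict[str, tuple[slice, tuple[int, ...]]] = {}
        d = 0

        def add(name: str, shape: tuple[int, ...]) -> None:
            nonlocal d
            size = int(np.prod(shape))
            self._idx[name] = (slice(d, d + size), shape)
            d += size

        if spec.adaptation == "curve":
            add("logC_start", (nc,))
            add("logC_asym", (nc,))
            add("log_rate", (nc,))
        elif spec.adaptation == "cells":
            add("mu_logC", (nc, self.R))
        else:
            add("mu_logC", (nc,))
        if spec.estimate_w:
            add("mu_logitw", (nc,))
        self._group_names = list(self._idx)
        if spec.pooling == "partial":
            add("log_sigma_C", (nc,))
            if nc == 2:
                add("u_rho_C", (1,))
            if spec.estimate_w:
                add("log_sigma_w", (nc,))
                if nc == 2:
                    add("u_rho_w", (1,))
            self._hyper_names = [k for k in self._idx if k not in self._group_names]
            add("delta_C", (n, nc))
            if spec.estimate_w:
                add("delta_w", (n, nc))
        else:
            self._hyper_names = []
        self.ndim = d
        self._group_idx = np.concatenate(
            [np.arange(self._idx[k][0].start, self._idx[k][0].stop)
             for k in self._group_names])
        self._hyper_idx = (np.concatenate(
            [np.arange(self._idx[k][0].start, self._idx[k][0].stop)
             for k in self._hyper_names]) if self._hyper_names else np.empty(0, dtype=int))

    def _get(self, params: np.ndarray, name: str) -> np.ndarray:
        sl, shape = self._idx[name]
        return params[:, sl].reshape((params.shape[0],) + shape)

    def has(self, name: str) -> bool:
        return name in self._idx

    # -- density pieces (all accept a (W, ndim) batch) ----------------------

    def group_logC(self, params: np.ndarray) -> np.ndarray:
        """Group-level log-capacity, shape (W, ncond, R)."""
        if self.spec.adaptation == "curve":
            start = self._get(params, "logC_start")[:, :, None]
            asym = self._get(params, "logC_asym")[:, :, None]
            rate = np.exp(np.clip(self._get(params, "log_rate"), -20, 6))[:, :, None]
            return asym + (start - asym) * np.exp(-rate * self._rvals[None, None, :])
        if self.spec.adaptation == "cells":
            return self._get(params, "mu_logC")
        return self._get(params, "mu_logC")[:, :, None]

    def _deltas(self, params: np.ndarray, which: str) -> np.ndarray | None:
        if self.spec.pooling != "partial":
            return None
        if which == "w" and not self.spec.estimate_w:
            return None
        return self._get(params, f"delta_{which}")

    def theta(self, params: np.ndarray) -> np.ndarray:
        """Probe-first probability per cell, shape (W, ncells)."""
        params = np.atleast_2d(params)
        logC = self.group_logC(params)[:, self._ci, self._ri]
        dC = self._deltas(params, "C")
        if dC is not None:
            logC = logC + dC[:, self._pi, self._ci]
        C = np.exp(np.clip(logC, -10.0, 12.0))
        if self.spec.estimate_w:
            lw = self._get(params, "mu_logitw")[:, self._ci]
            dw = self._deltas(params, "w")
            if dw is not None:
                lw = lw + dw[:, self._pi, self._ci]
            w = expit(lw)
        else:
            w = 0.5
        v_p = C * w
        v_r = C - v_p
        s = self._soa
        th = np.where(
            s < 0,
            1.0 - np.exp(-v_p * np.abs(s)) * (1.0 - w),
            np.exp(-v_r * np.abs(s)) * w,
        )
        return np.clip(th, 1e-12, 1.0 - 1e-12)

    def pointwise_loglik(self, params: np.ndarray) -> np.ndarray:
        """Per-cell binomial log-likelihood (without the count coefficient)."""
        th = self.theta(params)
        return self._y * np.log(th) + (self._n - self._y) * np.log1p(-th)

    def loglik_by_participant(self, params: np.ndarray) -> np.ndarray:
        """Likelihood summed per participant, shape (W, n_part)."""
        ll = self.pointwise_loglik(params)
        out = np.zeros((ll.shape[0], self.n_part))
        np.add.at(out.T, self._pi, ll.T)
        return out

    def log_prior_group(self, params: np.ndarray) -> np.ndarray:
        pri = self.spec.full_priors
        lp = np.zeros(params.shape[0])
        m, s = pri["mu_logC"]
        for name in ("mu_logC", "logC_start", "logC_asym"):
            if self.has(name):
                v = self._get(params, name)
                lp += -0.5 * (((v - m) / s) ** 2).reshape(params.shape[0], -1).sum(1)
        if self.has("log_rate"):
            rm, rs = pri["log_rate"]
            v = self._get(params, "log_rate")
            lp += -0.5 * (((v - rm) / rs) ** 2).sum(1)
        if self.has("mu_logitw"):
            wm, ws = pri["mu_logitw"]
            v = self._get(params, "mu_logitw")
            lp += -0.5 * (((v - wm) / ws) ** 2).sum(1)
        return lp

    def _cov_terms(self, params: np.ndarray, which: str):
        """Sigma (W, ncond) and rho (W,) of the deviation prior."""
        sig = np.exp(np.clip(self._get(params, f"log_sigma_{which}"), -12, 4))
        if self.ncond == 2:
            rho = np.tanh(self._get(params, f"u_rho_{which}")[:, 0])
        else:
            rho = np.zeros(params.shape[0])
        return sig, rho

    def log_prior_hyper(self, params: np.ndarray) -> np.ndarray:
        """Half-normal/LKJ densities of the hyper-parameters (with Jacobians),
        excluding the deviation terms."""
        pri = self.spec.full_priors
        lp = np.zeros(params.shape[0])
        for which, key in (("C", "sigma_logC"), ("w", "sigma_logitw")):
            if which == "w" and not self.spec.estimate_w:
                continue
            if not self.has(f"log_sigma_{which}"):
                continue
            ls = self._get(params, f"log_sigma_{which}")
            sig = np.exp(np.clip(ls, -12, 4))
            lp += (-0.5 * (sig / pri[key]) ** 2 + ls).sum(1)
            if self.ncond == 2:
                u = self._get(params, f"u_rho_{which}")[:, 0]
                rho2 = np.tanh(u) ** 2
                lp += self.spec.lkj_eta * np.log1p(-np.clip(rho2, 0.0, 1.0 - 1e-12))
        return lp

    def log_prior_delta_by_participant(self, params: np.ndarray, which: str) -> np.ndarray:
        """MVN(0, Sigma) density of each participant's deviations, (W, n_part)."""
        delta = self._deltas(params, which)
        sig, rho = self._cov_terms(params, which)
        if self.ncond == 2:
            om = 1.0 - rho**2
            d0 = delta[:, :, 0] / sig[:, None, 0]
            d1 = delta[:, :, 1] / sig[:, None, 1]
            quad = (d0**2 - 2 * rho[:, None] * d0 * d1 + d1**2) / om[:, None]
            logdet = (np.log(sig).sum(1) + 0.5 * np.log(om))[:, None]
        else:
            quad = (delta[:, :, 0] / sig[:, None, 0]) ** 2
            logdet = np.log(sig[:, 0])[:, None]
        return -0.5 * quad - logdet

    def log_prob(self, params: np.ndarray) -> np.ndarray:
        """Full joint log-density (up to a constant), for testing and checks."""
        params = np.atleast_2d(params)
        lp = self.log_prior_group(params) + self.pointwise_loglik(params).sum(1)
        if self.spec.pooling == "partial":
            lp = lp + self.log_prior_hyper(params)
            lp = lp + self.log_prior_delta_by_participant(params, "C").sum(1)
            if self.spec.estimate_w:
                lp = lp + self.log_prior_delta_by_participant(params, "w").sum(1)
        return np.where(np.isfinite(lp), lp, -np.inf)

    # -- initialization -----------------------------------------------------

    def _crude_estimates(self) -> dict[str, np.ndarray]:
        """Coarse grid MLE per condition on pooled counts, for chain seeding."""
        logC0 = np.empty(self.ncond)
        lw0 = np.zeros(self.ncond)
        Cgrid = np.exp(np.linspace(math.log(5.0), math.log(200.0), 60))
        wgrid = (np.linspace(0.3, 0.7, 17) if self.spec.estimate_w else np.array([0.5]))
        for k in range(self.ncond):
            m = self._ci == k
            y, n, s = self._y[m], self._n[m], self._soa[m]
            best, best_ll = (40.0, 0.5), -np.inf
            for C in Cgrid:
                for w in wgrid:
                    v_p, v_r = C * w, C * (1 - w)
                    th = np.where(s < 0, 1 - np.exp(-v_p * np.abs(s)) * (1 - w),
                                  np.exp(-v_r * np.abs(s)) * w)
                    th = np.clip(th, 1e-12, 1 - 1e-12)
                    ll = float(np.sum(y * np.log(th) + (n - y) * np.log1p(-th)))
                    if ll > best_ll:
                        best, best_ll = (C, w), ll
            logC0[k] = math.log(best[0])
            lw0[k] = logit(min(max(best[1], 0.31), 0.69))
        return {"logC": logC0, "logitw": lw0}

    def initial(self, rng: np.random.Generator) -> np.ndarray:
        """One over-dispersed starting point near the crude pooled estimate."""
        x = np.zeros(self.ndim)
        cr = self._crude

        def put(name: str, vals) -> None:
            sl, _ = self._idx[name]
            x[sl] = np.asarray(vals).ravel()

        for name in ("mu_logC", "logC_start", "logC_asym"):
            if self.has(name):
                _, shape = self._idx[name]
                base = np.broadcast_to(
                    cr["logC"].reshape((self.ncond,) + (1,) * (len(shape) - 1)), shape)
                put(name, base + 0.15 * rng.standard_normal(shape))
        if self.has("log_rate"):
            put("log_rate", math.log(0.7) + 0.5 * rng.standard_normal(self.ncond))
        if self.has("mu_logitw"):
            put("mu_logitw", cr["logitw"] + 0.15 * rng.standard_normal(self.ncond))
        if self.spec.pooling == "partial":
            for which in ("C", "w"):
                if which == "w" and not self.spec.estimate_w:
                    continue
                put(f"log_sigma_{which}",
                    math.log(0.15) + 0.3 * rng.standard_normal(self.ncond))
                if self.ncond == 2:
                    put(f"u_rho_{which}", 0.3 * rng.standard_normal(1))
                put(f"delta_{which}",
                    0.1 * rng.standard_normal((self.n_part, self.ncond)))
        return x

    def prior_predictive(self, rng: np.random.Generator, n_draws: int = 500) -> np.ndarray:
        """Draw theta from the prior, shape (n_draws, ncells)."""
        pri = self.spec.full_priors
        p = np.zeros((n_draws, self.ndim))
        for name in ("mu_logC", "logC_start", "logC_asym"):
            if self.has(name):
                sl, _ = self._idx[name]
                m, s = pri["mu_logC"]
                p[:, sl] = rng.normal(m, s, (n_draws, sl.stop - sl.start))
        if self.has("log_rate"):
            sl, _ = self._idx["log_rate"]
            m, s = pri["log_rate"]
            p[:, sl] = rng.normal(m, s, (n_draws, sl.stop - sl.start))
        if self.has("mu_logitw"):
            sl, _ = self._idx["mu_logitw"]
            m, s = pri["mu_logitw"]
            p[:, sl] = rng.normal(m, s, (n_draws, sl.stop - sl.start))
        if self.spec.pooling == "partial":
            for which, key in (("C", "sigma_logC"), ("w", "sigma_logitw")):
                if which == "w" and not self.spec.estimate_w:
                    continue
                sig = np.abs(rng.normal(0, pri[key], (n_draws, self.ncond)))
                sig = np.maximum(sig, 1e-6)
                sl, _ = self._idx[f"log_sigma_{which}"]
                p[:, sl] = np.log(sig)
                if self.ncond == 2:
                    rho = 2.0 * rng.beta(self.spec.lkj_eta, self.spec.lkj_eta, n_draws) - 1.0
                    rho = np.clip(rho, -0.999, 0.999)
                    sl, _ = self._idx[f"u_rho_{which}"]
                    p[:, sl] = np.arctanh(rho)[:, None]
                    z = rng.standard_normal((n_draws, self.n_part, 2))
                    d0 = sig[:, None, 0] * z[:, :, 0]
                    d1 = sig[:, None, 1] * (rho[:, None] * z[:, :, 0]
                                            + np.sqrt(1 - rho**2)[:, None] * z[:, :, 1])
                    delta = np.stack([d0, d1], axis=2)
                else:
                    delta = sig[:, None, :] * rng.standard_normal(
                        (n_draws, self.n_part, self.ncond))
                sl, _ = self._idx[f"delta_{which}"]
                p[:, sl] = delta.reshape(n_draws, -1)
        return self.theta(p)


def build_model(cells: pd.DataFrame, spec: ModelSpec) -> TOJModel:
    """Assemble the generative model for a set of binomial cells."""
    return TOJModel(cells, spec)


# ---------------------------------------------------------------------------
# adaptive Metropolis-within-Gibbs


def _run_chain(model: TOJModel, seed: int, warmup: int, draws: int, thin: int):
    """One chain; returns (draws, ndim) samples, (draws, ncells) log-lik,
    (draws,) log-posterior, and the mean group-block acceptance rate."""
    rng = np.random.default_rng(seed)
    x = model.initial(rng)
    partial = model.spec.pooling == "partial"
    gi, hi = model._group_idx, model._hyper_idx
    dg = len(gi)

    # current cached state
    ll_part = model.loglik_by_participant(x[None])[0]      # (n_part,)
    lp_group = float(model.log_prior_group(x[None])[0])
    if partial:
        lp_hyper = float(model.log_prior_hyper(x[None])[0])
        lp_delta = model.log_prior_delta_by_participant(x[None], "C")[0]
        if model.spec.estimate_w:
            lp_delta = lp_delta + model.log_prior_delta_by_participant(x[None], "w")[0]
    n_part = model.n_part
    ndelta = (2 if model.spec.estimate_w else 1) * model.ncond

    # proposal state
    ls_g = math.log(0.2 / math.sqrt(dg))
    chol_g = np.eye(dg)
    hist: list[np.ndarray] = []
    if partial:
        dh = len(hi)
        ls_h = math.log(0.3 / math.sqrt(dh))
        chol_h = np.eye(dh)
        hist_h: list[np.ndarray] = []
        ls_d = np.full(n_part, math.log(0.4 / math.sqrt(ndelta)))
        d_slices = []
        for which in ("C", "w"):
            if model.has(f"delta_{which}"):
                sl, _ = model._idx[f"delta_{which}"]
                d_slices.append((sl.start, sl.stop))
        # translation (interweaving) moves: shift a condition's group level and
        # counter-shift its deviations; the likelihood is invariant, so the
        # move is accepted on the prior ratio alone. It decorrelates the group
        # means from the participant deviations.
        trans_moves = []  # (group indices to shift, delta indices to counter-shift)
        for which in ("C", "w"):
            if not model.has(f"delta_{which}"):
                continue
            dsl, _ = model._idx[f"delta_{which}"]
            for c in range(model.ncond):
                if which == "C":
                    if model.spec.adaptation == "curve":
                        g_ix = [model._idx["logC_start"][0].start + c,
                                model._idx["logC_asym"][0].start + c]
                    else:
                        sl, shape = model._idx["mu_logC"]
                        if len(shape) == 2:  # cells model: all reps of condition c
                            g_ix = list(range(sl.start + c * shape[1],
                                              sl.start + (c + 1) * shape[1]))
                        else:
                            g_ix = [sl.start + c]
                else:
                    g_ix = [model._idx["mu_logitw"][0].start + c]
                d_ix = [dsl.start + i * model.ncond + c for i in range(n_part)]
                trans_moves.append((np.asarray(g_ix), np.asarray(d_ix)))
        ls_t = np.full(len(trans_moves), math.log(0.05))
        # rescaling (non-centered direction) moves: multiply a condition's
        # deviations by exp(e) while adding e to its log-spread; crosses the
        # sigma-delta funnel. Jacobian of the deviation map is exp(n_part e).
        resc_moves = []  # (log_sigma index, delta indices)
        for which in ("C", "w"):
            if not model.has(f"delta_{which}"):
                continue
            dsl, _ = model._idx[f"delta_{which}"]
            ssl, _ = model._idx[f"log_sigma_{which}"]
            for c in range(model.ncond):
                d_ix = np.asarray([dsl.start + i * model.ncond + c for i in range(n_part)])
                resc_moves.append((ssl.start + c, d_ix))
        ls_r = np.full(len(resc_moves), math.log(0.2))
        # rho refresh: independence proposal from the LKJ prior (no likelihood
        # term; the prior densities cancel against the proposal, leaving the
        # deviation-MVN ratio)
        rho_ix = [model._idx[f"u_rho_{wh}"][0].start
                  for wh in ("C", "w") if model.has(f"u_rho_{wh}")]

    keep = np.empty((draws, model.ndim))
    keep_ll = np.empty((draws, len(model.cells)))
    keep_lp = np.empty(draws)
    acc_g_sum = 0.0
    n_iter = warmup + draws * thin
    for it in range(n_iter):
        gamma = min(0.25, 5.0 / (1.0 + it)) if it < warmup else 0.0

        # --- group block ---
        prop = x.copy()
        prop[gi] = x[gi] + math.exp(ls_g) * (chol_g @ rng.standard_normal(dg))
        ll_prop = model.loglik_by_participant(prop[None])[0]
        lp_g_prop = float(model.log_prior_group(prop[None])[0])
        log_a = (lp_g_prop + ll_prop.sum()) - (lp_group + ll_part.sum())
        a = math.exp(min(0.0, log_a)) if np.isfinite(log_a) else 0.0
        if rng.random() < a:
            x, ll_part, lp_group = prop, ll_prop, lp_g_prop
        if it >= warmup:
            acc_g_sum += a
        if gamma:
            ls_g += gamma * (a - _TARGET_ACCEPT)
            hist.append(x[gi].copy())
            if it % 200 == 199 and len(hist) >= 100:
                cov = np.cov(np.asarray(hist[-1000:]).T) + 1e-9 * np.eye(dg)
                try:
                    chol_g = np.linalg.cholesky(cov / np.trace(cov) * dg)
                except np.linalg.LinAlgError:
                    pass

        if partial:
            # --- translation moves (likelihood-invariant) ---
            for m_i, (g_ix, d_ix) in enumerate(trans_moves):
                e = math.exp(ls_t[m_i]) * rng.standard_normal()
                prop = x.copy()
                prop[g_ix] += e
                prop[d_ix] -= e
                lp_g_prop = float(model.log_prior_group(prop[None])[0])
                lp_d_prop = model.log_prior_delta_by_participant(prop[None], "C")[0]
                if model.spec.estimate_w:
                    lp_d_prop = lp_d_prop + model.log_prior_delta_by_participant(
                        prop[None], "w")[0]
                log_a = (lp_g_prop + lp_d_prop.sum()) - (lp_group + lp_delta.sum())
                a = math.exp(min(0.0, log_a)) if np.isfinite(log_a) else 0.0
                if rng.random() < a:
                    x, lp_group, lp_delta = prop, lp_g_prop, lp_d_prop
                if gamma:
                    ls_t[m_i] += gamma * (a - 0.44)

            # --- rho refresh (independence proposal from the LKJ prior) ---
            eta = model.spec.lkj_eta
            for s_ix in rho_ix:
                u_new = math.atanh(np.clip(2.0 * rng.beta(eta, eta) - 1.0, -0.999, 0.999))
                prop = x.copy()
                prop[s_ix] = u_new
                lp_h_prop = float(model.log_prior_hyper(prop[None])[0])
                lp_d_prop = model.log_prior_delta_by_participant(prop[None], "C")[0]
                if model.spec.estimate_w:
                    lp_d_prop = lp_d_prop + model.log_prior_delta_by_participant(
                        prop[None], "w")[0]
                lkj_cur = eta * math.log1p(-math.tanh(x[s_ix]) ** 2)
                lkj_new = eta * math.log1p(-math.tanh(u_new) ** 2)
                log_a = ((lp_h_prop + lp_d_prop.sum()) - (lp_hyper + lp_delta.sum())
                         - (lkj_new - lkj_cur))
                a = math.exp(min(0.0, log_a)) if np.isfinite(log_a) else 0.0
                if rng.random() < a:
                    x, lp_hyper, lp_delta = prop, lp_h_prop, lp_d_prop

            # --- rescaling moves (cross the sigma-delta funnel) ---
            for m_i, (s_ix, d_ix) in enumerate(resc_moves):
                if (it + m_i) % 2:  # alternate sweeps; each move still adapts
                    continue
                e = math.exp(ls_r[m_i]) * rng.standard_normal()
                prop = x.copy()
                prop[s_ix] += e
                prop[d_ix] *= math.exp(e)
                ll_prop = model.loglik_by_participant(prop[None])[0]
                lp_h_prop = float(model.log_prior_hyper(prop[None])[0])
                lp_d_prop = model.log_prior_delta_by_participant(prop[None], "C")[0]
                if model.spec.estimate_w:
                    lp_d_prop = lp_d_prop + model.log_prior_delta_by_participant(
                        prop[None], "w")[0]
                log_a = ((lp_h_prop + lp_d_prop.sum() + ll_prop.sum())
                         - (lp_hyper + lp_delta.sum() + ll_part.sum())
                         + n_part * e)
                a = math.exp(min(0.0, log_a)) if np.isfinite(log_a) else 0.0
                if rng.random() < a:
                    x, ll_part, lp_hyper, lp_delta = prop, ll_prop, lp_h_prop, lp_d_prop
                if gamma:
                    ls_r[m_i] += gamma * (a - 0.44)

            # --- hyper block (no likelihood term) ---
            prop = x.copy()
            prop[hi] = x[hi] + math.exp(ls_h) * (chol_h @ rng.standard_normal(dh))
            lp_h_prop = float(model.log_prior_hyper(prop[None])[0])
            lp_d_prop = model.log_prior_delta_by_participant(prop[None], "C")[0]
            if model.spec.estimate_w:
                lp_d_prop = lp_d_prop + model.log_prior_delta_by_participant(prop[None], "w")[0]
            log_a = (lp_h_prop + lp_d_prop.sum()) - (lp_hyper + lp_delta.sum())
            a = math.exp(min(0.0, log_a)) if np.isfinite(log_a) else 0.0
            if rng.random() < a:
                x, lp_hyper, lp_delta = prop, lp_h_prop, lp_d_prop
            if gamma:
                ls_h += gamma * (a - _TARGET_ACCEPT)
                hist_h.append(x[hi].copy())
                if it % 200 == 199 and len(hist_h) >= 100:
                    cov = np.cov(np.asarray(hist_h[-1000:]).T) + 1e-9 * np.eye(dh)
                    try:
                        chol_h = np.linalg.cholesky(cov / np.trace(cov) * dh)
                    except np.linalg.LinAlgError:
                        pass

            # --- participant block: propose all deviations, accept per participant
            prop = x.copy()
            step = np.exp(ls_d)
            for lo, hiidx in d_slices:
                prop[lo:hiidx] = (x[lo:hiidx]
                                  + np.repeat(step, model.ncond)
                                  * rng.standard_normal(hiidx - lo))
            ll_prop = model.loglik_by_participant(prop[None])[0]
            lp_d_prop = model.log_prior_delta_by_participant(prop[None], "C")[0]
            if model.spec.estimate_w:
                lp_d_prop = lp_d_prop + model.log_prior_delta_by_participant(prop[None], "w")[0]
            log_a_i = (ll_prop + lp_d_prop) - (ll_part + lp_delta)
            a_i = np.exp(np.minimum(0.0, np.where(np.isfinite(log_a_i), log_a_i, -np.inf)))
            acc = rng.random(n_part) < a_i
            if acc.any():
                for lo, hiidx in d_slices:
                    mask = np.repeat(acc, model.ncond)
                    x[lo:hiidx][mask] = prop[lo:hiidx][mask]
                ll_part = np.where(acc, ll_prop, ll_part)
                lp_delta = np.where(acc, lp_d_prop, lp_delta)
            if gamma:
                ls_d += gamma * (a_i - _TARGET_ACCEPT)

        if it >= warmup and (it - warmup) % thin == thin - 1:
            j = (it - warmup) // thin
            keep[j] = x
            keep_ll[j] = model.pointwise_loglik(x[None])[0] + model._lgamma
            lp = lp_group + ll_part.sum()
            if partial:
                lp += lp_hyper + lp_delta.sum()
            keep_lp[j] = lp
    acc_rate = acc_g_sum / max(1, draws * thin)
    return keep, keep_ll, keep_lp, acc_rate


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FitResult:
    """Posterior draws, derived quantities, and diagnostics of one model fit."""

    idata: az.InferenceData
    spec: ModelSpec
    model: TOJModel
    warnings: list[str]
    seed: int

    @property
    def names(self) -> list[str]:
        return list(self.idata.posterior.data_vars)

    def draws(self, name: str) -> np.ndarray:
        if name not in self.idata.posterior:
            raise KeyError(f"unknown quantity {name!r}; have {self.names}")
        return self.idata.posterior[name].to_numpy()

    def pooled(self, name: str) -> np.ndarray:
        return self.draws(name).ravel()

    def summary(self, name: str) -> PosteriorSummary:
        if name not in self.idata.posterior:
            raise KeyError(f"unknown quantity {name!r}")
        ess = float(az.ess(self.idata, var_names=[name])[name])
        rhat = float(az.rhat(self.idata, var_names=[name])[name])
        return summarize(self.pooled(name), ess=ess, rhat=rhat)

    def summary_table(self, names: list[str] | None = None) -> pd.DataFrame:
        rows = []
        for name in names or [n for n in self.names if not n.startswith("C_part_")]:
            s = self.summary(name)
            rows.append({"quantity": name, "mode": s.mode, "hpd_low": s.hpd_low,
                         "hpd_high": s.hpd_high, "ess": s.ess, "rhat": s.rhat})
        return pd.DataFrame(rows)


def _dl_draws(C: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized difference limen (seconds) per posterior draw."""
    from .model import AttentionalParams, difference_limen

    w_in = np.clip(w, 0.2501, 0.7499)
    v_p, v_r = C * w_in, C * (1 - w_in)
    dl = 0.5 * (np.log(4 * w_in) / v_r + np.log(4 * (1 - w_in)) / v_p)
    out_of_band = (w <= 0.2501) | (w >= 0.7499)
    if np.any(out_of_band):
        flat_C, flat_w, flat_dl = C.ravel(), w.ravel(), dl.ravel()
        for i in np.nonzero(out_of_band.ravel())[0]:
            flat_dl[i] = difference_limen(AttentionalParams(flat_C[i], flat_w[i]))
        dl = flat_dl.reshape(C.shape)
    return dl


def _pss_draws(C: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Vectorized point of subjective simultaneity (seconds) per draw."""
    v_p, v_r = C * w, C * (1 - w)
    return np.where(w >= 0.5, np.log(2 * w) / v_r, -np.log(2 * (1 - w)) / v_p)


def fit(model: TOJModel, seed: int = 0) -> FitResult:
    """Sample the posterior and package draws, derived quantities, diagnostics.

    Runs ``chains`` independent adaptive Metropolis-within-Gibbs chains from
    over-dispersed starts; deterministic given ``seed``.  Raises
    :class:`DiagnosticError` when the chains stall (mean group-block
    acceptance below 2%); surfaces non-fatal issues (ESS below target,
    R-hat above 1.01) as warnings on the result.
    """
    spec = model.spec
    smp = spec.full_sampler
    chains = int(smp["chains"])
    draws = int(smp["draws_per_chain"])
    warmup = int(smp["warmup"])
    thin = int(smp["thin"])
    root = np.random.default_rng(seed)
    chain_seeds = root.integers(2**31, size=chains)

    samples = np.empty((chains, draws, model.ndim))
    log_lik = np.empty((chains, draws, len(model.cells)))
    lp = np.empty((chains, draws))
    acc = []
    for c in range(chains):
        samples[c], log_lik[c], lp[c], a = _run_chain(
            model, int(chain_seeds[c]), warmup, draws, thin)
        acc.append(a)
    if float(np.mean(acc)) < 0.02:
        raise DiagnosticError(
            f"group-block acceptance {np.mean(acc):.3f} < 0.02; the posterior draws "
            "are unusable. Increase warmup or revisit the model/priors.")

    flat = samples.reshape(-1, model.ndim)
    posterior = _derived_quantities(model, flat, (chains, draws))
    idata = az.from_dict(posterior=posterior,
                         log_likelihood={"y": log_lik},
                         sample_stats={"lp": lp})

    warns: list[str] = []
    group_names = [k for k in posterior
                   if k.startswith(("C_", "w_")) and not k.startswith("C_part_")]
    ess = az.ess(idata, var_names=group_names)
    min_ess = float(min(ess[v].min() for v in group_names))
    if min_ess < smp["ess_target"]:
        warns.append(f"ESS {min_ess:.0f} below target {smp['ess_target']} "
                     "for at least one parameter of interest")
    rhat = az.rhat(idata, var_names=group_names)
    max_rhat = float(max(rhat[v].max() for v in group_names))
    if max_rhat > 1.01:
        warns.append(f"R-hat {max_rhat:.3f} exceeds 1.01")
    for w in warns:
        _warnings.warn(w, UserWarning, stacklevel=2)
    return FitResult(idata=idata, spec=spec, model=model, warnings=warns, seed=seed)


def _derived_quantities(model: TOJModel, flat: np.ndarray,
                        shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Per-draw group-level quantities on natural scales."""
    spec = model.spec
    out: dict[str, np.ndarray] = {}

    def put(name: str, vals: np.ndarray) -> None:
        out[name] = vals.reshape(shape)

    glogC = model.group_logC(flat)  # (N, ncond, R)
    if spec.estimate_w:
        w_by_cond = expit(model._get(flat, "mu_logitw"))
    else:
        w_by_cond = np.full((flat.shape[0], model.ncond), 0.5)
    for k, cond in enumerate(model.conditions):
        if spec.adaptation == "off":
            C = np.exp(glogC[:, k, 0])
            put(f"C_{cond}", C)
            put(f"w_{cond}", w_by_cond[:, k])
            put(f"DL_{cond}", _dl_draws(C, w_by_cond[:, k]) * 1000.0)  # ms
            put(f"PSS_{cond}", _pss_draws(C, w_by_cond[:, k]) * 1000.0)  # ms
        else:
            for j, r in enumerate(model.rep_levels):
                put(f"C_{cond}_rep{r}", np.exp(glogC[:, k, j]))
            if spec.estimate_w:
                put(f"w_{cond}", w_by_cond[:, k])
            if spec.adaptation == "curve":
                put(f"C_{cond}_start", np.exp(model._get(flat, "logC_start")[:, k]))
                put(f"C_{cond}_asym", np.exp(model._get(flat, "logC_asym")[:, k]))
                put(f"rate_{cond}", np.exp(model._get(flat, "log_rate")[:, k]))
    if spec.pooling == "partial":
        sig, rho = model._cov_terms(flat, "C")
        for k, cond in enumerate(model.conditions):
            put(f"sigma_logC_{cond}", sig[:, k])
        if model.ncond == 2:
            put("rho_C", rho)
        if spec.estimate_w and model.ncond == 2:
            put("rho_w", model._cov_terms(flat, "w")[1])
        # participant-level capacities (used by shrinkage checks)
        dC = model._deltas(flat, "C")
        for k, cond in enumerate(model.conditions):
            part = np.exp(glogC[:, k, :].mean(axis=1, keepdims=True) + dC[:, :, k])
            out[f"C_part_{cond}"] = part.reshape(shape + (model.n_part,))
    return out


def contrast(fit_result: FitResult, quantity_a: str, quantity_b: str,
             mass: float = 0.95) -> PosteriorSummary:
    """Posterior summary of the per-draw difference A - B."""
    a = fit_result.pooled(quantity_a)
    b = fit_result.pooled(quantity_b)
    if a.shape != b.shape:
        raise ValueError("quantities have mismatched draw counts")
    return summarize(a - b, mass=mass)


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ComparisonReport:
    """PSIS-LOO comparison of two fits on identical cells (A minus B)."""

    elpd_a: float
    elpd_b: float
    elpd_diff: float
    se_diff: float
    preferred: str
    n_high_pareto_k: int


def compare_models(fit_a: FitResult, fit_b: FitResult,
                   names: tuple[str, str] = ("A", "B")) -> ComparisonReport:
    """ELPD difference (A - B) with its standard error via PSIS-LOO."""
    ca = fit_a.model.cells[["participant_id", "condition", "rep", "soa", "y", "n"]]
    cb = fit_b.model.cells[["participant_id", "condition", "rep", "soa", "y", "n"]]
    if len(ca) != len(cb) or not ca.reset_index(drop=True).equals(cb.reset_index(drop=True)):
        raise ValueError("model comparison requires identical observation cells")
    loo_a = az.loo(fit_a.idata, pointwise=True)
    loo_b = az.loo(fit_b.idata, pointwise=True)
    diff_i = loo_a.loo_i.to_numpy() - loo_b.loo_i.to_numpy()
    n = diff_i.size
    se = float(np.sqrt(n * np.var(diff_i)))
    elpd_diff = float(np.sum(diff_i))
    k_high = int(np.sum(loo_a.pareto_k.to_numpy() > 0.7)
                 + np.sum(loo_b.pareto_k.to_numpy() > 0.7))
    return ComparisonReport(
        elpd_a=float(loo_a.elpd_loo), elpd_b=float(loo_b.elpd_loo),
        elpd_diff=elpd_diff, se_diff=se,
        preferred=names[0] if elpd_diff > 0 else names[1],
        n_high_pareto_k=k_high,
    )


# ---------------------------------------------------------------------------
# no-pooling reference estimates (for shrinkage checks)


def no_pooling_estimates(cells: pd.DataFrame, estimate_w: bool = True) -> pd.DataFrame:
    """Per-participant, per-condition maximum-likelihood (C, w) with no pooling."""
    rows = []
    for (pid, cond), sub in cells.groupby(["participant_id", "condition"]):
        y = sub["y"].to_numpy(dtype=float)
        n = sub["n"].to_numpy(dtype=float)
        s = sub["soa"].to_numpy(dtype=float) / 1000.0

        def nll(x):
            C = math.exp(min(x[0], 12.0))
            w = expit(x[1]) if estimate_w else 0.5
            v_p, v_r = C * w, C * (1 - w)
            th = np.where(s < 0, 1 - np.exp(-v_p * np.abs(s)) * (1 - w),
                          np.exp(-v_r * np.abs(s)) * w)
            th = np.clip(th, 1e-12, 1 - 1e-12)
            return -float(np.sum(y * np.log(th) + (n - y) * np.log1p(-th)))

        res = minimize(nll, [math.log(40.0), 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000})
        rows.append({"participant_id": pid, "condition": cond,
                     "C_hat": math.exp(res.x[0]),
                     "w_hat": float(expit(res.x[1])) if estimate_w else 0.5})
    return pd.DataFrame(rows)
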