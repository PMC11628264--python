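"""Synthetic TOJ experiments with the statistical structure the analysis assumes.

Generates complete trial tables — participants, designs, responses — from a
known population truth, so every estimator in the package can be verified by
parameter recovery without any external data.  Responses can be produced two
ways: an explicit exponential race between probe and reference (the
generative story) or a Bernoulli draw from the closed-form probe-first
probability (the fast path); both have the same long-run behaviour.

Designs
-------
``exp1``   244 trials/session of alternating assertion/negation sequences of
           lengths {1, 2, 5}; seven SOAs (0, ±16.7, ±50, ±100 ms); a
           task-irrelevant distractor pair is present (flag only) and the two
           judged stimuli share attention equally (w = 0.5).
``exp2``   same sequence structure and SOA grid, single stimulus pair; the
           attentional weight w is a free parameter of the population.
``exp3``   two blocked 220-trial sessions (one condition each), eleven SOAs
           (adds ±33.3, ±66.7 ms), 20 trials per SOA.

Between-participant heterogeneity is multivariate normal on transformed
scales (log C, logit w) with a shared correlation between the assertion and
negation effects.  Within-sequence adaptation follows an inverse-exponential
curve applied to the group-level log-capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import EncodingRates, AttentionalParams, probe_first_probability, rates_from_capacity

__all__ = [
    "AdaptationCurveParams",
    "PopulationConfig",
    "ExperimentDesign",
    "EXP12_SOAS_MS",
    "EXP3_SOAS_MS",
    "adaptation_value",
    "simulate_race_trial",
    "simulate_bernoulli_trial",
    "sample_population",
    "build_design",
    "simulate_dataset",
    "default_design",
    "default_population",
]

EXP12_SOAS_MS = (-100.0, -50.0, -16.7, 0.0, 16.7, 50.0, 100.0)
EXP3_SOAS_MS = (-100.0, -66.7, -50.0, -33.3, -16.7, 0.0, 16.7, 33.3, 50.0, 66.7, 100.0)

CONDITIONS = ("assertion", "negation")


@dataclass(frozen=True)
class AdaptationCurveParams:
    """Inverse-exponential adaptation curve over within-run position.

    value(r) = asymptote + (start - asymptote) * exp(-rate * r); equals
    ``start`` at the first occurrence (r = 0) and approaches ``asymptote``
    monotonically as repetitions accumulate.
    """

    start: float
    asymptote: float
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("adaptation rate must be >= 0")


def adaptation_value(curve: AdaptationCurveParams, repetition) -> float | np.ndarray:
    """Evaluate the adaptation curve at a repetition index (0 = first occurrence)."""
    r = np.asarray(repetition, dtype=float)
    if np.any(r < 0):
        raise ValueError("repetition index must be >= 0")
    out = curve.asymptote + (curve.start - curve.asymptote) * np.exp(-curve.rate * r)
    return float(out) if np.ndim(repetition) == 0 else out


@dataclass(frozen=True)
class PopulationConfig:
    """Group-level truth for simulation.

    Capacities in Hz; spreads are standard deviations on the transformed
    scales (log for C, logit for w); ``corr`` couples the assertion and
    negation effects within a participant.  Optional per-condition
    adaptation curves act on the group-level capacity (Hz) as a function of
    within-run position.
    """

    mean_C_assert: float = 53.8
    mean_C_negate: float = 44.5
    mean_w_assert: float = 0.576
    mean_w_negate: float = 0.504
    sd_C: float = 0.15
    sd_w: float = 0.2
    corr: float = 0.5
    adaptation: dict[str, AdaptationCurveParams] | None = None
    mixture_eps: float = 0.0  # attention-capture lapse: random response w.p. eps
    seed: int = 0

    def __post_init__(self) -> None:
        for C in (self.mean_C_assert, self.mean_C_negate):
            if C <= 0:
                raise ValueError("mean capacities must be positive")
        for w in (self.mean_w_assert, self.mean_w_negate):
            if not 0 < w < 1:
                raise ValueError("mean weights must lie in (0, 1)")
        if self.sd_C < 0 or self.sd_w < 0:
            raise ValueError("spreads must be >= 0")
        if not -1 < self.corr < 1:
            raise ValueError("correlation must lie in (-1, 1)")
        if not 0 <= self.mixture_eps < 1:
            raise ValueError("mixture_eps must lie in [0, 1)")


@dataclass(frozen=True)
class ExperimentDesign:
    soa_set_ms: tuple[float, ...]
    trials_per_session: int
    structure: str  # "alternating_sequences" | "blocked"
    sequence_lengths: tuple[int, ...]
    n_participants: int
    sessions_per_participant: int
    has_distractor_pair: bool = False

    def __post_init__(self) -> None:
        if self.structure not in ("alternating_sequences", "blocked"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure == "blocked":
            n_soa = len(self.soa_set_ms)
            if self.trials_per_session % n_soa:
                raise ValueError(
                    "blocked design requires trials_per_session to be a "
                    f"multiple of the SOA count ({n_soa})"
                )


def default_design(experiment: str, n_participants: int | None = None,
                   sessions: int | None = None) -> ExperimentDesign:
    """The three study layouts with their published trial budgets."""
    if experiment == "exp1":
        return ExperimentDesign(EXP12_SOAS_MS, 244, "alternating_sequences", (1, 2, 5),
                                n_participants or 30, sessions or 3, has_distractor_pair=True)
    if experiment == "exp2":
        return ExperimentDesign(EXP12_SOAS_MS, 244, "alternating_sequences", (1, 2, 5),
                                n_participants or 42, sessions or 3)
    if experiment == "exp3":
        return ExperimentDesign(EXP3_SOAS_MS, 220, "blocked", (220,),
                                n_participants or 30, sessions or 2)
    raise ValueError(f"unknown experiment {experiment!r}")


def default_population(experiment: str, seed: int = 0) -> PopulationConfig:
    """Population truths anchored at the group estimates of each study."""
    if experiment == "exp1":
        return PopulationConfig(
            mean_C_assert=36.1, mean_C_negate=29.4,
            mean_w_assert=0.5, mean_w_negate=0.5, sd_w=0.0,
            adaptation={
                "assertion": AdaptationCurveParams(start=36.7, asymptote=36.0, rate=1.0),
                "negation": AdaptationCurveParams(start=26.1, asymptote=31.5, rate=0.8),
            },
            seed=seed,
        )
    if experiment == "exp2":
        return PopulationConfig(seed=seed)  # 53.8/44.5 Hz, 0.576/0.504
    if experiment == "exp3":
        return PopulationConfig(
            mean_C_assert=61.1, mean_C_negate=55.1,
            mean_w_assert=0.561, mean_w_negate=0.487,
            seed=seed,
        )
    raise ValueError(f"unknown experiment {experiment!r}")


# ---------------------------------------------------------------------------
# single-trial generators


def simulate_race_trial(rates: EncodingRates, soa: float, rng: np.random.Generator) -> bool:
    """One explicit exponential race; ``soa`` in seconds (probe minus reference onset).

    Encoding times are onset-anchored independent exponentials; returns
    whether the probe's absolute encoding time is smaller.
    """
    t_probe = max(soa, 0.0) + rng.exponential(1.0 / rates.v_p)
    t_ref = max(-soa, 0.0) + rng.exponential(1.0 / rates.v_r)
    return bool(t_probe < t_ref)


def simulate_bernoulli_trial(params: AttentionalParams, soa: float,
                             rng: np.random.Generator) -> bool:
    """Bernoulli draw from the closed-form probe-first probability; ``soa`` in seconds."""
    p = probe_first_probability(rates_from_capacity(params), soa)
    return bool(rng.random() < p)


def sample_population(config: PopulationConfig, n: int,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` participants' condition parameters.

    Correlated bivariate normals on the transformed scales: (log C_assert,
    log C_negate) share ``config.corr``, as do the logit weights.  Returns a
    frame with columns C_assertion, C_negation, w_assertion, w_negation and
    the transformed-scale values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rho = config.corr
    R = np.array([[1.0, rho], [rho, 1.0]])
    mu_logC = np.log([config.mean_C_assert, config.mean_C_negate])
    mu_lw = _logit(np.array([config.mean_w_assert, config.mean_w_negate]))
    logC = rng.multivariate_normal(mu_logC, (config.sd_C**2) * R, size=n)
    lw = rng.multivariate_normal(mu_lw, (config.sd_w**2) * R, size=n)
    return pd.DataFrame({
        "participant_id": [f"p{i:03d}" for i in range(n)],
        "logC_assertion": logC[:, 0], "logC_negation": logC[:, 1],
        "logitw_assertion": lw[:, 0], "logitw_negation": lw[:, 1],
        "C_assertion": np.exp(logC[:, 0]), "C_negation": np.exp(logC[:, 1]),
        "w_assertion": _expit(lw[:, 0]), "w_negation": _expit(lw[:, 1]),
    })


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# design scaffolds


def _sequence_lengths_for_budget(lengths: tuple[int, ...], budget: int) -> list[int]:
    """Per-condition multiset of sequence lengths whose trials sum to ``budget``,
    keeping the length counts as even as possible."""
    cycle_total = sum(lengths)
    counts = {L: budget // cycle_total for L in lengths}
    remainder = budget - cycle_total * (budget // cycle_total)
    # top up with the smallest lengths that fit exactly
    for L in sorted(lengths, reverse=True):
        while remainder >= L:
            counts[L] += 1
            remainder -= L
    if remainder:
        raise ValueError(f"trial budget {budget} not reachable with lengths {lengths}")
    out: list[int] = []
    for L in lengths:
        out.extend([L] * counts[L])
    return out


def build_design(experiment, seed: int = 0, n_participants: int | None = None,
                 sessions: int | None = None) -> pd.DataFrame:
    """Trial scaffold (every TrialRecord field except the response).

    ``experiment`` is ``"exp1" | "exp2" | "exp3"`` or an explicit
    :class:`ExperimentDesign`.  Deterministic given ``seed``.  SOA counts are
    balanced within (condition, repetition) cells as closely as the trial
    budget allows, by cycling independently shuffled SOA lists per cell.
    """
    if isinstance(experiment, str):
        design = default_design(experiment, n_participants, sessions)
    else:
        design = experiment
        if n_participants is not None:
            design = replace(design, n_participants=n_participants)
        if sessions is not None:
            design = replace(design, sessions_per_participant=sessions)
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for i in range(design.n_participants):
        pid = f"p{i:03d}"
        if design.structure == "alternating_sequences":
            for sess in range(1, design.sessions_per_participant + 1):
                rows.extend(_alternating_session(design, pid, sess, rng))
        else:
            # one condition per blocked session; order counterbalanced
            order = CONDITIONS if i % 2 == 0 else CONDITIONS[::-1]
            for sess, cond in enumerate(order[: design.sessions_per_participant], start=1):
                rows.extend(_blocked_session(design, pid, sess, cond, rng))
    df = pd.DataFrame(rows)
    return df


def _alternating_session(design: ExperimentDesign, pid: str, session: int,
                         rng: np.random.Generator) -> list[dict]:
    per_cond = design.trials_per_session // 2
    seqs = {c: _sequence_lengths_for_budget(design.sequence_lengths, per_cond)
            for c in CONDITIONS}
    for c in CONDITIONS:
        rng.shuffle(seqs[c])
    # SOA cyclers per (condition, repetition) cell for positional balance
    cyclers: dict[tuple[str, int], list[float]] = {}

    def next_soa(cond: str, rep: int) -> float:
        key = (cond, rep)
        if not cyclers.get(key):
            soas = list(design.soa_set_ms)
            rng.shuffle(soas)
            cyclers[key] = soas
        return cyclers[key].pop()

    rows = []
    trial = 0
    for a_len, n_len in zip(seqs["assertion"], seqs["negation"]):
        for cond, L in (("assertion", a_len), ("negation", n_len)):
            for rep in range(L):
                rows.append({
                    "participant_id": pid, "session": session, "trial_index": trial,
                    "condition": cond, "sequence_length": L,
                    "repetition_index": rep, "position_in_run": rep,
                    "soa": next_soa(cond, rep),
                    "has_distractor_pair": design.has_distractor_pair,
                })
                trial += 1
    return rows


def _blocked_session(design: ExperimentDesign, pid: str, session: int, cond: str,
                     rng: np.random.Generator) -> list[dict]:
    reps = design.trials_per_session // len(design.soa_set_ms)
    soas = np.repeat(design.soa_set_ms, reps)
    rng.shuffle(soas)
    L = design.trials_per_session
    return [{
        "participant_id": pid, "session": session, "trial_index": t,
        "condition": cond, "sequence_length": L,
        "repetition_index": min(t, 4), "position_in_run": t,
        "soa": float(soas[t]),
        "has_distractor_pair": design.has_distractor_pair,
    } for t in range(L)]


# ---------------------------------------------------------------------------
# dataset simulation


def simulate_dataset(design, config: PopulationConfig,
                     rng: np.random.Generator | None = None,
                     method: str = "bernoulli") -> pd.DataFrame:
    """Simulate responses for a design scaffold under a population truth.

    ``design`` is an experiment name, an :class:`ExperimentDesign`, or a
    scaffold frame from :func:`build_design`.  Participant parameters are
    drawn once per participant; when adaptation curves are configured the
    group-level capacity follows the curve over within-run position and each
    participant's offset shifts it on the log scale.  ``method`` selects the
    Bernoulli shortcut or the explicit exponential race.
    """
    if method not in ("bernoulli", "race"):
        raise ValueError(f"unknown method {method!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if not isinstance(design, pd.DataFrame):
        design = build_design(design, seed=int(rng.integers(2**31)))
    df = design.copy()
    pids = df["participant_id"].unique()
    pop = sample_population(config, len(pids), rng)
    pop.index = pids

    cond = df["condition"].to_numpy()
    pos = df["position_in_run"].to_numpy()
    logC = np.empty(len(df))
    logitw = np.empty(len(df))
    for c in CONDITIONS:
        m = cond == c
        part = df.loc[m, "participant_id"].map(pop[f"logC_{c}"]).to_numpy()
        partw = df.loc[m, "participant_id"].map(pop[f"logitw_{c}"]).to_numpy()
        mean_logC = math.log(config.mean_C_assert if c == "assertion"
                             else config.mean_C_negate)
        if config.adaptation and c in config.adaptation:
            curve = config.adaptation[c]
            group = np.log(adaptation_value(curve, pos[m]))
            logC[m] = group + (part - mean_logC)
        else:
            logC[m] = part
        logitw[m] = partw
    C = np.exp(logC)
    w = _expit(logitw)
    v_p = C * w
    v_r = C * (1.0 - w)
    soa_s = df["soa"].to_numpy() / 1000.0

    if method == "bernoulli":
        p = np.where(
            soa_s < 0,
            1.0 - np.exp(-v_p * np.abs(soa_s)) * (1.0 - w),
            np.exp(-v_r * np.abs(soa_s)) * w,
        )
        if config.mixture_eps > 0:
            p = (1 - config.mixture_eps) * p + config.mixture_eps * 0.5
        resp = rng.random(len(df)) < p
    else:
        t_probe = np.maximum(soa_s, 0.0) + rng.exponential(1.0, len(df)) / v_p
        t_ref = np.maximum(-soa_s, 0.0) + rng.exponential(1.0, len(df)) / v_r
        resp = t_probe < t_ref
        if config.mixture_eps > 0:
            lapse = rng.random(len(df)) < config.mixture_eps
            resp = np.where(lapse, rng.random(len(df)) < 0.5, resp)

    df["response_probe_first"] = resp
    return df
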