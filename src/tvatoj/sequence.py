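"""Sequential decompositions: repetition annotation and sliding-window fits.

Two ways the trial stream is cut up for analysis: (1) position within a run
of same-condition trials (first occurrence, first repetition, ...), used for
the adaptation analyses; (2) overlapping sliding windows over long blocked
sessions, used to look for slow drifts in capacity and weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import ModelSpec, aggregate_cells, build_model, contrast, fit

__all__ = ["WindowSpec", "annotate_repetitions", "make_windows", "windowed_fit"]

REPETITION_CAP = 4  # comparability with the five-position sequence analyses


@dataclass(frozen=True)
class WindowSpec:
    """Sliding windows of ``width`` trials advanced by ``step`` trials."""

    width: int
    step: int

    def __post_init__(self) -> None:
        if not self.width >= self.step >= 1:
            raise ValueError("require width >= step >= 1")

    def windows(self, block_length: int) -> list[tuple[int, int]]:
        return make_windows(block_length, self)


def annotate_repetitions(trials: pd.DataFrame) -> pd.DataFrame:
    """Assign each trial its position within the maximal run of
    same-condition trials of a (participant, session) block.

    Adds/overwrites ``position_in_run`` (full index) and ``repetition_index``
    (capped at 4).  Requires trials ordered by trial_index within each
    participant x session group; idempotent.
    """
    for col in ("participant_id", "session", "trial_index", "condition"):
        if col not in trials.columns:
            raise ValueError(f"trial table lacks required column {col!r}")
    out = trials.copy()
    pos = np.empty(len(out), dtype=int)
    for _, sub in out.groupby(["participant_id", "session"], sort=False):
        ti = sub["trial_index"].to_numpy()
        if np.any(np.diff(ti) <= 0):
            raise ValueError(
                "trials must be ordered by trial_index within participant and session")
        cond = sub["condition"].to_numpy()
        run = 0
        for j in range(len(sub)):
            run = 0 if j == 0 or cond[j] != cond[j - 1] else run + 1
            pos[out.index.get_loc(sub.index[j])] = run
    out["position_in_run"] = pos
    out["repetition_index"] = np.minimum(pos, REPETITION_CAP)
    return out


def make_windows(block_length: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open [start, start+width) intervals stepping through the block."""
    if block_length < spec.width:
        raise ValueError(
            f"block of {block_length} trials is shorter than the window width {spec.width}")
    starts = range(0, block_length - spec.width + 1, spec.step)
    return [(s, s + spec.width) for s in starts]


def windowed_fit(trials: pd.DataFrame, window_spec: WindowSpec,
                 model_spec: ModelSpec | None = None, seed: int = 0,
                 block_length: int | None = None) -> pd.DataFrame:
    """Per-window posterior summaries of C and w for blocked sessions.

    Each sliding window is fit independently (windows overlap, so a joint
    likelihood over all windows would count trials more than once).  Trials
    fall into a window by their within-block position (``position_in_run``).
    Returns a tidy frame with one row per (condition or contrast, window,
    quantity): columns condition, window_id, start, end, quantity, mode,
    hpd_low, hpd_high.
    """
    if model_spec is None:
        model_spec = ModelSpec(estimate_w=True, pooling="complete",
                               sampler={"chains": 4, "draws_per_chain": 750,
                                        "warmup": 1000, "thin": 2, "ess_target": 1000})
    if block_length is None:
        block_length = int(trials["position_in_run"].max()) + 1
    windows = make_windows(block_length, window_spec)
    conditions = sorted(trials["condition"].unique())
    rows = []
    all_soas = set(trials["soa"].unique())
    for wid, (start, end) in enumerate(windows):
        sub = trials[(trials["position_in_run"] >= start) & (trials["position_in_run"] < end)]
        missing = all_soas - set(sub["soa"].unique())
        if missing:
            warnings.warn(f"window {wid} [{start}, {end}) lacks SOA level(s) "
                          f"{sorted(missing)}; those cells are dropped", UserWarning)
        cells = aggregate_cells(sub, "condition")
        result = fit(build_model(cells, model_spec), seed=seed + wid)
        for cond in conditions:
            for qty in ("C", "w") if model_spec.estimate_w else ("C",):
                s = result.summary(f"{qty}_{cond}")
                rows.append({"condition": cond, "window_id": wid, "start": start,
                             "end": end, "quantity": qty, "mode": s.mode,
                             "hpd_low": s.hpd_low, "hpd_high": s.hpd_high})
        if len(conditions) == 2:
            for qty in ("C", "w") if model_spec.estimate_w else ("C",):
                s = contrast(result, f"{qty}_{conditions[0]}", f"{qty}_{conditions[1]}")
                rows.append({"condition": f"{conditions[0]}-{conditions[1]}",
                             "window_id": wid, "start": start, "end": end,
                             "quantity": qty, "mode": s.mode,
                             "hpd_low": s.hpd_low, "hpd_high": s.hpd_high})
    return pd.DataFrame(rows)
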