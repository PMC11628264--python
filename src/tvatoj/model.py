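"""Closed-form TVA mathematics for temporal-order judgments.

The Theory of Visual Attention (TVA) treats visual encoding as a
fixed-capacity parallel exponential race into visual short-term memory:
stimulus ``x`` is encoded by time ``t`` with probability
``1 - exp(-v_x (t - t0))`` for ``t > t0``, where ``v_x`` is the stimulus'
encoding rate (Hz) and ``t0`` an encoding threshold.  In a two-stimulus
temporal-order judgment (TOJ) the probe and reference race with rates
``v_p`` and ``v_r`` whose onsets are offset by the stimulus onset
asynchrony (SOA); the probability of reporting the probe first is the
probability that the probe's encoding finishes before the reference's.

Conventions
-----------
* Rates are in Hz, times in **seconds** throughout this module; the
  tabular I/O layer speaks milliseconds.
* SOA is the probe onset minus the reference onset: negative SOA means
  the probe leads.
* The two estimands of interest are the overall processing capacity
  ``C = v_p + v_r`` and the probe's relative attentional weight
  ``w = v_p / (v_p + v_r)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "EncodingRates",
    "AttentionalParams",
    "encoding_probability",
    "probe_first_probability",
    "rates_from_capacity",
    "capacity_from_rates",
    "point_of_subjective_simultaneity",
    "difference_limen",
    "psychometric_curve",
]


@dataclass(frozen=True)
class EncodingRates:
    """Stimulus-wise exponential race rates (Hz)."""

    v_p: float
    v_r: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v_p) and math.isfinite(self.v_r)):
            raise ValueError("encoding rates must be finite")
        if self.v_p <= 0 or self.v_r <= 0:
            raise ValueError(f"encoding rates must be positive, got ({self.v_p}, {self.v_r})")


@dataclass(frozen=True)
class AttentionalParams:
    """Overall processing capacity C (Hz) and probe weight w in (0, 1)."""

    C: float
    w: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.C) and math.isfinite(self.w)):
            raise ValueError("attentional parameters must be finite")
        if self.C <= 0:
            raise ValueError(f"capacity must be positive, got {self.C}")
        if not 0.0 < self.w < 1.0:
            raise ValueError(f"weight must lie strictly in (0, 1), got {self.w}")


def encoding_probability(rate: float, exposure: float, threshold: float = 0.0) -> float:
    """Probability that a stimulus with encoding ``rate`` (Hz) is encoded
    within ``exposure`` seconds, given threshold ``threshold`` seconds.

    Returns 0 when the exposure does not exceed the threshold; no
    effective encoding occurs below it.
    """
    if rate <= 0 or not math.isfinite(rate):
        raise ValueError(f"rate must be positive and finite, got {rate}")
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if exposure <= threshold:
        return 0.0
    return -math.expm1(-rate * (exposure - threshold))


def probe_first_probability(rates: EncodingRates, soa) -> float | np.ndarray:
    """Probability the probe is encoded before the reference at a given SOA.

    Piecewise in the SOA ``s`` (seconds, probe minus reference onset),
    with ``w = v_p / (v_p + v_r)``:

    * ``s < 0`` (probe leads): ``1 - exp(-v_p |s|) (1 - w)`` — either the
      probe finishes before the reference even starts, or both are
      pending and the probe wins the simultaneous race with probability w.
    * ``s >= 0`` (probe trails): ``exp(-v_r s) w`` — the reference must
      still be pending at probe onset, then the probe wins the race.

    Both branches equal ``w`` at ``s = 0``; the function is continuous and
    strictly decreasing in the SOA. Accepts a scalar or array SOA.
    """
    v_p, v_r = rates.v_p, rates.v_r
    w = v_p / (v_p + v_r)
    s = np.asarray(soa, dtype=float)
    out = np.where(
        s < 0,
        1.0 - np.exp(-v_p * np.abs(s)) * (1.0 - w),
        np.exp(-v_r * np.abs(s)) * w,
    )
    if np.ndim(soa) == 0:
        return float(out)
    return out


def rates_from_capacity(params: AttentionalParams) -> EncodingRates:
    """Split capacity into stimulus rates: ``v_p = C w``, ``v_r = C (1 - w)``."""
    return EncodingRates(v_p=params.C * params.w, v_r=params.C * (1.0 - params.w))


def capacity_from_rates(rates: EncodingRates) -> AttentionalParams:
    """Recover ``C = v_p + v_r`` and ``w = v_p / C`` from the race rates."""
    C = rates.v_p + rates.v_r
    return AttentionalParams(C=C, w=rates.v_p / C)


def point_of_subjective_simultaneity(params: AttentionalParams) -> float:
    """SOA (seconds) at which both temporal orders are reported equally often.

    Closed form: ``ln(2w)/v_r`` for ``w >= 0.5`` (probe favoured, positive
    PSS) and ``-ln(2(1-w))/v_p`` for ``w < 0.5``.  ``sign(PSS) = sign(w - 0.5)``.
    """
    rates = rates_from_capacity(params)
    if params.w >= 0.5:
        return math.log(2.0 * params.w) / rates.v_r
    return -math.log(2.0 * (1.0 - params.w)) / rates.v_p


def difference_limen(params: AttentionalParams) -> float:
    """Half the SOA span between the 25% and 75% points of the curve (seconds).

    For ``0.25 < w < 0.75`` the quartile SOAs sit on opposite branches and
    the closed form ``[ln(4w)/v_r + ln(4(1-w))/v_p] / 2`` applies; outside
    that band the quartiles are located numerically.  At ``w = 0.5`` this
    reduces to ``ln 2 / (C/2)``.
    """
    rates = rates_from_capacity(params)
    if 0.25 < params.w < 0.75:
        return 0.5 * (
            math.log(4.0 * params.w) / rates.v_r
            + math.log(4.0 * (1.0 - params.w)) / rates.v_p
        )
    soa_25 = soa_at_probability(rates, 0.25)
    soa_75 = soa_at_probability(rates, 0.75)
    return 0.5 * (soa_25 - soa_75)


def soa_at_probability(rates: EncodingRates, p: float) -> float:
    """Invert the psychometric function: the SOA (seconds) where the
    probe-first probability equals ``p`` in (0, 1), by bracketed
    root-finding on the strictly decreasing curve."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly in (0, 1)")
    f = lambda s: probe_first_probability(rates, s) - p
    # the curve spans (0, 1) over +/- 60 time constants of the slower rate
    span = 60.0 / min(rates.v_p, rates.v_r)
    return brentq(f, -span, span, xtol=1e-12)


def psychometric_curve(params: AttentionalParams, soas) -> np.ndarray:
    """Vectorized probe-first probabilities at each SOA (seconds)."""
    soas = np.asarray(soas, dtype=float)
    if soas.size == 0:
        return np.empty(0)
    return probe_first_probability(rates_from_capacity(params), soas)
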