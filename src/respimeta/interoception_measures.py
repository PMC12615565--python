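"""Interoceptive outcome measures from trial logs.

Four measures per subject: signal sensitivity d' and decision bias c from
yes/no counts (signal detection theory), metacognitive bias (mean confidence
over the analysed trials), and metacognitive insight Mratio = meta-d'/d'
estimated hierarchically across subjects (see :mod:`respimeta.hmeta`).

Sign conventions follow the standard equal-variance SDT model with the
stimulus-absent distribution at -d'/2 and stimulus-present at +d'/2:
d' = z(H) - z(F) and c = -(z(H) + z(F))/2, so c > 0 means a conservative
criterion — a tendency to under-report the presence of the resistance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm

from .fdt_engine import TrialRecord

__all__ = [
    "SDTCounts",
    "SubjectMeasures",
    "ConfidenceCounts",
    "DEFAULT_BIN_EDGES",
    "sdt_counts",
    "dprime_criterion",
    "metacognitive_bias",
    "bin_confidence",
    "type2_probabilities",
    "measures_table",
]

#: Default 4-bin grouping of the 1-10 confidence scale: {1-3, 4-5, 6-8, 9-10}.
DEFAULT_BIN_EDGES: dict[int, tuple[int, ...]] = {
    10: tuple(range(1, 11)),
    4: (1, 1, 1, 2, 2, 3, 3, 3, 4, 4),
}


@dataclass(frozen=True)
class SDTCounts:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    @property
    def n_signal(self) -> int:
        return self.hits + self.misses

    @property
    def n_noise(self) -> int:
        return self.false_alarms + self.correct_rejections

    @property
    def total(self) -> int:
        return self.n_signal + self.n_noise


@dataclass(frozen=True)
class SubjectMeasures:
    subject_id: str
    d_prime: float
    criterion_c: float
    metacog_bias: float
    mratio: float | None
    is_filters: int
    valid: bool


@dataclass(frozen=True)
class ConfidenceCounts:
    """Rating counts indexed (stimulus: absent/present) x (response: no/yes) x bin."""

    counts: np.ndarray  # shape (2, 2, B), int

    def __post_init__(self) -> None:
        if self.counts.ndim != 3 or self.counts.shape[:2] != (2, 2):
            raise ValueError("counts must have shape (2, 2, n_bins)")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    def to_sdt_counts(self) -> SDTCounts:
        c = self.counts.sum(axis=2)
        return SDTCounts(
            hits=int(c[1, 1]),
            misses=int(c[1, 0]),
            false_alarms=int(c[0, 1]),
            correct_rejections=int(c[0, 0]),
        )


def sdt_counts(trials: Sequence[TrialRecord]) -> SDTCounts:
    """Tabulate hits/misses/false alarms/correct rejections.

    Resistance trials are "signal", sham trials "noise"; a "yes" response
    reports the signal.
    """
    if len(trials) == 0:
        raise ValueError("no trials to tabulate")
    h = m = fa = cr = 0
    for t in trials:
        if t.condition == "resistance":
            if t.response == "yes":
                h += 1
            else:
                m += 1
        else:
            if t.response == "yes":
                fa += 1
            else:
                cr += 1
    return SDTCounts(h, m, fa, cr)


def dprime_criterion(
    counts: SDTCounts,
    correction_rule: Literal["loglinear", "half_count", "none"] = "loglinear",
) -> tuple[float, float]:
    """d' and criterion c from hit and false-alarm rates.

    ``loglinear`` adds 0.5 to every cell, but only when some rate is 0 or 1
    (otherwise the observed rates are used untouched); ``half_count``
    replaces extreme rates with 1/(2N) or 1 - 1/(2N).
    """
    if counts.n_signal == 0 or counts.n_noise == 0:
        raise ValueError("need at least one signal and one noise trial")
    h, ns = counts.hits, counts.n_signal
    f, nn = counts.false_alarms, counts.n_noise
    H, F = h / ns, f / nn
    extreme = H in (0.0, 1.0) or F in (0.0, 1.0)
    if extreme and correction_rule == "loglinear":
        H = (h + 0.5) / (ns + 1.0)
        F = (f + 0.5) / (nn + 1.0)
    elif extreme and correction_rule == "half_count":
        H = min(max(H, 1 / (2 * ns)), 1 - 1 / (2 * ns))
        F = min(max(F, 1 / (2 * nn)), 1 - 1 / (2 * nn))
    elif extreme:
        raise ValueError("extreme rate with correction_rule='none'")
    zH, zF = norm.ppf(H), norm.ppf(F)
    return float(zH - zF), float(-(zH + zF) / 2.0)


def metacognitive_bias(trials: Sequence[TrialRecord]) -> float:
    """Mean confidence rating over the analysed trials (scale 1-10)."""
    if len(trials) == 0:
        raise ValueError("no trials")
    return float(np.mean([t.confidence for t in trials]))


def bin_confidence(trials: Sequence[TrialRecord], n_bins: int = 4) -> ConfidenceCounts:
    """Map 1-10 ratings onto B ordered bins and tabulate by stimulus x response."""
    if n_bins > 10:
        raise ValueError("n_bins cannot exceed the 10-point rating scale")
    if n_bins not in DEFAULT_BIN_EDGES:
        raise ValueError(f"no default edge set for n_bins={n_bins}; use 4 or 10")
    mapping = DEFAULT_BIN_EDGES[n_bins]
    counts = np.zeros((2, 2, n_bins), dtype=int)
    for t in trials:
        stim = 1 if t.condition == "resistance" else 0
        resp = 1 if t.response == "yes" else 0
        counts[stim, resp, mapping[t.confidence - 1] - 1] += 1
    return ConfidenceCounts(counts)


def type2_probabilities(
    meta_d: float,
    type1_c_scaled: float,
    criteria_no: np.ndarray,
    criteria_yes: np.ndarray,
) -> np.ndarray:
    """Response-conditional confidence-bin probabilities of the meta-d' observer.

    The type-2 observer redraws the evidence from N(-meta_d/2, 1) (stimulus
    absent) or N(+meta_d/2, 1) (present), answers "yes" above the scaled
    type-1 criterion c' = c * meta_d/d', and rates confidence by which of the
    ordered type-2 criteria the evidence clears.  ``criteria_no`` are the B-1
    criteria below c' (ascending), ``criteria_yes`` the B-1 above (ascending);
    confidence grows with distance from c' on either side.

    Returns an array ``p`` of shape (2, 2, B) with
    ``p[stimulus, response]`` a distribution over bins summing to one.
    """
    criteria_no = np.asarray(criteria_no, dtype=float)
    criteria_yes = np.asarray(criteria_yes, dtype=float)
    if criteria_no.shape != criteria_yes.shape or criteria_no.ndim != 1:
        raise ValueError("criteria_no and criteria_yes must be 1-D of equal length")
    if criteria_no.size and (
        np.any(np.diff(criteria_no) <= 0)
        or np.any(np.diff(criteria_yes) <= 0)
        or criteria_no[-1] >= type1_c_scaled
        or criteria_yes[0] <= type1_c_scaled
    ):
        raise ValueError("type-2 criteria must be strictly ordered around c'")
    p = _type2_prob_batch(
        np.array([meta_d]),
        np.array([type1_c_scaled]),
        criteria_no[None, :],
        criteria_yes[None, :],
    )[0]
    return p


def _type2_prob_batch(
    meta_d: np.ndarray,
    c_scaled: np.ndarray,
    criteria_no: np.ndarray,
    criteria_yes: np.ndarray,
) -> np.ndarray:
    """Vectorised core of :func:`type2_probabilities`.

    Shapes: meta_d, c_scaled (S,); criteria (S, B-1). Returns (S, 2, 2, B).
    """
    S, Bm1 = criteria_no.shape
    B = Bm1 + 1
    # boundaries for the "yes" response, low->high confidence: c', t1..t_{B-1}, +inf
    yes_bounds = np.concatenate(
        [c_scaled[:, None], criteria_yes, np.full((S, 1), np.inf)], axis=1
    )
    # boundaries for "no", low->high confidence: c', u_{B-1}..u_1, -inf (descending)
    no_bounds = np.concatenate(
        [c_scaled[:, None], criteria_no[:, ::-1], np.full((S, 1), -np.inf)], axis=1
    )
    out = np.empty((S, 2, 2, B))
    for stim, sign in ((0, -1.0), (1, 1.0)):
        mu = sign * meta_d / 2.0
        cdf_yes = ndtr(yes_bounds - mu[:, None])  # (S, B+1)
        p_yes_bins = np.diff(cdf_yes, axis=1)  # mass in (bound_j, bound_{j+1})
        cdf_no = ndtr(no_bounds - mu[:, None])
        p_no_bins = -np.diff(cdf_no, axis=1)  # mass below, walking downward
        p_yes = np.clip(p_yes_bins, 1e-300, None)
        p_no = np.clip(p_no_bins, 1e-300, None)
        out[:, stim, 1, :] = p_yes / p_yes.sum(axis=1, keepdims=True)
        out[:, stim, 0, :] = p_no / p_no.sum(axis=1, keepdims=True)
    return out


def measures_table(per_subject: Iterable[SubjectMeasures]) -> pd.DataFrame:
    """Collect per-subject measures into the TSV-ready table."""
    rows = [
        {
            "id": m.subject_id,
            "d_prime": m.d_prime,
            "criterion_c": m.criterion_c,
            "metacog_bias": m.metacog_bias,
            "mratio": m.mratio,
            "is_filters": m.is_filters,
            "valid": m.valid,
        }
        for m in per_subject
    ]
    return pd.DataFrame(rows)
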