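"""Scoring of the one-back cover task and 2AFC recognition test.

The one-back task is scored with signal-detection d': a keypress is a hit if
it falls within a response window (default 250-1500 ms) after a probe; each
response is assigned to at most one probe (greedy, earliest unmatched probe
first) and unassigned responses are false alarms.  Hit and false-alarm rates
of exactly 0 or 1 are corrected by the 1/(2N) rule before the z-transform.
Group comparisons use a two-sided paired Wilcoxon signed-rank test for
reaction times, one-sample/paired t-tests for d', and a signed-rank test of
2AFC percent correct against chance (50%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import BehavioralRecord
from .streams import TokenStream

__all__ = [
    "OneBackScore",
    "TwoAFCScore",
    "score_one_back",
    "group_rt_test",
    "dprime_tests",
    "score_2afc",
]

DEFAULT_WINDOW_S = (0.25, 1.5)


@dataclass
class OneBackScore:
    """Signal-detection summary of one participant's one-back performance."""

    hits: int
    misses: int
    false_alarms: int
    n_probes: int
    n_nonprobe: int
    d_prime: float
    hit_rate: float
    fa_rate: float
    mean_rt_s: float  # mean reaction time over hits; NaN with no hits
    condition: str
    participant: str


@dataclass
class TwoAFCScore:
    """Two-alternative forced-choice recognition score."""

    n_trials: int
    n_correct: int
    participant: str = "P01"

    @property
    def pct_correct(self) -> float:
        return 100.0 * self.n_correct / self.n_trials


def _corrected_rate(count: int, n: int) -> float:
    """Proportion with the 1/(2N) correction applied at the 0 and 1 extremes."""
    if n <= 0:
        raise ValueError("rate denominator must be positive")
    if count == 0:
        return 1.0 / (2 * n)
    if count == n:
        return 1.0 - 1.0 / (2 * n)
    return count / n


def score_one_back(
    stream: TokenStream,
    record: BehavioralRecord,
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
) -> OneBackScore:
    """Score one-back probe detection with d'.

    Responses are assigned greedily: scanning responses in time order, each is
    matched to the earliest unmatched probe whose window contains it.  The
    false-alarm opportunity set is the count of non-probe tokens.
    """
    w0, w1 = window_s
    if w0 < 0 or w1 <= w0:
        raise ValueError("response window must satisfy 0 <= start < end")
    probe_onsets = stream.onsets_s[stream.repeat_probes]
    responses = np.sort(record.response_times_s)
    matched = np.zeros(len(probe_onsets), dtype=bool)
    hit_rts = []
    n_fa = 0
    for r in responses:
        candidates = np.flatnonzero(
            ~matched & (r >= probe_onsets + w0) & (r <= probe_onsets + w1)
        )
        if len(candidates):
            p = candidates[0]
            matched[p] = True
            hit_rts.append(r - probe_onsets[p])
        else:
            n_fa += 1
    hits = int(matched.sum())
    n_probes = len(probe_onsets)
    n_nonprobe = int((~stream.is_probe).sum())
    hit_rate = _corrected_rate(hits, n_probes) if n_probes else np.nan
    fa_rate = _corrected_rate(n_fa, n_nonprobe)
    d_prime = float(stats.norm.ppf(hit_rate) - stats.norm.ppf(fa_rate))
    return OneBackScore(
        hits=hits,
        misses=n_probes - hits,
        false_alarms=n_fa,
        n_probes=n_probes,
        n_nonprobe=n_nonprobe,
        d_prime=d_prime,
        hit_rate=hit_rate,
        fa_rate=fa_rate,
        mean_rt_s=float(np.mean(hit_rts)) if hit_rts else float("nan"),
        condition=record.condition,
        participant=record.participant,
    )


def group_rt_test(
    scores_structured: list[OneBackScore], scores_random: list[OneBackScore]
) -> dict:
    """Two-sided paired Wilcoxon signed-rank test on mean reaction times.

    Scores must be paired by participant (same order).  Returns the Z
    statistic (normal approximation) and two-sided p; with all differences
    zero the test is undefined and Z=0, p=1 is reported with a note.
    """
    if len(scores_structured) != len(scores_random):
        raise ValueError("condition lists must be paired by participant")
    a = np.array([s.mean_rt_s for s in scores_structured])
    b = np.array([s.mean_rt_s for s in scores_random])
    diffs = a - b
    if np.allclose(diffs, 0):
        return {"Z": 0.0, "p_value": 1.0, "n": len(a), "note": "all differences zero"}
    res = stats.wilcoxon(a, b, alternative="two-sided", method="approx")
    return {
        "Z": float(res.zstatistic),
        "p_value": float(res.pvalue),
        "n": len(a),
        "note": "",
    }


def dprime_tests(
    scores: list[OneBackScore], paired: list[OneBackScore] | None = None
) -> dict:
    """One-sample t-test of d' against 0, and optionally a paired t-test
    across conditions.  Zero-variance samples yield an infinite t, flagged."""
    d = np.array([s.d_prime for s in scores])
    if len(d) < 2:
        raise ValueError("need >= 2 participants")
    out: dict = {}
    if np.ptp(d) == 0:
        if d[0] == 0:
            out["one_sample"] = {"t": 0.0, "df": len(d) - 1, "p_value": 1.0,
                                 "degenerate": False}
        else:
            out["one_sample"] = {
                "t": float(np.inf) * np.sign(d[0]),
                "df": len(d) - 1,
                "p_value": 0.0,
                "degenerate": True,
            }
    else:
        t, p = stats.ttest_1samp(d, 0.0)
        out["one_sample"] = {"t": float(t), "df": len(d) - 1, "p_value": float(p),
                             "degenerate": False}
    if paired is not None:
        d2 = np.array([s.d_prime for s in paired])
        if len(d2) != len(d):
            raise ValueError("paired scores must match in length")
        t, p = stats.ttest_rel(d, d2)
        out["paired"] = {"t": float(t), "df": len(d) - 1, "p_value": float(p)}
    return out


def score_2afc(scores: list[TwoAFCScore]) -> dict:
    """Group Wilcoxon signed-rank test of 2AFC percent correct against 50%."""
    pct = np.array([s.pct_correct for s in scores])
    diffs = pct - 50.0
    if np.allclose(diffs, 0):
        return {
            "Z": 0.0,
            "p_value": 1.0,
            "mean_pct": 50.0,
            "n": len(pct),
            "note": "all participants exactly at chance; no signed ranks",
        }
    res = stats.wilcoxon(diffs, alternative="two-sided", method="approx")
    return {
        "Z": float(res.zstatistic),
        "p_value": float(res.pvalue),
        "mean_pct": float(pct.mean()),
        "n": len(pct),
        "note": "",
    }
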