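"""Behavioral scoring: trial classification, RT clipping, error decomposition,
and the 2x2 within-subject ANOVA over domain and difficulty.

The task is go/no-go matching: a button press to a matching pair is a hit,
silence a miss; a press to a mismatching pair is a false alarm, silence a
correct rejection.  Responses are only recorded between 300 and 1,900 ms
after stimulus onset; presses outside that window count as absent.
Reaction times are winsorized at 2.5 SD from the participant-condition mean
before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ACTIVE_CONDITIONS

RESPONSE_WINDOW_MS = (300.0, 1900.0)

DOMAIN = {"semantic_easy": "semantic", "semantic_difficult": "semantic",
          "perceptual_easy": "perceptual", "perceptual_difficult": "perceptual"}
DIFFICULTY = {"semantic_easy": "easy", "semantic_difficult": "difficult",
              "perceptual_easy": "easy", "perceptual_difficult": "difficult"}


def classify_trial(is_match: bool, response_time_ms: float | None) -> str:
    """Outcome of one trial; out-of-window responses are treated as absent."""
    responded = (response_time_ms is not None
                 and np.isfinite(response_time_ms)
                 and RESPONSE_WINDOW_MS[0] <= response_time_ms <= RESPONSE_WINDOW_MS[1])
    if is_match:
        return "hit" if responded else "miss"
    return "false_alarm" if responded else "correct_rejection"


def score_trials(events: pd.DataFrame) -> pd.DataFrame:
    """Add an ``outcome`` column to a trial table with response times.

    Rows that are not active-condition trials (rest blocks, missing match
    status) are marked ``unscored``.
    """
    out = events.copy()
    outcomes = []
    for cond, m, rt in zip(out["trial_type"], out["is_match"],
                           out["response_time_ms"]):
        if cond not in ACTIVE_CONDITIONS or pd.isna(m):
            outcomes.append("unscored")
        else:
            outcomes.append(classify_trial(bool(int(m)), rt))
    out["outcome"] = outcomes
    return out


def clip_rts(rts, *, mode: str = "winsorize", reference=None) -> np.ndarray:
    """Clip RTs at mean +/- 2.5 SD of the unclipped values.

    The bounds use the mean and sample SD (n-1 denominator) of the *raw*
    values of one participant-condition cell — pass them as ``reference``
    when ``rts`` has already been processed; by default ``rts`` itself is
    the reference.  Because the bounds derive from the raw cell, clipping is
    a projection onto a fixed interval and re-applying it changes nothing.
    ``mode='winsorize'`` replaces out-of-bound values by the bound
    (default); ``mode='discard'`` drops them.
    """
    x = np.asarray(rts, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        if x.size == 1:
            warnings.warn("single RT value; returned unchanged")
        return x.copy()
    ref = x if reference is None else np.asarray(reference, dtype=float)
    ref = ref[np.isfinite(ref)]
    mu = ref.mean()
    sd = ref.std(ddof=1)
    lo, hi = mu - 2.5 * sd, mu + 2.5 * sd
    if mode == "winsorize":
        return np.clip(x, lo, hi)
    if mode == "discard":
        return x[(x >= lo) & (x <= hi)]
    raise ValueError(f"unknown mode {mode!r}")


def participant_summary(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-condition accuracy, clipped mean RT, miss and false-alarm rates.

    RTs from all trials with (in-window) button presses — hits and false
    alarms pooled — enter the clipped mean.  Rates are over all trials of the
    condition, so miss + false-alarm + correct proportions sum to one.
    """
    rows = []
    for cond in ACTIVE_CONDITIONS:
        sub = scored[scored["trial_type"] == cond]
        n = len(sub)
        if n == 0:
            continue
        miss = (sub["outcome"] == "miss").sum() / n
        fa = (sub["outcome"] == "false_alarm").sum() / n
        pressed = sub["outcome"].isin(["hit", "false_alarm"])
        rts = clip_rts(sub.loc[pressed, "response_time_ms"].to_numpy())
        rows.append(dict(
            condition=cond, n_trials=n, accuracy=1.0 - miss - fa,
            miss_rate=miss, false_alarm_rate=fa,
            mean_rt_ms=float(rts.mean()) if rts.size else np.nan,
        ))
    return pd.DataFrame(rows)


def decompose_errors(summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean miss, false-alarm, and total error rate per condition.

    ``summaries`` stacks per-participant summary tables.  Total error is
    exactly miss rate + false-alarm rate.
    """
    g = summaries.groupby("condition")[["miss_rate", "false_alarm_rate"]].mean()
    g["total_error_rate"] = g["miss_rate"] + g["false_alarm_rate"]
    g["sd_total"] = (summaries.assign(
        tot=summaries["miss_rate"] + summaries["false_alarm_rate"])
        .groupby("condition")["tot"].std())
    return g.reset_index()


@dataclass(frozen=True)
class AnovaEffect:
    effect: str
    F: float
    df1: float
    df2: float
    p: float


def rm_anova_2x2(table: pd.DataFrame) -> pd.DataFrame:
    """2 (domain) x 2 (difficulty) repeated-measures ANOVA.

    ``table`` has one row per participant and one column per active
    condition.  With two levels per factor each effect is an exact F(1, n-1)
    test — the squared one-sample t of the per-participant contrast score —
    and no sphericity correction applies.
    """
    missing = [c for c in ACTIVE_CONDITIONS if c not in table.columns]
    if missing:
        raise ValueError(f"table missing condition columns: {missing}")
    if table[list(ACTIVE_CONDITIONS)].isna().any().any():
        raise ValueError("missing cells are not allowed")
    n = len(table)
    if n < 3:
        raise ValueError("need at least 3 participants")
    se = table["semantic_easy"].to_numpy(float)
    sd_ = table["semantic_difficult"].to_numpy(float)
    pe = table["perceptual_easy"].to_numpy(float)
    pd_ = table["perceptual_difficult"].to_numpy(float)
    # grouped as paired differences so identical cells cancel exactly
    contrasts = {
        "domain": ((se - pe) + (sd_ - pd_)) / 2.0,
        "difficulty": ((sd_ - se) + (pd_ - pe)) / 2.0,
        "interaction": (sd_ - se) - (pd_ - pe),
    }
    rows = []
    for name, c in contrasts.items():
        var = c.var(ddof=1)
        F = 0.0 if var == 0 else n * c.mean() ** 2 / var
        p = float(stats.f.sf(F, 1, n - 1)) if var > 0 else 1.0
        rows.append(AnovaEffect(name, float(F), 1.0, float(n - 1), p))
    return pd.DataFrame([r.__dict__ for r in rows])


def accuracy_table(scored_by_participant: dict[str, pd.DataFrame],
                   measure: str = "accuracy") -> pd.DataFrame:
    """Participant x condition table of a summary measure for the ANOVA."""
    rows = {}
    for pid, scored in scored_by_participant.items():
        summ = participant_summary(scored).set_index("condition")[measure]
        rows[pid] = summ
    return pd.DataFrame(rows).T[list(ACTIVE_CONDITIONS)]
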