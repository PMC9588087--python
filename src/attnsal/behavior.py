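"""Behavioral scoring and across-session statistics.

Outcome labels follow the detection-task rules: a saccade within the response
window after a target luminance change is a hit, a response to a distractor
change is a false alarm, holding fixation through a distractor-only trial is
a correct rejection, and anything else is a miss.  Session metrics are
summarized as mean +/- SEM across sessions and compared with a two-tailed
Wilcoxon signed-rank test (exact sign-flip enumeration for small n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task import TaskConfig, TaskTrial

SALIENCE_LEVELS = ("salient", "non_salient", "any")


def score_trial(trial: TaskTrial, config: TaskConfig) -> str:
    """Recompute the outcome label of a trial from its response timing.

    Returns one of hit / miss / false_alarm / correct_rejection, or "break"
    for a premature response (before any luminance change), which is excluded
    from all rate denominators.
    """
    lo, hi = config.response_window
    resp = trial.t_response

    def in_window(change_time):
        return (change_time is not None and resp is not None
                and change_time + lo <= resp < change_time + hi)

    changes = [t for t in (trial.t_change_on, trial.t_distractor_change_on) if t is not None]
    if resp is not None and changes and resp < min(changes) + lo:
        return "break"

    if trial.paradigm == "D":
        return "hit" if in_window(trial.t_change_on) else "miss"

    # paradigm G: the distractor change resolves first
    if trial.trial_type in ("distractor_only", "distractor_target"):
        if in_window(trial.t_distractor_change_on):
            return "false_alarm"
        if trial.trial_type == "distractor_only":
            return "correct_rejection" if resp is None else "miss"
    return "hit" if in_window(trial.t_change_on) else "miss"


def _condition(trial: TaskTrial) -> tuple:
    sal = trial.change_at_salient
    sal_label = None if sal is None else ("salient" if sal else "non_salient")
    return trial.trial_type, sal_label


@dataclass
class SessionPerformance:
    """Per-condition outcome counts, rates, and RT means for one session."""

    paradigm: str
    table: pd.DataFrame  # rows: (trial_type, salience) incl. "any" marginals

    def metric(self, trial_type: str, salience: str, name: str) -> float:
        return float(self.table.loc[(trial_type, salience), name])


def session_performance(trials: Sequence[TaskTrial], config: TaskConfig) -> SessionPerformance:
    """Score every trial and tabulate counts/rates per condition.

    Single-stimulus trials and premature breaks are excluded.  The salience
    split ("salient" / "non_salient") covers only trials with distinct
    stimulus values; the "any" rows are marginals over all double-stimulus
    trials of that type.
    """
    rows = {}
    for trial in trials:
        if trial.is_single_stimulus:
            continue
        outcome = score_trial(trial, config)
        if outcome == "break":
            continue
        ttype, sal = _condition(trial)
        cells = [(ttype, "any")] + ([(ttype, sal)] if sal is not None else [])
        for key in cells:
            row = rows.setdefault(key, {o: 0 for o in
                                        ("hit", "miss", "false_alarm", "correct_rejection")})
            row[outcome] += 1
            if outcome in ("hit", "false_alarm") and trial.rt_s is not None:
                row.setdefault("_rts_" + outcome, []).append(trial.rt_s)

    records = []
    for (ttype, sal), row in sorted(rows.items()):
        n_target = row["hit"] + row["miss"]
        n_distractor = row["false_alarm"] + row["correct_rejection"] + (
            row["hit"] + row["miss"] if ttype == "distractor_target" else 0)
        rec = {
            "trial_type": ttype, "salience": sal,
            "n_hit": row["hit"], "n_miss": row["miss"],
            "n_false_alarm": row["false_alarm"],
            "n_correct_rejection": row["correct_rejection"],
            "hit_rate": row["hit"] / n_target if n_target else np.nan,
            "cr_rate": (row["correct_rejection"]
                        / (row["correct_rejection"] + row["false_alarm"])
                        if (row["correct_rejection"] + row["false_alarm"]) else np.nan),
            "fa_rate": row["false_alarm"] / n_distractor if n_distractor else np.nan,
            "rt_hit_mean_s": float(np.mean(row["_rts_hit"])) if "_rts_hit" in row else np.nan,
            "rt_fa_mean_s": (float(np.mean(row["_rts_false_alarm"]))
                             if "_rts_false_alarm" in row else np.nan),
        }
        records.append(rec)
    table = pd.DataFrame.from_records(records).set_index(["trial_type", "salience"])
    return SessionPerformance(paradigm=config.paradigm, table=table)


def summarize_sessions(sessions: Sequence[SessionPerformance],
                       metrics=("hit_rate", "cr_rate", "fa_rate", "rt_hit_mean_s",
                                "rt_fa_mean_s")) -> pd.DataFrame:
    """Across-session mean and SEM (sd/sqrt(n), n-1 denominator) per condition.

    Conditions missing in a session are excluded pairwise (n reflects the
    sessions contributing to each cell).
    """
    if len(sessions) < 2:
        raise ValueError("need at least two sessions")
    frames = [s.table for s in sessions]
    all_index = frames[0].index
    for f in frames[1:]:
        all_index = all_index.union(f.index)
    records = []
    for key in all_index:
        for metric in metrics:
            vals = np.array([float(f.loc[key, metric]) if key in f.index else np.nan
                             for f in frames])
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            records.append({
                "trial_type": key[0], "salience": key[1], "metric": metric,
                "mean": vals.mean() if n else np.nan,
                "sem": vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan,
                "n_sessions": n,
            })
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float
    direction: int  # sign of the median difference (a - b)
    n: int  # pairs after zero-difference removal
    degenerate: bool = False
    exact: bool = True


def _exact_signflip_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Two-tailed p by enumeration of all 2^n sign assignments of the ranks.

    Tied ranks are mid-ranks, so work on doubled (integer) ranks and build the
    exact distribution of 2*W+ by dynamic-programming convolution.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def paired_wilcoxon(values_a, values_b, exact_max_n: int = 15) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test on paired per-session metrics.

    Zero differences are dropped (Wilcoxon's rule); ties get mid-ranks.  For
    n <= ``exact_max_n`` the p-value is exact over all sign assignments,
    otherwise a tie-corrected normal approximation is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    d = (a - b)[keep]
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, direction=0, n=0, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    direction = int(np.sign(w_plus - ranks.sum() / 2))
    if n < 5:
        # too few pairs for a meaningful test; still report the exact p
        pass
    if n <= exact_max_n:
        p = _exact_signflip_pvalue(ranks, w_plus)
        return WilcoxonResult(w_plus, p, direction, n, exact=True)
    mean = ranks.sum() / 2
    # variance of W+ under random signs: sum(rank^2)/4 (tie-corrected by construction)
    var = float((ranks ** 2).sum()) / 4.0
    z = (w_plus - mean) / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, min(1.0, p), direction, n, exact=False)
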