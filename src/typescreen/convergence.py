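"""Session-count convergence and daily trajectories of the screening score.

A subject's screening score is the running mean of their chronological
session probabilities.  The *convergence count* is the smallest number of
sessions after which every cumulative mean stays within a tolerance
(default 0.05) of the final full-sequence mean — i.e. how much typing is
needed before the estimate is stable.  Daily trajectories aggregate session
probabilities per calendar day, supporting the analysis of day-to-day
variability against daily typing volume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import correlation_with_phq9

__all__ = [
    "convergence_session_count",
    "convergence_table",
    "daily_trajectories",
    "daily_variability_correlation",
]


def convergence_session_count(session_probs, tolerance: float = 0.05) -> int:
    """Smallest n such that all cumulative means from n on lie within
    ``tolerance`` of the final mean.

    The result always satisfies its defining predicate (re-scannable) and is
    1 for a constant stream.
    """
    p = np.asarray(session_probs, dtype=float)
    if len(p) == 0:
        raise ValueError("need at least one session probability")
    cum = np.cumsum(p) / np.arange(1, len(p) + 1)
    final = cum[-1]
    dev = np.abs(cum - final)
    bad = np.flatnonzero(dev > tolerance)
    return 1 if len(bad) == 0 else int(bad[-1]) + 2


def convergence_table(results, tolerance: float = 0.05) -> pd.DataFrame:
    """Per-subject convergence counts and final means from a results object."""
    rows = []
    for s in results.subject_ids:
        probs = results.session_probs(s)
        rows.append(
            {"subject_id": s,
             "n_sessions": len(probs),
             "n_converge": convergence_session_count(probs, tolerance),
             "final_mean": float(np.mean(probs))}
        )
    return pd.DataFrame(rows)


def daily_trajectories(session_table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject daily mean probability and session count.

    ``session_table`` needs columns ``subject_id``, ``day_index`` and
    ``prob`` (as produced by the LOSO results).  Days with no sessions are
    simply absent from the output.
    """
    grouped = (
        session_table.groupby(["subject_id", "day_index"])["prob"]
        .agg(mean_prob="mean", n_sessions="count")
        .reset_index()
    )
    return grouped


def daily_variability_correlation(
    daily: pd.DataFrame, min_days: int = 2
) -> tuple[float, float]:
    """Spearman correlation of daily-probability variability vs typing volume.

    For every subject with at least ``min_days`` observed days, computes the
    standard deviation of daily mean probabilities and the average daily
    session count, then correlates the two across subjects.  Subjects with a
    single day are excluded.
    """
    stats_rows = []
    for subject, g in daily.groupby("subject_id"):
        if len(g) < min_days:
            continue
        stats_rows.append(
            {"subject_id": subject,
             "daily_std": float(g["mean_prob"].std(ddof=1)),
             "mean_daily_sessions": float(g["n_sessions"].mean())}
        )
    if len(stats_rows) < 3:
        raise ValueError("need at least 3 subjects with enough days")
    frame = pd.DataFrame(stats_rows)
    return correlation_with_phq9(
        frame["daily_std"].to_numpy(), frame["mean_daily_sessions"].to_numpy()
    )
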