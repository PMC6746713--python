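"""Per-session feature vectors: dynamics statistics plus typing metadata.

Each valid session is summarised by four statistics — median, standard
deviation, skewness and kurtosis — of each of the four dynamics variables
(HT, FT, SP, PFR), plus four metadata values: session duration T (s),
characters typed L, delete rate DR and characters per minute CPM.  That gives
the fixed 20-dimensional session feature vector used by the screening
pipeline.

Statistic conventions
---------------------
* median: midpoint rule on the ascending-sorted sequence,
  ``(a_ceil(n/2) + a_floor(n/2+1)) / 2`` with 1-based indexing;
* std: population standard deviation ``sqrt(sum (a_k - mu)^2 / N)``;
* skewness / kurtosis: ``sum z^3 / (N+1)`` and ``sum z^4 / (N+1)`` with
  ``z = (a_k - mu) / sigma``.  The ``N+1`` denominator is the method's native
  convention; ``standard_moments=True`` switches to the usual ``N``.  The
  difference is a per-sequence scalar factor and does not affect ranking-based
  analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    DynamicsSequences,
    FilterConfig,
    extract_dynamics,
    flag_outlier_sessions,
    is_valid_session,
)
from .sessions import RawTypingSession

MS_PER_DAY = 86_400_000

DYNAMICS_VARIABLES = ("ht", "ft", "sp", "pfr")
STATISTIC_NAMES = ("median", "std", "skew", "kurt")
METADATA_NAMES = ("t_s", "l_chars", "dr", "cpm")

#: Canonical order of the 20 session features.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{var}_{stat}" for var in DYNAMICS_VARIABLES for stat in STATISTIC_NAMES
) + METADATA_NAMES

MIN_SEQUENCE_LENGTH = 4


class IncompleteSessionError(ValueError):
    """A session lacks a component of the 20-feature vector."""


@dataclass(frozen=True)
class SessionFeatureVector:
    subject_id: str
    session_id: str
    day_index: int
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(FEATURE_NAMES):
            raise IncompleteSessionError(
                f"expected {len(FEATURE_NAMES)} features, got {len(self.values)}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(FEATURE_NAMES, self.values))


def summary_statistics(
    seq: Sequence[float], standard_moments: bool = False
) -> tuple[float, float, float, float]:
    """(median, std, skew, kurt) of a sequence, per the module conventions.

    Sequences shorter than :data:`MIN_SEQUENCE_LENGTH` raise; a zero-variance
    sequence yields skew = kurt = 0.
    """
    a = np.sort(np.asarray(seq, dtype=float))
    n = len(a)
    if n < MIN_SEQUENCE_LENGTH:
        raise ValueError(f"need at least {MIN_SEQUENCE_LENGTH} values, got {n}")
    # 1-based ceil/floor midpoint rule
    lo = a[math.ceil(n / 2) - 1]
    hi = a[math.floor(n / 2 + 1) - 1]
    median = (lo + hi) / 2.0
    mu = a.mean()
    std = float(np.sqrt(np.mean((a - mu) ** 2)))
    if std == 0.0:
        return float(median), 0.0, 0.0, 0.0
    z = (a - mu) / std
    denom = n if standard_moments else n + 1
    skew = float(np.sum(z**3) / denom)
    kurt = float(np.sum(z**4) / denom)
    return float(median), std, skew, kurt


def session_metadata(session: RawTypingSession) -> tuple[float, int, float, float]:
    """(T, L, DR, CPM) of a session.

    T is the elapsed time (s) from keyboard launch to the last key release;
    L counts character registrations (deletes excluded); DR is delete presses
    over total key presses; CPM = L / (T / 60).
    """
    if session.n_keys == 0:
        raise ValueError(f"session {session.session_id} has no events")
    last_release = max(e.release_time for e in session.events)
    t_s = (last_release - session.start_time) / 1000.0
    n_deletes = sum(e.is_delete for e in session.events)
    l_chars = session.n_keys - n_deletes
    dr = n_deletes / session.n_keys
    if t_s <= 0:
        raise ValueError(f"session {session.session_id}: non-positive duration")
    cpm = l_chars / (t_s / 60.0)
    return t_s, l_chars, dr, cpm


def assemble_feature_vector(
    stats: Mapping[str, tuple[float, float, float, float]],
    metadata: tuple[float, float, float, float],
    subject_id: str = "",
    session_id: str = "",
    day_index: int = 0,
) -> SessionFeatureVector:
    """Combine per-variable statistics and metadata into the 20-vector.

    ``stats`` maps each of ``ht``, ``ft``, ``sp``, ``pfr`` to its
    (median, std, skew, kurt) tuple; any missing variable raises
    :class:`IncompleteSessionError`.
    """
    values: list[float] = []
    for var in DYNAMICS_VARIABLES:
        if var not in stats:
            raise IncompleteSessionError(f"missing statistics for variable '{var}'")
        quad = tuple(stats[var])
        if len(quad) != 4:
            raise IncompleteSessionError(f"variable '{var}' needs 4 statistics")
        values.extend(float(v) for v in quad)
    if len(metadata) != 4:
        raise IncompleteSessionError("metadata must be (T, L, DR, CPM)")
    values.extend(float(v) for v in metadata)
    return SessionFeatureVector(
        subject_id=subject_id,
        session_id=session_id,
        day_index=day_index,
        values=tuple(values),
    )


def session_features(
    session: RawTypingSession,
    dyn: DynamicsSequences,
    day_index: int = 0,
    standard_moments: bool = False,
) -> SessionFeatureVector:
    """Feature vector of one filtered session; raises if any component is missing."""
    stats = {}
    for var in DYNAMICS_VARIABLES:
        seq = getattr(dyn, var)
        if len(seq) < MIN_SEQUENCE_LENGTH:
            raise IncompleteSessionError(
                f"session {session.session_id}: variable '{var}' has "
                f"{len(seq)} values after filtering (< {MIN_SEQUENCE_LENGTH})"
            )
        stats[var] = summary_statistics(seq, standard_moments=standard_moments)
    meta = session_metadata(session)
    return assemble_feature_vector(
        stats, meta,
        subject_id=session.subject_id,
        session_id=session.session_id,
        day_index=day_index,
    )


def extract_feature_table(
    sessions: Iterable[RawTypingSession],
    cfg: FilterConfig | None = None,
    standard_moments: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Cohort-level feature extraction.

    Applies, in order: the 8-key validity rule, the timing filters, the
    per-user 3-sigma FT-median outlier rule, and the completeness requirement
    (every variable must retain at least four values).  Returns the feature
    table (one row per surviving session, columns ``subject_id``,
    ``session_id``, ``day_index``, then the 20 canonical features) and a count
    report of sessions read / invalid / outlier-flagged / incomplete / kept.
    """
    cfg = cfg or FilterConfig()
    report = {"read": 0, "invalid": 0, "outlier": 0, "incomplete": 0, "kept": 0}

    by_subject: dict[str, list[tuple[RawTypingSession, DynamicsSequences]]] = {}
    for s in sessions:
        report["read"] += 1
        if not is_valid_session(s, cfg.min_keys):
            report["invalid"] += 1
            continue
        by_subject.setdefault(s.subject_id, []).append((s, extract_dynamics(s, cfg)))

    rows = []
    for subject_id, pairs in by_subject.items():
        pairs.sort(key=lambda p: p[0].start_time)
        day0 = pairs[0][0].start_time // MS_PER_DAY
        mask = flag_outlier_sessions([d for _, d in pairs], cfg.outlier_sigma)
        for (sess, dyn), flagged in zip(pairs, mask):
            if flagged:
                report["outlier"] += 1
                continue
            day_index = int(sess.start_time // MS_PER_DAY - day0)
            try:
                fv = session_features(
                    sess, dyn, day_index=day_index, standard_moments=standard_moments
                )
            except (IncompleteSessionError, ValueError):
                report["incomplete"] += 1
                continue
            rows.append(
                {"subject_id": fv.subject_id, "session_id": fv.session_id,
                 "day_index": fv.day_index, **fv.as_dict()}
            )
            report["kept"] += 1

    columns = ["subject_id", "session_id", "day_index", *FEATURE_NAMES]
    table = pd.DataFrame(rows, columns=columns)
    return table, report
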